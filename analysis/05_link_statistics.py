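#!/usr/bin/env python
"""Relate the quantified neurochemistry to the BOLD hemodynamics.

Reports the young-vs-old group differences (pooled t, Cohen's d) of the
fitted GABA+ and Glx, the F statistic of their mutual regression, the
power-based per-group sample size at the GABA+ effect size, the Bonferroni
threshold for three first-segment regions, and the adjusted-R^2-ranked
7-model suite for each HRF metric.
"""

import pandas as pd

from common import RESULTS
from megabold import io as mio
from megabold.stats_link import (
    bonferroni_alpha,
    fit_model_suite,
    group_difference,
    power_sample_size,
    regression_f_from_r2,
)

conc = mio.read_table(RESULTS / "03_concentrations.tsv")
metrics = mio.read_table(RESULTS / "04_hrf_metrics.tsv")
table = conc.merge(metrics, on=["subject_id", "group"])

young = table[table.group == "young"]
old = table[table.group == "old"]
for met in ("GABA", "Glx"):
    r = group_difference(young[met], old[met])
    print(f"  {met:4s}: t = {r['t']:.2f}, p = {r['p']:.3f}, "
          f"d = {r['d']:.2f}")

r2 = table[["GABA", "Glx"]].corr().iloc[0, 1] ** 2
f = regression_f_from_r2(r2, len(table), 1)
print(f"  GABA-Glx: R^2 = {r2:.2f}, F = {f:.2f}")

d_gaba = group_difference(young.GABA, old.GABA)["d"]
if d_gaba > 0:
    print(f"  per-group n for 80% power at d = {d_gaba:.2f}: "
          f"{power_sample_size(d_gaba)}")
print(f"  Bonferroni threshold for 3 regions: "
      f"{bonferroni_alpha(0.01, 3):.4f}")

report = []
for resp in ("amplitude", "ttp", "fwhm"):
    fits = fit_model_suite(table, resp)
    best = fits[0]
    print(f"  {resp:9s}: best model {best.name} "
          f"(adj R^2 = {best.rsquared_adj:.2f}, F = {best.fvalue:.2f}, "
          f"p = {best.f_pvalue:.3f}, {best.flag})")
    for _, row in best.params.iterrows():
        report.append(
            {"response": resp, "best_model": best.name,
             "R2": best.rsquared, "adj_R2": best.rsquared_adj,
             "F": best.fvalue, "p": best.f_pvalue, "term": row["term"],
             "beta": row["beta"], "t": row["t"], "term_p": row["p"]}
        )
mio.write_table(RESULTS / "05_model_report.tsv", pd.DataFrame(report))
print(f"  model report -> {RESULTS/'05_model_report.tsv'}")
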