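#!/usr/bin/env python
"""Generate the synthetic two-group cohort and report its calibration.

Draws 14 young / 14 old subjects with correlated GABA+/Glx from the group
distributions, age-dependent linewidth and CSF fraction, and baseline CBF;
writes the ground-truth cohort table and prints the group summaries it
realises.
"""

import pandas as pd

from common import COHORT, RESULTS
from megabold import io as mio
from megabold import synthetic

cohort = synthetic.generate_cohort(COHORT)
table = pd.DataFrame([vars(s) for s in cohort])
RESULTS.mkdir(exist_ok=True)
mio.write_table(RESULTS / "01_cohort_truth.tsv", table)

print(f"generated {len(table)} subjects -> {RESULTS/'01_cohort_truth.tsv'}")
for g, sub in table.groupby("group"):
    print(
        f"  {g:5s}: age {sub.age.mean():5.1f}+/-{sub.age.std():4.1f}  "
        f"GABA {sub.true_gaba.mean():4.2f}+/-{sub.true_gaba.std():4.2f}  "
        f"Glx {sub.true_glx.mean():5.2f}+/-{sub.true_glx.std():4.2f}  "
        f"linewidth {sub.linewidth.mean():4.1f} Hz"
    )
r2 = table[["true_gaba", "true_glx"]].corr().iloc[0, 1] ** 2
print(f"  realised GABA-Glx R^2 = {r2:.2f} (target 0.48)")
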