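#!/usr/bin/env python
"""Extract task-BOLD hemodynamics and parcellate the voxel grid.

Per subject: deconvolve the 48-s HRF (13 FIR taps at TR 4 s), spline
interpolate to 0.5 s, extract the biphasic peak metrics (signed amplitude,
time-to-peak, FWHM), compute segment-wise Z(AUC), and neuro-sensitize
against baseline CBF.  Group-level one-sample t-tests with sign-flip
cluster-extent FWE control parcellate the grid into anterior/mid/posterior
regions.
"""

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from common import BOLD, BOLD_NOISE_SD, COHORT, RESULTS, SEED, VOXEL_GRID
from megabold import hemodynamics as hemo
from megabold import io as mio
from megabold import synthetic

cohort = synthetic.generate_cohort(COHORT)
rows, z_by_seg, cbf_maps = [], [[], [], []], []
affine = None
for s in cohort:
    ds = synthetic.synthesize_bold_dataset(
        s, BOLD, voxel_grid=VOXEL_GRID, noise_sd=BOLD_NOISE_SD, seed=SEED,
        coupling=COHORT.coupling_coeffs,
    )
    affine = ds.affine
    taps, avg = hemo.deconvolve_hrf(ds.runs, list(ds.truth["stimulus"]),
                                    BOLD)
    avg = hemo.interpolate_hrf(avg)
    m = hemo.hrf_peak_metrics(avg)
    curves = CubicSpline(avg.times, taps, axis=0)(avg.fine_times).T
    energ = hemo.segment_energetics(curves, avg.fine_times)
    cbf_maps.append(ds.cbf.ravel())
    for k in range(3):
        z_by_seg[k].append(energ.z[k])
    rows.append(
        {"subject_id": s.subject_id, "group": s.group,
         "amplitude": m.amplitude, "ttp": m.ttp, "fwhm": m.fwhm}
    )

metrics = pd.DataFrame(rows)
mio.write_table(RESULTS / "04_hrf_metrics.tsv", metrics)
for g, sub in metrics.groupby("group"):
    print(
        f"  {g:5s}: amplitude {sub.amplitude.mean():5.2f}%  "
        f"ttp {sub.ttp.mean():4.1f} s  fwhm {sub.fwhm.mean():4.1f} s"
    )

cbf_mat = np.array(cbf_maps)
parcel = {}
for k in range(3):
    z = np.array(z_by_seg[k])
    # neuro-sensitized maps feed the ROI regressions; cluster inference
    # runs on the per-group segment-wise Z(AUC) maps themselves
    sens, _ = hemo.neurosensitize(z, cbf_mat)
    for g in ("young", "old"):
        idx = [i for i, s in enumerate(cohort) if s.group == g]
        maps = z[idx].reshape((len(idx),) + VOXEL_GRID)
        res = hemo.parcellate(maps, affine, n_null=1000, seed=SEED)
        parcel[f"seg{k+1}-{g}"] = {
            "n_clusters": len(res.clusters),
            "extent_threshold": res.cluster_extent_threshold,
            "clusters": [
                {"size": c.size, "centroid_mm": list(c.centroid_mm),
                 "label": c.label, "peak_t": c.peak_t}
                for c in res.clusters
            ],
        }
mio.write_json(RESULTS / "04_parcellation.json", parcel)
n_tot = sum(v["n_clusters"] for v in parcel.values())
print(f"  {n_tot} surviving clusters across segments/groups "
      f"-> {RESULTS/'04_parcellation.json'}")
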