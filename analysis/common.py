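"""Shared desk-scale configuration for the numbered analysis drivers.

The cohort matches the study conditions (14 young / 14 old with the
printed GABA+/Glx distributions); the per-subject transient count is kept
moderate so every driver runs in seconds-to-minutes on one CPU.
"""

from pathlib import Path

from megabold.types import AcquisitionSpec, BoldDesign, CohortSpec

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 20260924

COHORT = CohortSpec(n_young=14, n_old=14, seed=SEED)
ACQ = AcquisitionSpec(n_transient_pairs=64)
BOLD = BoldDesign()
VOXEL_GRID = (8, 8, 8)
MRS_NOISE_SD = 100.0
BOLD_NOISE_SD = 0.2
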