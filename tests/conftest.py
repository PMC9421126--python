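"""Shared fixtures: small acquisition geometries, a default basis set, and
a session-scope collection of preprocessed synthetic cohorts used by the
baseline-sweep tests (generating them once keeps the suite fast)."""

from __future__ import annotations

import numpy as np
import pytest

from megabold import lc_fit, mrs_prep, synthetic
from megabold.types import AcquisitionSpec, CohortSpec, DriftModel


@pytest.fixture(scope="session")
def acq() -> AcquisitionSpec:
    return AcquisitionSpec()


@pytest.fixture(scope="session")
def acq_fast() -> AcquisitionSpec:
    """Shorter FID for tests that only need the transforms."""
    return AcquisitionSpec(n_points=1024, n_transient_pairs=8)


@pytest.fixture(scope="session")
def basis(acq) -> synthetic.BasisSet:
    return synthetic.generate_basis(acq)


def make_diff(
    subject,
    basis,
    acq,
    noise_sd: float = 8.0,
    seed: int = 0,
    background=synthetic.BackgroundModel(),
):
    """Averaged-level difference spectrum for one subject: a single
    noiseless-pair synthesis plus spectrum-level noise equivalent to an
    averaged multi-transient acquisition (no drift, so no registration
    needed).  Much faster than the full transient path for fit-level
    tests."""
    one_pair = acq.model_copy(update={"n_transient_pairs": 1})
    series, water = synthetic.synthesize_megapress_fids(
        subject, basis, one_pair,
        drift_model=None, noise_sd=noise_sd, seed=seed,
        background=background,
    )
    diff, off = mrs_prep.average_and_difference(series, align=False)
    return diff, off, water


@pytest.fixture(scope="session")
def sweep_replicates(acq, basis):
    """Twenty preprocessed synthetic cohorts (full transient path: drift,
    registration, rejection, averaging) for the baseline-sweep tests."""
    acq_sw = acq.model_copy(update={"n_transient_pairs": 48})
    out = []
    for rep in range(20):
        cohort = synthetic.generate_cohort(
            CohortSpec(n_young=3, n_old=3, seed=1000 + rep)
        )
        diffs = []
        for s in cohort:
            series, _ = synthetic.synthesize_megapress_fids(
                s, basis, acq_sw, drift_model=DriftModel(),
                noise_sd=100.0, seed=1000 + rep,
            )
            drift, corr = mrs_prep.spectral_register(series)
            keep = mrs_prep.reject_transients(
                drift, edit_labels=series.edit_labels
            )
            diff, _ = mrs_prep.average_and_difference(corr, keep)
            diffs.append(diff)
        table, report = lc_fit.sweep_and_select(diffs, basis)
        out.append({"cohort": cohort, "table": table, "report": report})
    return out
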