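"""Synthetic cohort, spectra, and BOLD generation.

Generates every input the pipeline consumes, with the statistical structure
the downstream analysis assumes:

* a two-group (young/old) cohort whose GABA+/Glx values are drawn from the
  study's group distributions with correlated GABA-Glx, age-dependent
  linewidth, CSF fraction, and baseline CBF;
* a parametric difference-spectrum basis set (Lorentzian-Gaussian multiplets
  at literature chemical shifts; no density-matrix simulation);
* interleaved ON/OFF MEGA-PRESS transients with frequency/phase drift, an
  unmodeled smooth background (so baseline fitting is exercised), and a
  matching unsuppressed-water series;
* sparse-sampled task-BOLD runs built from a biphasic ground-truth HRF whose
  latency/dispersion/amplitude are coupled to age, GABA x Glx, and baseline
  CBF, together with CBF and tissue-fraction maps.

All randomness flows from one master seed via named substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import gamma as gamma_dist

from .mrs_prep import (
    WATER_PPM,
    TransientSeries,
    fid_to_spectrum,
    ppm_axis,
    time_axis,
)
from .types import (
    AcquisitionSpec,
    BoldDesign,
    CohortSpec,
    DriftModel,
    SubjectRecord,
    substream,
)

__all__ = [
    "BasisSet",
    "LineshapeParams",
    "BackgroundModel",
    "BoldDataset",
    "DEFAULT_DIFF_LINES",
    "DEFAULT_OFF_LINES",
    "generate_cohort",
    "generate_basis",
    "synthesize_megapress_fids",
    "synthesize_bold_dataset",
    "gaussian_component_for_linewidth",
    "default_affine",
]

_LN2 = np.log(2.0)

# Difference-spectrum signatures: metabolite -> list of (ppm, weight).
# GABA+ appears as a broad pseudo-triplet at 3 ppm (the co-edited
# macromolecule-contaminated composite), Glx as the 3.75 ppm
# glutamate+glutamine multiplet, and NAA as the inverted 2 ppm resonance
# characteristic of the edited difference spectrum.
DEFAULT_DIFF_LINES: dict[str, list[tuple[float, float]]] = {
    "GABA": [(2.93, 0.33), (3.01, 0.34), (3.09, 0.33)],
    "Glx": [(3.68, 0.33), (3.76, 0.34), (3.84, 0.33)],
    "NAA": [(2.01, -1.0)],
}

# Static (non-edited) content shared by ON and OFF sub-spectra; it cancels
# in the difference but provides the 3 ppm creatine reference for alignment
# and linewidth QC.  name -> (ppm, amplitude in generator units).
DEFAULT_OFF_LINES: dict[str, tuple[float, float]] = {
    "Cr": (3.03, 6.0),
    "Cho": (3.19, 2.5),
    "NAA_off": (2.01, 9.0),
    "mI": (3.55, 4.0),
}


@dataclass
class LineshapeParams:
    """Intrinsic basis lineshape before any subject broadening."""

    lorentz_fwhm: float = 2.0   # Hz
    gauss_fwhm: float = 0.0     # Hz

    def __post_init__(self) -> None:
        if self.lorentz_fwhm <= 0:
            raise ValueError("lorentz_fwhm must be > 0")
        if self.gauss_fwhm < 0:
            raise ValueError("gauss_fwhm must be >= 0")


@dataclass
class BasisSet:
    """Frequency-domain basis spectra on the shared ppm axis.

    Each signature is normalised so its real part integrates (over its
    multiplet window, in ppm) to the configured amplitude (default 1) at
    the intrinsic lineshape; amplitudes in the linear-combination fit are
    therefore in integral units.
    """

    metabolite_names: list[str]
    basis_spectra: np.ndarray       # complex, (n_metabolites, n_points)
    ppm_axis: np.ndarray
    acq: AcquisitionSpec
    lineshape: LineshapeParams
    lines: dict[str, list[tuple[float, float]]]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.basis_spectra.view(float))):
            raise ValueError("basis spectra must be finite")
        if len(self.ppm_axis) != self.acq.n_points:
            raise ValueError("ppm_axis length must equal n_points")

    def spectrum(self, name: str) -> np.ndarray:
        return self.basis_spectra[self.metabolite_names.index(name)]


@dataclass
class BackgroundModel:
    """Smooth unmodeled background added to the ON sub-spectrum (and hence
    present in the difference), emulating macromolecule/lipid and residual
    shim structure not represented in the basis set.

    Each hump is (ppm center, FWHM in ppm, integral amplitude); amplitudes
    grow mildly with age (macromolecule contamination) and are jittered per
    subject.
    """

    humps: list[tuple[float, float, float]] = field(
        default_factory=lambda: [
            (2.20, 0.6, 0.65),
            (2.90, 0.6, 0.50),
            (3.50, 0.6, -0.40),
            (4.00, 0.6, 0.45),
        ]
    )
    scale: float = 1.0
    age_slope: float = 0.004        # fractional amplitude per year about 45
    subject_jitter_sd: float = 0.08


def _lorentz_gauss_fid(
    t: np.ndarray,
    ppm: float,
    acq: AcquisitionSpec,
    lorentz_fwhm: float,
    gauss_fwhm: float,
) -> np.ndarray:
    """Time-domain signal of one resonance with a Voigt-family lineshape."""
    f_off = (WATER_PPM - ppm) * acq.transmitter_freq
    env = np.exp(-np.pi * lorentz_fwhm * t)
    if gauss_fwhm > 0:
        env = env * np.exp(-((np.pi * gauss_fwhm * t) ** 2) / (4.0 * _LN2))
    return np.exp(2j * np.pi * f_off * t) * env


def _unit_integral_line_fid(
    t: np.ndarray,
    ppm_c: float,
    acq: AcquisitionSpec,
    lorentz_fwhm: float,
    gauss_fwhm: float,
    pad_ppm: float = 0.5,
) -> np.ndarray:
    """Single resonance scaled so its absorption-mode real part integrates
    to 1 over the line's ppm window — the same amplitude convention as the
    basis signatures, so static lines, water, and background humps are
    commensurate with the fitted metabolite amplitudes."""
    fid = _lorentz_gauss_fid(t, ppm_c, acq, lorentz_fwhm, gauss_fwhm)
    spec = fid_to_spectrum(fid, acq)
    ppm = ppm_axis(acq)
    asc = np.argsort(ppm)
    win = (ppm[asc] >= ppm_c - pad_ppm) & (ppm[asc] <= ppm_c + pad_ppm)
    integral = np.trapezoid(spec.real[asc][win], ppm[asc][win])
    return fid / abs(integral)


def gaussian_component_for_linewidth(
    total_fwhm: float, lorentz_fwhm: float
) -> float:
    """Gaussian FWHM (Hz) to add to a Lorentzian of width ``lorentz_fwhm``
    so the combined (Voigt) line has ``total_fwhm``, using the standard
    Voigt-width approximation."""
    rest = (total_fwhm - 0.5346 * lorentz_fwhm) ** 2 - 0.2166 * lorentz_fwhm**2
    return float(np.sqrt(max(rest, 0.0)))


def _gauss_envelope(t: np.ndarray, gauss_fwhm: float) -> np.ndarray:
    if gauss_fwhm <= 0:
        return np.ones_like(t)
    return np.exp(-((np.pi * gauss_fwhm * t) ** 2) / (4.0 * _LN2))


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Draw the per-subject ground truth for a two-group cohort.

    GABA and Glx are drawn per group from a bivariate normal whose
    cross-correlation is sqrt(gaba_glx_r2); linewidth and baseline CBF are
    group-dependent; CSF fraction is uniform with a higher mean in the old
    group (atrophy).  Deterministic under ``spec.seed``.
    """
    rng = substream(spec.seed, "cohort")
    r = float(np.sqrt(spec.gaba_glx_r2))
    subjects: list[SubjectRecord] = []
    groups = [
        ("young", spec.n_young, spec.age_range_young,
         spec.gaba_mean_sd_young, spec.glx_mean_sd_young,
         spec.linewidth_mean_young, spec.linewidth_sd_young,
         spec.cbf_mean_young, (0.05, 0.18)),
        ("old", spec.n_old, spec.age_range_old,
         spec.gaba_mean_sd_old, spec.glx_mean_sd_old,
         spec.linewidth_mean_old, spec.linewidth_sd_old,
         spec.cbf_mean_old, (0.12, 0.25)),
    ]
    for (group, n, age_rng, (mg, sg), (mx, sx),
         lw_m, lw_s, cbf_m, csf_rng) in groups:
        if n == 0:
            continue
        ages = rng.uniform(*age_rng, size=n)
        cov = np.array([[sg**2, r * sg * sx], [r * sg * sx, sx**2]])
        met = rng.multivariate_normal([mg, mx], cov, size=n,
                                      method="cholesky")
        gaba = np.clip(met[:, 0], 0.05, None)
        glx = np.clip(met[:, 1], 0.05, None)
        f_csf = rng.uniform(*csf_rng, size=n)
        lw = np.clip(rng.normal(lw_m, lw_s, size=n), 3.0, None)
        cbf = np.clip(rng.normal(cbf_m, spec.cbf_sd, size=n), 15.0, None)
        for i in range(n):
            subjects.append(
                SubjectRecord(
                    subject_id=f"{group}-{i + 1:02d}",
                    group=group,
                    age=float(ages[i]),
                    true_gaba=float(gaba[i]),
                    true_glx=float(glx[i]),
                    f_csf=float(f_csf[i]),
                    linewidth=float(lw[i]),
                    baseline_cbf=float(cbf[i]),
                )
            )
    return subjects


# ---------------------------------------------------------------------------
# basis
# ---------------------------------------------------------------------------

def generate_basis(
    acq: AcquisitionSpec,
    lineshape_params: LineshapeParams | None = None,
    lines: dict[str, list[tuple[float, float]]] | None = None,
    amplitudes: dict[str, float] | None = None,
    window_pad_ppm: float = 0.5,
) -> BasisSet:
    """Parametric difference-spectrum basis set.

    Each metabolite signature is a sum of Lorentzian-Gaussian lines at
    fixed chemical shifts, scaled so the real part integrates over the
    multiplet window (line span padded by ``window_pad_ppm``) to its
    configured amplitude (default 1); signed signatures (inverted NAA)
    keep their sign, with the absolute integral normalised.
    """
    ls = lineshape_params or LineshapeParams()
    lines = lines if lines is not None else DEFAULT_DIFF_LINES
    amplitudes = amplitudes or {}
    t = time_axis(acq)
    ppm = ppm_axis(acq)
    asc = np.argsort(ppm)
    spectra = []
    names = list(lines)
    for name in names:
        fid = np.zeros(acq.n_points, dtype=complex)
        for line_ppm, weight in lines[name]:
            fid += weight * _lorentz_gauss_fid(
                t, line_ppm, acq, ls.lorentz_fwhm, ls.gauss_fwhm
            )
        spec = fid_to_spectrum(fid, acq)
        pos = [p for p, _ in lines[name]]
        lo, hi = min(pos) - window_pad_ppm, max(pos) + window_pad_ppm
        in_win = (ppm[asc] >= lo) & (ppm[asc] <= hi)
        integral = np.trapezoid(spec.real[asc][in_win], ppm[asc][in_win])
        if abs(integral) < 1e-12:
            raise ValueError(f"degenerate basis signature for {name}")
        spec = spec * (amplitudes.get(name, 1.0) / abs(integral))
        spectra.append(spec)
    return BasisSet(
        metabolite_names=names,
        basis_spectra=np.array(spectra),
        ppm_axis=ppm,
        acq=acq,
        lineshape=ls,
        lines=lines,
    )


# ---------------------------------------------------------------------------
# MEGA-PRESS transients
# ---------------------------------------------------------------------------

def _background_fid(
    t: np.ndarray,
    acq: AcquisitionSpec,
    background: BackgroundModel,
    age: float,
    rng: np.random.Generator,
) -> np.ndarray:
    fid = np.zeros(acq.n_points, dtype=complex)
    age_factor = 1.0 + background.age_slope * (age - 45.0)
    for ppm_c, fwhm_ppm, amp in background.humps:
        jitter = 1.0 + background.subject_jitter_sd * rng.standard_normal()
        gauss_hz = fwhm_ppm * acq.transmitter_freq
        # unit ppm-integral hump, so amp is in the basis amplitude units
        line = _unit_integral_line_fid(
            t, ppm_c, acq, 0.5, gauss_hz, pad_ppm=1.5 * fwhm_ppm
        )
        fid += amp * background.scale * age_factor * jitter * line
    return fid


def synthesize_megapress_fids(
    subject: SubjectRecord,
    basis: BasisSet,
    acq: AcquisitionSpec,
    drift_model: DriftModel | None = None,
    noise_sd: float = 100.0,
    seed: int = 0,
    background: BackgroundModel | None = BackgroundModel(),
    off_lines: dict[str, tuple[float, float]] | None = None,
    metabolite_amps: dict[str, float] | None = None,
    water_concentration: float = 1.0,
    n_water_transients: int = 8,
) -> tuple[TransientSeries, TransientSeries]:
    """Interleaved ON/OFF transients for one subject, plus a matching
    unsuppressed-water series (TR 10 s semantics).

    The OFF sub-spectrum carries the static singlets (Cr/Cho/NAA/mI); the
    ON sub-spectrum adds the edited difference signatures and the smooth
    background, so the noiseless drift-free DIFF equals the analytic basis
    combination exactly.  Subject linewidth is applied as a Gaussian
    broadening envelope on top of the basis Lorentzian; per-transient
    frequency/phase offsets follow ``drift_model``; complex white noise of
    per-component SD ``noise_sd`` is added to every FID sample.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if basis.acq.n_points != acq.n_points:
        raise ValueError("subject basis and acquisition disagree in n_points")
    rng = substream(seed, f"spectra:{subject.subject_id}")
    t = time_axis(acq)
    off_lines = off_lines if off_lines is not None else DEFAULT_OFF_LINES
    tissue = 1.0 - subject.f_csf

    if metabolite_amps is None:
        metabolite_amps = {
            "GABA": subject.true_gaba,
            "Glx": subject.true_glx,
            "NAA": 9.0,
        }

    # static OFF content (integral-normalised, like the basis signatures)
    off_fid = np.zeros(acq.n_points, dtype=complex)
    for ppm_c, amp in off_lines.values():
        off_fid += amp * tissue * _unit_integral_line_fid(
            t, ppm_c, acq, basis.lineshape.lorentz_fwhm,
            basis.lineshape.gauss_fwhm,
        )

    # edited difference content from the basis (time domain)
    diff_fid = np.zeros(acq.n_points, dtype=complex)
    for name in basis.metabolite_names:
        amp = metabolite_amps.get(name, 0.0) * tissue
        if amp == 0.0:
            continue
        spec = basis.spectrum(name)
        diff_fid += amp * (
            np.fft.ifft(np.fft.ifftshift(spec)) / acq.dwell_time
        )

    on_fid = off_fid + diff_fid
    if background is not None:
        on_fid = on_fid + tissue * _background_fid(
            t, acq, background, subject.age, rng
        )

    g_subj = gaussian_component_for_linewidth(
        subject.linewidth, basis.lineshape.lorentz_fwhm
    )
    env = _gauss_envelope(t, g_subj)
    on_fid = on_fid * env
    off_fid = off_fid * env

    n_tr = 2 * acq.n_transient_pairs
    labels = np.array(["ON", "OFF"] * acq.n_transient_pairs, dtype=object)
    if drift_model is not None:
        freq_off, phase_off = drift_model.offsets(n_tr, rng)
    else:
        freq_off = np.zeros(n_tr)
        phase_off = np.zeros(n_tr)

    fids = np.empty((n_tr, acq.n_points), dtype=complex)
    for i in range(n_tr):
        base = on_fid if labels[i] == "ON" else off_fid
        fid = base * np.exp(
            1j * (2.0 * np.pi * freq_off[i] * t + np.radians(phase_off[i]))
        )
        if noise_sd > 0:
            fid = fid + noise_sd * (
                rng.standard_normal(acq.n_points)
                + 1j * rng.standard_normal(acq.n_points)
            )
        fids[i] = fid
    series = TransientSeries(fids=fids, edit_labels=labels, acq=acq)

    # unsuppressed water reference: same geometry, long-TR semantics
    water_acq = acq.model_copy(update={"tr": 10.0})
    water_line = water_concentration * _unit_integral_line_fid(
        t, WATER_PPM, acq, basis.lineshape.lorentz_fwhm,
        basis.lineshape.gauss_fwhm,
    ) * env
    wfids = np.empty((n_water_transients, acq.n_points), dtype=complex)
    for i in range(n_water_transients):
        fid = water_line
        if noise_sd > 0:
            fid = fid + noise_sd * (
                rng.standard_normal(acq.n_points)
                + 1j * rng.standard_normal(acq.n_points)
            )
        wfids[i] = fid
    water = TransientSeries(
        fids=wfids,
        edit_labels=np.array(["OFF"] * n_water_transients, dtype=object),
        acq=water_acq,
    )
    return series, water


# ---------------------------------------------------------------------------
# BOLD
# ---------------------------------------------------------------------------

def default_affine(spacing_mm: float = 6.0) -> np.ndarray:
    """Analysis-grid affine: isotropic spacing with the y extent spanning
    the posterior-to-anterior range of the medial-frontal target region."""
    aff = np.diag([spacing_mm, spacing_mm, spacing_mm, 1.0])
    aff[:3, 3] = [-21.0, 12.0, 20.0]
    return aff


@dataclass
class BoldDataset:
    """One subject's synthetic task-fMRI record with stored ground truth."""

    runs: list[np.ndarray]          # each (X, Y, Z, T), % BOLD change
    events: pd.DataFrame            # run, onset, duration, trial_type
    cbf: np.ndarray                 # (X, Y, Z), mL/100g/min
    gm: np.ndarray                  # grey-matter fraction
    csf: np.ndarray                 # CSF fraction
    affine: np.ndarray
    design: BoldDesign
    truth: dict                     # hrf_taps, gain, neural_gain, stimulus


def _gamma_lobe(tt: np.ndarray, mode: float, sd: float) -> np.ndarray:
    """Gamma-family lobe parameterised by its mode (s) and SD (s),
    normalised to unit peak."""
    theta = (-mode + np.sqrt(mode**2 + 4.0 * sd**2)) / 2.0
    k = mode / theta + 1.0
    lobe = gamma_dist.pdf(tt, a=k, scale=theta)
    peak = gamma_dist.pdf(mode, a=k, scale=theta)
    return lobe / peak


def ground_truth_hrf_taps(
    subject: SubjectRecord,
    design: BoldDesign,
    coupling: dict[str, float],
) -> np.ndarray:
    """Biphasic ground-truth HRF at the native TR grid (13 taps).

    Difference of two gamma-family lobes: a positive early lobe whose
    latency/width shift with age and the GABA/Glx balance, and a negative
    late lobe (post-stimulus undershoot).  Units: % BOLD change per
    stimulus presentation.
    """
    tt = np.arange(design.n_lags) * design.tr
    mode1 = 8.0 + coupling.get("age_ttp", 0.0) * (subject.age - 45.0)
    fwhm1 = (
        9.0
        + coupling.get("age_fwhm", 0.0) * (subject.age - 45.0)
        + coupling.get("gaba_fwhm", 0.0) * (subject.true_gaba - 2.78)
        + coupling.get("glx_fwhm", 0.0) * (subject.true_glx - 12.5)
    )
    fwhm1 = max(fwhm1, 4.0)
    sd1 = fwhm1 / (2.0 * np.sqrt(2.0 * _LN2))
    amp = 1.0 * (
        1.0 + coupling.get("cbf_amp", 0.0) * (subject.baseline_cbf - 47.0)
    )
    pos = amp * _gamma_lobe(tt, mode1, sd1)
    neg = 0.45 * amp * _gamma_lobe(tt, 38.0, 5.0)
    return pos - neg


def _rest_lengths(design: BoldDesign, rng: np.random.Generator) -> np.ndarray:
    lo, hi = design.rest_jitter
    n_periods = design.n_blocks_per_run + 1
    target = design.n_measurements_per_run - \
        design.n_blocks_per_run * design.block_length
    lengths = rng.integers(lo, hi + 1, size=n_periods)
    while lengths.sum() > target:
        cand = np.flatnonzero(lengths > lo)
        lengths[rng.choice(cand)] -= 1
    while lengths.sum() < target:
        cand = np.flatnonzero(lengths < hi)
        lengths[rng.choice(cand)] += 1
    return lengths


def stimulus_indicator(
    design: BoldDesign, rng: np.random.Generator
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-TR task-stimulus indicator and its events table for one run."""
    rests = _rest_lengths(design, rng)
    s = np.zeros(design.n_measurements_per_run)
    rows = []
    t = 0
    for b in range(design.n_blocks_per_run):
        t += int(rests[b])
        for k in range(design.block_length):
            s[t] = 1.0
            rows.append(
                {"onset": t * design.tr, "duration": design.tr,
                 "trial_type": "word_gen", "block": b}
            )
            t += 1
    events = pd.DataFrame(rows)
    return s, events


def _smooth_field(
    shape: tuple[int, ...], rng: np.random.Generator, sigma_vox: float = 1.5
) -> np.ndarray:
    """Unit-variance smooth Gaussian random field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
    return (f - f.mean()) / f.std()


def activation_template(
    shape: tuple[int, int, int],
    center_frac: tuple[float, float, float] = (0.5, 0.65, 0.55),
    sigma_vox: float = 1.3,
) -> np.ndarray:
    """Fixed unit-peak Gaussian activation blob shared by all subjects —
    the consistent task-activation topography that group-level cluster
    inference is meant to detect."""
    grids = np.meshgrid(
        *[np.arange(n) for n in shape], indexing="ij"
    )
    centers = [f * (n - 1) for f, n in zip(center_frac, shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, centers))
    return np.exp(-d2 / (2.0 * sigma_vox**2))


def synthesize_bold_dataset(
    subject: SubjectRecord,
    design: BoldDesign,
    voxel_grid: tuple[int, int, int] = (8, 8, 8),
    noise_sd: float = 0.2,
    seed: int = 0,
    coupling: dict[str, float] | None = None,
    affine: np.ndarray | None = None,
    activation_amp: float = 0.5,
) -> BoldDataset:
    """Synthesize one subject's BOLD runs + events + CBF and tissue maps.

    Every voxel's time series is the stimulus train convolved with the
    subject's biphasic ground-truth HRF scaled by a voxel gain, plus white
    noise.  The voxel gain combines a fixed activation template shared by
    all subjects (what group-level cluster inference detects), a smooth
    subject-specific neural field, and a CBF-coupled component, so segment
    energetics correlate with baseline CBF through the configured
    coupling; all ground truth is stored for recovery tests.
    """
    if max(voxel_grid) > 16:
        raise ValueError("voxel_grid is meant for desk-scale grids (<= 16)")
    coupling = coupling if coupling is not None else {
        "age_ttp": 0.05, "age_fwhm": 0.04, "gaba_fwhm": -0.4,
        "glx_fwhm": 0.15, "cbf_amp": 0.012, "age_act": 0.012,
    }
    rng = substream(seed, f"bold:{subject.subject_id}")
    taps = ground_truth_hrf_taps(subject, design, coupling)

    cbf = subject.baseline_cbf + 6.0 * _smooth_field(voxel_grid, rng)
    cbf = np.clip(cbf, 5.0, None)
    gm = np.clip(0.65 + 0.10 * _smooth_field(voxel_grid, rng), 0.0, 1.0)
    csf = np.clip(
        subject.f_csf + 0.03 * _smooth_field(voxel_grid, rng), 0.0, 0.9
    )
    # activation weakens with age: group-level residualization keeps only
    # deviations from the pooled mean, so per-group cluster inference sees
    # exactly this differential component
    act = activation_amp * (
        1.0 - coupling.get("age_act", 0.0) * (subject.age - 45.0)
    )
    neural = (
        1.0
        + act * activation_template(voxel_grid)
        + 0.15 * _smooth_field(voxel_grid, rng)
    )
    gain = neural + coupling.get("cbf_amp", 0.0) * (cbf - 47.0)

    runs = []
    stim_all = []
    ev_frames = []
    for r in range(design.n_runs):
        s, ev = stimulus_indicator(design, rng)
        ev.insert(0, "run", r)
        ev_frames.append(ev)
        stim_all.append(s)
        clean = np.convolve(s, taps)[: len(s)]     # (T,)
        vol = gain[..., None] * clean[None, None, None, :]
        if noise_sd > 0:
            vol = vol + noise_sd * rng.standard_normal(vol.shape)
        runs.append(vol)
    events = pd.concat(ev_frames, ignore_index=True)

    return BoldDataset(
        runs=runs,
        events=events,
        cbf=cbf,
        gm=gm,
        csf=csf,
        affine=affine if affine is not None else default_affine(),
        design=design,
        truth={
            "hrf_taps": taps,
            "gain": gain,
            "neural_gain": neural,
            "stimulus": np.array(stim_all),
        },
    )
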