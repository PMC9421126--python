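"""Validated configuration types shared across the pipeline."""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field, model_validator


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible random substream derived from one master seed.

    Every source of randomness in the package draws from a substream so any
    single stage can be re-run in isolation with identical output.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


class AcquisitionSpec(BaseModel):
    """MEGA-PRESS acquisition geometry.

    Defaults follow a 3 T J-edited acquisition: 2000 Hz bandwidth
    (dwell 0.5 ms), 2048 complex points, ON/OFF editing at 1.9/7.5 ppm.
    """

    dwell_time: float = Field(default=5.0e-4, gt=0)           # seconds
    n_points: int = Field(default=2048, ge=64)
    transmitter_freq: float = Field(default=123.25, gt=0)     # MHz
    n_transient_pairs: int = Field(default=160, ge=1)
    edit_on_ppm: float = 1.9
    edit_off_ppm: float = 7.5
    tr: float = Field(default=2.0, gt=0)                      # seconds

    @property
    def spectral_width(self) -> float:
        """Spectral width in Hz (= 1/dwell_time)."""
        return 1.0 / self.dwell_time


class CohortSpec(BaseModel):
    """Study-condition cohort model: two age groups with the group GABA+/Glx
    distributions, correlated GABA-Glx, and age-dependent linewidth."""

    n_young: int = Field(default=14, ge=0)
    n_old: int = Field(default=14, ge=0)
    age_range_young: tuple[float, float] = (18.0, 34.0)
    age_range_old: tuple[float, float] = (60.0, 89.0)
    gaba_mean_sd_young: tuple[float, float] = (2.98, 0.43)
    gaba_mean_sd_old: tuple[float, float] = (2.58, 0.48)
    glx_mean_sd_young: tuple[float, float] = (14.11, 1.97)
    glx_mean_sd_old: tuple[float, float] = (10.89, 2.50)
    gaba_glx_r2: float = Field(default=0.48, ge=0, lt=1)
    linewidth_mean_young: float = Field(default=7.8, gt=0)    # Hz
    linewidth_mean_old: float = Field(default=10.0, gt=0)     # Hz
    linewidth_sd_young: float = Field(default=2.4, gt=0)
    linewidth_sd_old: float = Field(default=3.6, gt=0)
    cbf_mean_young: float = Field(default=52.0, gt=0)         # mL/100g/min
    cbf_mean_old: float = Field(default=42.0, gt=0)
    cbf_sd: float = Field(default=7.0, gt=0)
    # generator couplings: age->ttp (s/year), age->FWHM (s/year),
    # GABA->FWHM and Glx->FWHM (s per i.u.), CBF->amplitude gain
    # (fractional gain per mL/100g/min about the grand mean), and
    # age->activation (fractional template amplitude per year about 45).
    coupling_coeffs: dict[str, float] = Field(
        default_factory=lambda: {
            "age_ttp": 0.05,
            "age_fwhm": 0.04,
            "gaba_fwhm": -0.4,
            "glx_fwhm": 0.15,
            "cbf_amp": 0.012,
            "age_act": 0.012,
        }
    )
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        for name in ("gaba_mean_sd_young", "gaba_mean_sd_old",
                     "glx_mean_sd_young", "glx_mean_sd_old"):
            if getattr(self, name)[1] <= 0:
                raise ValueError(f"{name}: SD must be > 0")
        for name in ("age_range_young", "age_range_old"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: range must be increasing")
        ylo, yhi = self.age_range_young
        olo, ohi = self.age_range_old
        if max(ylo, olo) <= min(yhi, ohi):
            raise ValueError("age_range_young/age_range_old: ranges overlap")
        return self


@dataclass
class SubjectRecord:
    """Ground-truth per-subject covariates (the generator side of the
    regression models)."""

    subject_id: str
    group: str                  # "young" | "old"
    age: float                  # years
    true_gaba: float            # i.u.
    true_glx: float             # i.u.
    f_csf: float                # fraction [0, 1)
    linewidth: float            # Hz
    baseline_cbf: float         # mL/100g/min

    def __post_init__(self) -> None:
        if self.group not in ("young", "old"):
            raise ValueError(f"group must be young/old, got {self.group!r}")
        if not 0.0 <= self.f_csf < 1.0:
            raise ValueError("f_csf must be in [0, 1)")


class BoldDesign(BaseModel):
    """Sparse-sampled language-task BOLD design: 3 runs of 78 measurements
    at TR 4 s, six 8-stimulus blocks per run flanked by jittered 3-5 TR
    rest periods, and a 48-s FIR response window."""

    tr: float = Field(default=4.0, gt=0)
    n_measurements_per_run: int = Field(default=78, ge=1)
    n_runs: int = Field(default=3, ge=1)
    n_blocks_per_run: int = Field(default=6, ge=1)
    block_length: int = Field(default=8, ge=1)   # stimuli (one per TR)
    rest_jitter: tuple[int, int] = (3, 5)
    hrf_length: float = 48.0                     # seconds

    @model_validator(mode="after")
    def _check(self):
        if abs(self.block_length * self.tr - 32.0) > 1e-9:
            raise ValueError("block_length * tr must equal 32 s")
        if abs(self.hrf_length - 48.0) > 1e-9:
            raise ValueError("hrf_length must be 48 s")
        lo, hi = self.rest_jitter
        if not 1 <= lo <= hi:
            raise ValueError("rest_jitter must be an increasing positive range")
        n_task = self.n_blocks_per_run * self.block_length
        n_rest = self.n_measurements_per_run - n_task
        n_periods = self.n_blocks_per_run + 1
        if not n_periods * lo <= n_rest <= n_periods * hi:
            raise ValueError(
                "block arithmetic violated: rest TRs "
                f"({n_rest}) cannot be split into {n_periods} periods of "
                f"{lo}-{hi} TRs"
            )
        return self

    @property
    def n_lags(self) -> int:
        """FIR lags spanning [0, hrf_length] at TR resolution (13 by default)."""
        return int(round(self.hrf_length / self.tr)) + 1


@dataclass
class BaselineConfig:
    """Spline-baseline stiffness for linear-combination fitting.

    ``dkntmn`` is the knot spacing in ppm (smaller = more flexible);
    ``None`` disables the baseline entirely (the no-baseline control).
    """

    dkntmn: float | None = 0.6
    fit_window: tuple[float, float] = (1.9, 4.2)

    def __post_init__(self) -> None:
        if self.dkntmn is not None and self.dkntmn <= 0:
            raise ValueError("dkntmn must be > 0 when present")
        if not self.fit_window[0] < self.fit_window[1]:
            raise ValueError("fit_window must be increasing")

    @property
    def label(self) -> str:
        return "noBline" if self.dkntmn is None else f"{self.dkntmn:g}"


@dataclass
class SegmentScheme:
    """Partition of the 48-s response into three 16-s segments:
    early task (first 4 words), late task (last 4 words), and the
    post-stimulus undershoot period."""

    seg1: tuple[float, float] = (0.0, 16.0)
    seg2: tuple[float, float] = (16.0, 32.0)
    seg3: tuple[float, float] = (32.0, 48.0)

    def __post_init__(self) -> None:
        segs = [self.seg1, self.seg2, self.seg3]
        if segs[0][0] != 0.0 or segs[-1][1] != 48.0:
            raise ValueError("segments must span [0, 48] s")
        for a, b in zip(segs[:-1], segs[1:]):
            if a[1] != b[0]:
                raise ValueError("segments must partition [0, 48] s")

    @property
    def bounds(self) -> list[tuple[float, float]]:
        return [self.seg1, self.seg2, self.seg3]


@dataclass
class DriftModel:
    """Scan-time field-drift model for transient synthesis: a frequency
    random walk plus optional single-transient step events (motion), and a
    slow phase random walk."""

    rw_sd_hz: float = 0.25           # per-transient random-walk increment
    linear_hz_per_transient: float = 0.0
    step_events: list[tuple[int, float]] = field(default_factory=list)
    phase_rw_sd_deg: float = 0.5

    def offsets(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        freq = np.cumsum(rng.normal(0.0, self.rw_sd_hz, size=n)) if self.rw_sd_hz > 0 \
            else np.zeros(n)
        freq = freq + self.linear_hz_per_transient * np.arange(n)
        for idx, hz in self.step_events:
            if 0 <= idx < n:
                freq[idx] += hz
        phase = np.cumsum(rng.normal(0.0, self.phase_rw_sd_deg, size=n)) \
            if self.phase_rw_sd_deg > 0 else np.zeros(n)
        return freq, phase
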