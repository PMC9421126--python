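# Methods

This note records the models the package implements, the generator's
assumptions, the numerical choices, and what the passing tests do and do
not establish about real data.

## Spectral model and conventions

A free induction decay (FID) is sampled at dwell time 0.5 ms over 2048
complex points (2000 Hz bandwidth at 3 T, transmitter 123.25 MHz).  The
package-wide ppm convention places water at 4.7 ppm at the center of the
axis, with ppm decreasing as the frequency index increases; a resonance at
chemical shift δ therefore contributes `exp(2πi (4.7 − δ) f₀ t)` with f₀
in MHz.  `fid_to_spectrum` is the shifted DFT scaled by the dwell time, so
peak integrals approximate the continuous Fourier transform and the
transform is exactly invertible.

**Basis signatures.**  The difference-spectrum basis is parametric:
Lorentzian–Gaussian multiplets at literature chemical shifts — GABA+ as a
broad pseudo-triplet at 2.93/3.01/3.09 ppm (the composite includes
co-edited macromolecules and is wide in practice), Glx as a triplet at
3.68/3.76/3.84 ppm, and NAA as the inverted singlet at 2.01 ppm.  Each
signature is normalised so its absorption-mode real part integrates to one
over its multiplet window (line span ± 0.5 ppm) at the intrinsic lineshape
(Lorentzian 2 Hz by default); fitted amplitudes are therefore in integral
units commensurate across metabolites, static singlets, background, and
water.  Density-matrix simulation is deliberately out of scope: the
quantification pipeline, not spin physics, is what this package exercises.

**Subject linewidth.**  A subject's total linewidth (drawn
N(7.8, 2.4²) Hz young, N(10.0, 3.6²) Hz old, truncated at 3 Hz) is
realised by adding the Gaussian broadening that brings the intrinsic
Lorentzian to the target Voigt width (standard Voigt-width approximation,
inverted in `gaussian_component_for_linewidth`).

**Drift.**  Per-transient frequency offsets follow a random walk
(0.25 Hz/step) plus optional single-transient step events (motion); phase
follows a 0.5°/step walk.  Step events are transient-local so the 10 Hz
rejection rule removes exactly the stepped transients.

**Unmodeled background.**  The ON sub-spectrum carries four smooth humps
(2.20, 2.90, 3.50, 3.90 ppm; FWHM ≈ 0.6 ppm; integrals 0.65/0.50/−0.40/
0.45 with an age slope of 0.4%/year and 8% subject jitter).  The
functional form is a free generator choice — the macromolecule model
underlying real edited spectra is not observable here — and was fixed once
at a characteristic scale of ~0.6 ppm: rigid baselines (≥ 0.8 ppm
spacing) leave part of it in the residuals, flexible 0.2 ppm baselines
follow it and also absorb metabolite signal.  This is precisely the regime
in which a knot-spacing sweep is informative, and the qualitative optimum
the pipeline reproduces (see "Baseline sweep") is conditional on it.

**Water reference.**  A matching unsuppressed-water series (TR 10 s
semantics, 8 transients) carries a unit-integral water line scaled by the
configured water concentration; the water amplitude used for scaling is
the broadening-invariant real-part integral over 4.2–5.2 ppm.

## Preprocessing

1. **Registration** estimates each transient's (Δf, Δφ) by least-squares
   matching to a per-edit-label reference in the time domain, restricted
   to the first 512 FID samples (the early FID carries nearly all signal;
   this is purely a cost optimisation).  The initial iterate comes from
   the amplitude-weighted phase slope of `fid · conj(ref)`, which keeps
   offsets of tens of Hz out of local minima.  The reference is the
   medoid of the first eight transients of that label (robust to early
   instability; configurable).  The 10 Hz criterion is applied to the
   per-transient offset relative to this reference (the cumulative-vs-
   instantaneous reading is not decidable from the procedure's
   description; this choice is documented here once).
2. **Rejection** uses strict inequality (> 10 Hz) and drops ON/OFF pairs
   jointly, preserving subtraction pairing.
3. **Alignment at 3 ppm** minimises the squared ON–OFF mismatch in a
   0.4 ppm window by a bounded scalar search over ± 5 Hz, applying
   sub-bin shifts as Fourier phase ramps (no interpolation artifacts).
   A window without a usable peak warns and applies zero shift.
4. **Averaging/subtraction** forms DIFF = mean(ON) − mean(OFF) with
   kept/rejected provenance counts.

Linewidth QC measures the FWHM of the absorption-mode (real-part) peak
nearest 3 ppm after 4× zero-filling, with half-height crossings located
by linear interpolation; pass means < 18 Hz.  The real part (not the
magnitude) is used so a Lorentzian from `exp(−t/T2*)` reads 1/(πT2*).

No apodization is applied before fitting: the fit model carries the
lineshape, and apodizing would double-count broadening.

## Linear-combination fit

Over the fit window (default 1.9–4.2 ppm, spanning GABA+ 3.0, Glx 3.75
and the inverted NAA 2.0) the real part of DIFF is modeled as metabolite
columns plus cubic B-spline baseline columns.  The baseline's only
stiffness control is its uniform interior knot spacing (`dkntmn`, ppm);
the number of intervals is `floor(window/dkntmn)` (the spacing acts as a
minimum, so 0.8 and 1.0 ppm coincide on the default 2.3 ppm window), the
clamped cubic basis has n+3 columns and forms a partition of unity, and
no penalty is applied within a knot set.  Two global nonlinear parameters
— frequency shift (± 5 Hz) and Gaussian broadening (0–10 Hz) — are found
by Nelder–Mead around the closed-form inner least squares (a small,
smooth 2-parameter landscape).  Amplitudes are unconstrained in sign
(difference spectra legitimately contain negative lobes); expected-sign
violations only warn.

* **CRLB** per metabolite: 100 · sqrt(diag(σ̂²(XᵀX)⁻¹)) / |amplitude|
  with σ̂² from the residual variance; zero amplitude reports ∞.
* **SNR** per metabolite: max |fitted metabolite curve| over the window
  divided by twice the residual rms (the baseline curve subtracts out of
  the metabolite-plus-baseline fit).  Scale-invariant by construction.
* **Quantification**: concentration = amplitude / water amplitude ×
  scaling constant (1.0 — generator units are already institutional
  units; absolute molarity is out of scope), then divided by (1 − f_CSF)
  (α = 1: metabolites reside in tissue, water fills the voxel).

**Baseline sweep.**  Every subject is fitted under
{0.2, 0.4, 0.6, 0.8, 1.0 ppm, none}.  Each spline spacing's GABA+ SNR is
compared with the no-baseline control by a paired t-test; each spacing's
CRLB is compared with the pooled remaining configurations by a two-sample
t-test (the original comparison procedure names no exact test; this
one-vs-pooled-rest choice is configurable).  Spacings with significantly
higher SNR than the control form the candidate set and the candidate with
the lowest mean CRLB is recommended.  On cohorts from this generator the
recommendation is 0.6 ppm in ≥ 80% of seeded replicates, 0.2 ppm carries
the highest CRLB, and the control the lowest SNR — the directions the
sweep exists to detect.  GABA is the headline metabolite for the pairwise
SNR tests (whether the original comparisons pooled both metabolites is
not recoverable; per-metabolite results are reported for both).

## BOLD generation and hemodynamics

The task design is 3 runs × 78 measurements at TR 4 s: six 8-stimulus
blocks (32 s) flanked by jittered 3–5 TR rest periods (jitter makes the
FIR design identifiable).  The ground-truth HRF is a difference of two
gamma-family lobes parameterised by mode and SD: a positive early lobe
(mode 8 s + 0.05 s/year of age; FWHM 9 s + couplings from age and the
GABA/Glx balance) and a 0.45-relative negative late lobe at 38 s (the
post-stimulus undershoot).  Amplitude couples to baseline CBF
(1.2%/mL/100g/min about 47).  Voxel gains combine a fixed activation
template (a Gaussian blob, unit peak, amplitude 0.5 declining 1.2%/year
of age — younger subjects activate more strongly), a smooth
subject-specific field (SD 0.15), and the CBF-coupled component.  CBF,
grey-matter and CSF maps are smooth fields around the subject's values.

* **Deconvolution**: 13 FIR taps (0–48 s) by least squares over
  concatenated runs with per-run intercepts; exact on noiseless data.
* **Interpolation**: not-a-knot cubic spline to 0.5 s (97 samples),
  reproducing native points exactly.
* **Peak metrics**: the largest-|value| local maximum of |HRF| within
  the 0–32 s stimulus window (earliest wins ties, for determinism), sign
  restored; FWHM at half the peak's absolute height relative to zero,
  between the nearest half-crossings around the peak (half-prominence is
  available by flag; the half-height-from-zero reading is the default).
* **Segment energetics**: trapezoidal AUC over [0,16], [16,32],
  [32,48] s — segments share boundary samples so they sum exactly to the
  full-curve AUC (1-indexed native-sample phrasing of the second-segment
  start maps to the 16 s boundary on the continuous grid; a 17 s start is
  supported by passing a custom scheme).  Z-transform is across in-mask
  voxels within subject and segment (`z_across_subjects` provides the
  across-subjects scope).
* **Neuro-sensitization**: per voxel, OLS of Z(AUC) on baseline CBF
  across subjects pooled over groups (per-group via the ``groups``
  argument); the output is the residual (intercept removed), exactly
  orthogonal to the CBF regressor.
  Because the pooled per-voxel mean is removed, activation shared by all
  subjects cannot survive a one-sample test of the residuals — what
  survives is group-differential structure.  Accordingly, cluster-based
  parcellation runs on the per-group *unsensitized* Z(AUC) maps, while
  the neuro-sensitized values are the regression responses.
* **Parcellation**: one-sample t vs zero, two-sided voxel p ≤ 0.01,
  face-adjacency clusters, minimum extent calibrated from a sign-flip
  permutation null of the maximum cluster size so the familywise rate of
  any surviving noise cluster is ≤ 5% (exact under a symmetric null; no
  parametric smoothness estimate).  Surviving clusters are labelled by
  centroid y: anterior > 40 mm, posterior < 22 mm, mid between.

## Linking statistics

The seven-model OLS suite builds interaction products from mean-centered
main effects (reduces collinearity and matches standard least-squares
practice for cross terms; toggleable) and ranks models by adjusted R².
Significance vocabulary: significant at p ≤ 0.01, trending at
0.01 < p < 0.05.  Group differences use the pooled-variance t and
pooled-SD Cohen's d (these reproduce the printed cohort statistics from
the group summaries); Welch's t is available by flag.  The power-based
sample size solves the noncentral-t equation for the smallest per-group n
with two-sided power ≥ 0.80 at α = 0.05 — at the GABA+ effect size
d = 0.88 this gives n = 22 *per group*, which is the reading the
noncentral-t arithmetic supports for the reported minimum.

## Seeds and determinism

All randomness flows from one master seed through named substreams
(cohort, per-subject spectra, per-subject BOLD, parcellation null), so
any single stage reruns identically in isolation and the full pipeline is
bit-identical under a fixed seed.

## Problem sizes

The shipped analysis drivers use 14 + 14 subjects, 64 transient pairs per
subject, an 8³ voxel grid, and 1000-permutation nulls; the test suite
uses smaller cohorts (3 + 3 subjects, 16–48 pairs, 5³–12³ grids) chosen
as the smallest sizes at which each property is decidable.  Cluster-FWE
calibration is checked over 500 pure-noise cohorts at 8³ and 120 at 12³.

## What the synthetic data does and does not establish

The generator reproduces the statistical structure the analysis assumes:
group-separated, correlated GABA/Glx; age-dependent linewidth and CSF
fraction; drift and a smooth background; a biphasic HRF with age/
neurochemistry couplings; CBF-coupled energetics with stored ground
truth.  It does not emulate eddy currents, chemical-shift displacement,
residual water, motion beyond frequency steps, physiological noise
spectra, spatial autocorrelation of BOLD noise, or macromolecule
chemistry — so passing tests certify the estimators and their
calibration under the stated model, not performance on scanner data.
Real-data headline numbers that depend on the unreleased cohort (the
per-spacing concentrations, the regression tables, cluster coordinates)
are covered only as direction-preserving properties.

## Known limitations

* The background model is a design choice; sweeping its scale moves the
  SNR/CRLB margins between baseline configurations (the directions are
  robust across the pilot range, the magnitudes are not meaningful).
* CRLB percentages here are lower than typical in vivo GABA+ values
  because the synthetic basis is exactly correct; only CRLB *ratios*
  between configurations carry information.
* The no-baseline control's CRLB ties the optimum when the background is
  small relative to noise; its SNR deficit is the stable signature.
* `dkntmn` 0.8 and 1.0 coincide on the default window (two intervals
  each); they are kept as separate sweep entries for interface fidelity.
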