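# megabold

A synthetic-cohort pipeline linking baseline neurochemistry measured by
J-edited magnetic resonance spectroscopy (MRS) — GABA+ and the
glutamate–glutamine complex (Glx) — to language task-fMRI BOLD
hemodynamics in a young-vs-old cohort model.

The package is written for MRS/fMRI methods researchers who want a fully
seeded, ground-truth-controlled testbed for the multimodal analysis chain:

1. **Synthetic cohort** (`megabold.synthetic`) — two age groups
   (14 young, 18–34 y; 14 old, 60–89 y) with GABA+ drawn from
   2.98 ± 0.43 vs 2.58 ± 0.48 i.u. and Glx from 14.11 ± 1.97 vs
   10.89 ± 2.50 i.u. (GABA–Glx R² = 0.48), age-dependent linewidth,
   CSF fraction, baseline cerebral blood flow (CBF), MEGA-PRESS
   transients with drift and an unmodeled smooth background, and
   sparse-sampled BOLD runs built from a biphasic ground-truth HRF.
2. **Spectral preprocessing** (`megabold.mrs_prep`) — time-domain
   spectral registration of frequency/phase drift, rejection of
   transients drifting > 10 Hz (pairs dropped jointly), sub-bin ON/OFF
   alignment at the 3 ppm creatine resonance, averaging/subtraction into
   the difference (DIFF) spectrum, and creatine-linewidth QC (< 18 Hz).
3. **Linear-combination fitting** (`megabold.lc_fit`) — metabolite
   amplitudes plus a cubic B-spline baseline whose stiffness is set by
   its knot spacing `dkntmn` ∈ {0.2, 0.4, 0.6, 0.8, 1.0 ppm, none};
   Cramér–Rao lower bounds (CRLB); the metabolite signal-to-noise ratio

   ```
   SNR_met = max |Fit_met − Fit_baseline| / (2 · rms(residuals))
   ```

   water scaling and CSF correction (α = 1: divide by 1 − f_CSF); and
   the cohort-level sweep that compares each spacing's SNR against the
   no-baseline control (paired t) and its CRLB against the pooled rest,
   recommending a spacing.
4. **Hemodynamics** (`megabold.hemodynamics`) — 48-s HRF by 13-tap FIR
   deconvolution at TR 4 s, cubic-spline interpolation to 0.5 s, signed
   amplitude / time-to-peak / FWHM of the dominant biphasic peak,
   segment-wise Z(AUC) energetics over 0–16 / 16–32 / 32–48 s,
   neuro-sensitization (voxel-wise residualization of Z(AUC) against
   baseline CBF across subjects), and one-sample cluster inference with
   sign-flip permutation familywise-error control, labelling clusters
   anterior (y > 40 mm) / mid / posterior (y < 22 mm).
5. **Linking statistics** (`megabold.stats_link`) — the fixed suite of
   seven OLS models for each BOLD response `B`:

   ```
   B = A + B·Glx + e                       (Glx-only)
   B = A + B·GABA + e                      (GABA-only)
   B = A + B·Glx + C·GABA + D·GABA·Glx + e (GABA-by-Glx)
   B = A + B·Age + e                       (Age-only)
   ... two-way Age models, and the full three-way model
   ```

   ranked by adjusted R², plus pooled two-sample t and Cohen's d,
   noncentral-t power-based sample size, Bonferroni correction, and the
   R²→F identity F = (R²/p) / ((1 − R²)/(n − p − 1)).

`megabold.workflow.run_pipeline` chains all stages under one master seed;
`analysis/01…05_*.py` are narrative drivers that write their tables under
`results/`.

## Worked example

```sh
cd analysis
python 01_simulate_cohort.py
python 02_preprocess_spectra.py
python 03_baseline_sweep.py
```

prints (seeded run):

```
baseline sweep (mean GABA SNR / mean GABA CRLB%):
  dkntmn 0.2     : SNR   9.1  CRLB  4.16%
  dkntmn 0.4     : SNR   8.4  CRLB  2.71%
  dkntmn 0.6     : SNR   8.1  CRLB  2.42% <- recommended
  dkntmn 0.8     : SNR   7.8  CRLB  2.59%
  dkntmn 1       : SNR   7.8  CRLB  2.59%
  dkntmn noBline : SNR   6.0  CRLB  2.42%
  old  : GABA+ 2.52+/-0.45  Glx 10.17+/-2.60 i.u. (dkntmn 0.6)
  young: GABA+ 3.19+/-0.57  Glx 14.53+/-3.00 i.u. (dkntmn 0.6)
```

Every spline baseline improves the metabolite SNR over the no-baseline
control; the very flexible 0.2 ppm spacing inflates the CRLB (it absorbs
metabolite signal), and the moderate 0.6 ppm spacing minimises it — so
0.6 is recommended, and the quantified GABA+/Glx group means land on the
generating distributions.  `04_hemodynamics.py` then reports the HRF
metrics (older subjects: later, wider peaks) and the surviving clusters,
and `05_link_statistics.py` prints the group t/d statistics and the
best-fitting regression model per HRF metric.

For the power utility alone:

```sh
megabold stats --d 0.88
# per-group n = 22
```

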