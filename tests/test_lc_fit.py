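"""Linear-combination fitting tests: spline baseline construction, exact
and perturbed amplitude recovery, CRLB behaviour, metabolite SNR, water
scaling and CSF correction, and the cohort-level baseline sweep."""

import numpy as np
import pytest

from megabold import lc_fit, mrs_prep, synthetic
from megabold.lc_fit import (
    FitResult,
    build_spline_baseline,
    compute_crlb,
    fit_linear_combination,
    metabolite_snr,
    quantify,
    sweep_and_select,
    water_amplitude,
)
from megabold.mrs_prep import DiffSpectrum
from megabold.types import AcquisitionSpec, BaselineConfig, CohortSpec


def construct_diff(basis, acq, amps, background=None, noise_sd=0.0, seed=0):
    """Difference spectrum assembled directly from basis signatures plus an
    optional additive background array, at spectrum-level noise."""
    rng = np.random.default_rng(seed)
    values = np.zeros(acq.n_points, dtype=complex)
    for name, amp in amps.items():
        values += amp * basis.spectrum(name)
    if background is not None:
        values = values + background
    if noise_sd:
        values = values + noise_sd * (
            rng.standard_normal(acq.n_points)
            + 1j * rng.standard_normal(acq.n_points)
        )
    return DiffSpectrum(
        values=values, ppm_axis=basis.ppm_axis, n_kept=1, acq=acq
    )


def smooth_background(basis, acq, scale=1.0):
    """A background smooth at the ~1 ppm scale, fully representable by a
    moderate (0.6 ppm) knot spacing."""
    ppm = basis.ppm_axis
    bg = np.zeros(acq.n_points, dtype=complex)
    for c, w, a in [(2.3, 0.9, 1.2), (3.1, 1.0, 0.9), (3.9, 1.1, -0.7)]:
        bg += scale * a * np.exp(-0.5 * ((ppm - c) / (w / 2.355)) ** 2)
    return bg


class TestSplineBaseline:
    def test_column_count(self):
        cfg = BaselineConfig(dkntmn=0.6, fit_window=(1.8, 4.2))
        x = np.linspace(1.8, 4.2, 200)
        cols, names = build_spline_baseline(cfg, x)
        assert cols.shape == (200, 7)       # 4 intervals -> 7 columns
        assert len(names) == 7

    def test_none_gives_zero_columns(self):
        cols, names = build_spline_baseline(
            BaselineConfig(dkntmn=None), np.linspace(1.9, 4.2, 50)
        )
        assert cols.shape == (50, 0) and names == []

    def test_partition_of_unity(self):
        for spacing in (0.2, 0.6, 1.0):
            cfg = BaselineConfig(dkntmn=spacing)
            x = np.linspace(1.9, 4.2, 300)
            cols, _ = build_spline_baseline(cfg, x)
            assert np.allclose(cols.sum(axis=1), 1.0, atol=1e-12)

    def test_spacing_wider_than_window_warns(self):
        cfg = BaselineConfig(dkntmn=5.0)
        with pytest.warns(UserWarning):
            cols, _ = build_spline_baseline(cfg, np.linspace(1.9, 4.2, 50))
        assert cols.shape[1] == 4


class TestFit:
    def test_exact_recovery_noiseless(self, acq, basis):
        """2 x GABA + 1 x Glx with no baseline, no shift/broadening ->
        amplitudes recovered within 1e-8."""
        diff = construct_diff(basis, acq, {"GABA": 2.0, "Glx": 1.0})
        fit = fit_linear_combination(
            diff, basis, BaselineConfig(dkntmn=None), nonlinear=False
        )
        assert abs(fit.concentrations["GABA"] - 2.0) < 1e-8
        assert abs(fit.concentrations["Glx"] - 1.0) < 1e-8
        assert abs(fit.concentrations["NAA"]) < 1e-8

    def test_recovery_with_background(self, acq, basis):
        """A smooth additive background absorbed by a 0.6-ppm baseline
        leaves amplitudes within 5% of truth."""
        bg = smooth_background(basis, acq)
        diff = construct_diff(
            basis, acq, {"GABA": 2.0, "Glx": 8.0, "NAA": 9.0},
            background=bg,
        )
        fit = fit_linear_combination(
            diff, basis, BaselineConfig(dkntmn=0.6), nonlinear=False
        )
        assert abs(fit.concentrations["GABA"] - 2.0) < 0.10
        assert abs(fit.concentrations["Glx"] - 8.0) < 0.40

    def test_overfit_direction_02_vs_06(self, acq, basis):
        """dkntmn 0.2 removes signal attributes: its mean |GABA error| is
        at least that of 0.6 over 50 noisy replicates."""
        bg = smooth_background(basis, acq)
        errs = {0.2: [], 0.6: []}
        for seed in range(50):
            diff = construct_diff(
                basis, acq, {"GABA": 2.8, "Glx": 12.0, "NAA": 9.0},
                background=bg, noise_sd=0.25, seed=seed,
            )
            for k in errs:
                fit = fit_linear_combination(
                    diff, basis, BaselineConfig(dkntmn=k), nonlinear=False
                )
                errs[k].append(abs(fit.concentrations["GABA"] - 2.8))
        assert np.mean(errs[0.2]) >= np.mean(errs[0.6])

    def test_nested_model_rss(self, acq, basis):
        """Refining the knot set by subdivision (0.6 -> 0.3) never
        increases the residual sum of squares."""
        bg = smooth_background(basis, acq)
        diff = construct_diff(
            basis, acq, {"GABA": 2.0, "Glx": 8.0}, background=bg,
            noise_sd=0.1, seed=1,
        )
        rss = {}
        for k in (0.6, 0.3):
            fit = fit_linear_combination(
                diff, basis, BaselineConfig(dkntmn=k), nonlinear=False
            )
            rss[k] = float(fit.residuals @ fit.residuals)
        assert rss[0.3] <= rss[0.6] + 1e-12

    def test_rank_deficient_design_names_columns(self, acq, basis):
        dup = synthetic.BasisSet(
            metabolite_names=["GABA", "GABA2"],
            basis_spectra=np.array(
                [basis.spectrum("GABA"), basis.spectrum("GABA")]
            ),
            ppm_axis=basis.ppm_axis,
            acq=acq,
            lineshape=basis.lineshape,
            lines={"GABA": basis.lines["GABA"],
                   "GABA2": basis.lines["GABA"]},
        )
        diff = construct_diff(basis, acq, {"GABA": 1.0})
        with pytest.raises(ValueError, match="collinear"):
            fit_linear_combination(
                diff, dup, BaselineConfig(dkntmn=None), nonlinear=False
            )

    def test_shift_and_broadening_recovered(self, acq, basis):
        """The outer search finds an imposed global shift/broadening."""
        t = mrs_prep.time_axis(acq)
        values = np.zeros(acq.n_points, dtype=complex)
        for name, amp in (("GABA", 2.5), ("Glx", 10.0)):
            fid = np.fft.ifft(
                np.fft.ifftshift(basis.spectrum(name))
            ) / acq.dwell_time
            fid = fid * np.exp(2j * np.pi * 1.2 * t) * np.exp(
                -((np.pi * 4.0 * t) ** 2) / (4 * np.log(2))
            )
            values += amp * mrs_prep.fid_to_spectrum(fid, acq)
        diff = DiffSpectrum(values=values, ppm_axis=basis.ppm_axis,
                            acq=acq)
        fit = fit_linear_combination(diff, basis,
                                     BaselineConfig(dkntmn=None))
        assert abs(fit.nonlinear_params["freq_shift_hz"] - 1.2) < 0.1
        assert abs(fit.nonlinear_params["gauss_broadening_hz"] - 4.0) < 0.3
        assert abs(fit.concentrations["GABA"] - 2.5) < 0.02


class TestCrlb:
    def test_noiseless_limit(self, acq, basis):
        diff = construct_diff(basis, acq, {"GABA": 2.0, "Glx": 8.0})
        fit = fit_linear_combination(
            diff, basis, BaselineConfig(dkntmn=None), nonlinear=False
        )
        crlb = compute_crlb(fit)
        assert crlb["GABA"] < 1e-6

    def test_scales_with_noise(self, acq, basis):
        """Doubling the noise SD doubles the CRLB%% on average (ratio
        within [1.8, 2.2] over 100 replicates)."""
        ratios = []
        for seed in range(100):
            vals = {}
            for sd in (0.1, 0.2):
                diff = construct_diff(
                    basis, acq, {"GABA": 2.8, "Glx": 12.0, "NAA": 9.0},
                    noise_sd=sd, seed=seed,
                )
                fit = fit_linear_combination(
                    diff, basis, BaselineConfig(dkntmn=0.6),
                    nonlinear=False,
                )
                vals[sd] = compute_crlb(fit)["GABA"]
            ratios.append(vals[0.2] / vals[0.1])
        assert 1.8 <= np.mean(ratios) <= 2.2

    def test_zero_amplitude_reports_infinite(self, acq, basis):
        diff = construct_diff(basis, acq, {"GABA": 2.0}, noise_sd=0.05,
                              seed=0)
        fit = fit_linear_combination(
            diff, basis, BaselineConfig(dkntmn=None), nonlinear=False
        )
        fit.concentrations["Glx"] = 0.0
        crlb = compute_crlb(fit)
        assert np.isinf(crlb["Glx"])

    def test_estimator_sd_matches_crlb(self, acq, basis):
        """Empirical amplitude SD matches the CRLB prediction within 20%
        at moderate SNR."""
        amps, preds = [], []
        for seed in range(120):
            diff = construct_diff(
                basis, acq, {"GABA": 2.8, "Glx": 12.0, "NAA": 9.0},
                noise_sd=0.2, seed=seed,
            )
            fit = fit_linear_combination(
                diff, basis, BaselineConfig(dkntmn=None), nonlinear=False
            )
            amps.append(fit.concentrations["GABA"])
            crlb = compute_crlb(fit)
            preds.append(
                crlb["GABA"] / 100.0 * abs(fit.concentrations["GABA"])
            )
        emp = np.std(amps, ddof=1)
        assert abs(emp - np.mean(preds)) < 0.20 * np.mean(preds)


def handmade_fit(curve_max=10.0, rms=1.0, n=64):
    """Minimal FitResult with a known metabolite curve and residual rms."""
    res = np.full(n, rms)
    curve = np.zeros(n)
    curve[n // 2] = curve_max
    return FitResult(
        concentrations={"GABA": 1.0},
        baseline_curve=np.zeros(n),
        residuals=res,
        crlb_percent={},
        snr={},
        nonlinear_params={},
        config=BaselineConfig(dkntmn=None),
        metabolite_curves={"GABA": curve},
    )


class TestSnr:
    def test_arithmetic(self):
        """max|fit - baseline| = 10 with rms residual 1 gives SNR 5."""
        assert metabolite_snr(handmade_fit())["GABA"] == pytest.approx(5.0)

    def test_scale_invariance(self):
        a = metabolite_snr(handmade_fit(10.0, 1.0))["GABA"]
        b = metabolite_snr(handmade_fit(70.0, 7.0))["GABA"]
        assert a == pytest.approx(b)

    def test_zero_rms_raises(self):
        with pytest.raises(ValueError):
            metabolite_snr(handmade_fit(rms=0.0))

    def test_decreases_with_noise(self, acq, basis):
        """SNR is strictly decreasing in added white-noise SD on a fixed
        signal (Monte-Carlo average over seeds)."""
        means = []
        for sd in (0.1, 0.2, 0.4):
            vals = []
            for seed in range(30):
                diff = construct_diff(
                    basis, acq, {"GABA": 2.8, "Glx": 12.0},
                    noise_sd=sd, seed=seed,
                )
                fit = fit_linear_combination(
                    diff, basis, BaselineConfig(dkntmn=None),
                    nonlinear=False,
                )
                vals.append(metabolite_snr(fit)["GABA"])
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]


class TestQuantify:
    def test_csf_zero_identity(self):
        fit = handmade_fit()
        q = quantify(fit, 1.0, f_csf=0.0)
        assert q.gaba_h2o == pytest.approx(fit.concentrations["GABA"])

    def test_csf_correction_arithmetic(self):
        fit = handmade_fit()
        fit.concentrations = {"GABA": 2.0, "Glx": 4.0}
        q = quantify(fit, 1.0, f_csf=0.2)
        assert q.gaba_h2o == pytest.approx(2.5)      # 2.0 / (1 - 0.2)
        assert q.uncorrected["GABA"] == pytest.approx(2.0)

    def test_water_scaling_ratio(self):
        fit = handmade_fit()
        fit.concentrations = {"GABA": 2.0}
        a = quantify(fit, 1.0, 0.0).gaba_h2o
        b = quantify(fit, 2.0, 0.0).gaba_h2o
        assert b == pytest.approx(a / 2.0)

    def test_invalid_f_csf(self):
        with pytest.raises(ValueError):
            quantify(handmade_fit(), 1.0, f_csf=1.0)

    def test_water_amplitude_recovers_concentration(self, acq):
        """End-to-end water scaling: fitted amplitude / water integral
        reproduces the configured concentration."""
        basis = synthetic.generate_basis(acq)
        s = synthetic.generate_cohort(
            CohortSpec(n_young=1, n_old=0, seed=2)
        )[0]
        one = acq.model_copy(update={"n_transient_pairs": 1})
        series, water = synthetic.synthesize_megapress_fids(
            s, basis, one, drift_model=None, noise_sd=0.0, seed=0,
            background=None,
        )
        diff, _ = mrs_prep.average_and_difference(series, align=False)
        w_spec = mrs_prep.fid_to_spectrum(water.fids[0], acq)
        w_amp = water_amplitude(w_spec, basis.ppm_axis)
        fit = fit_linear_combination(diff, basis,
                                     BaselineConfig(dkntmn=None))
        q = quantify(fit, w_amp, s.f_csf)
        assert q.gaba_h2o == pytest.approx(s.true_gaba, rel=0.02)
        assert q.glx_h2o == pytest.approx(s.true_glx, rel=0.02)


class TestSweep:
    def test_single_config_returned(self, acq, basis):
        diffs = [
            construct_diff(basis, acq, {"GABA": 2.8, "Glx": 12.0},
                           noise_sd=0.1, seed=s)
            for s in range(3)
        ]
        _, report = sweep_and_select(diffs, basis, configs=(0.6,))
        assert report["recommended"] == "0.6"

    def test_recommends_default_spacing(self, sweep_replicates):
        """On cohorts with the generator's aging structure and smooth
        background, the sweep recommends 0.6 in at least 80% of
        replicates."""
        recs = [r["report"]["recommended"] for r in sweep_replicates]
        assert sum(r == "0.6" for r in recs) >= 0.8 * len(recs)

    def test_flexible_baseline_inflates_crlb(self, sweep_replicates):
        """dkntmn 0.2 has the highest mean GABA CRLB of all configs in
        most cohorts (overfitting direction)."""
        hits = 0
        for r in sweep_replicates:
            pc = r["report"]["per_config"]
            worst = max(pc, key=lambda k: pc[k]["mean_crlb"])
            hits += worst == "0.2"
        assert hits >= 0.8 * len(sweep_replicates)

    def test_no_baseline_lowers_snr(self, sweep_replicates):
        """Fitting without a baseline yields the lowest mean GABA SNR in
        every cohort replicate."""
        for r in sweep_replicates:
            pc = r["report"]["per_config"]
            assert min(pc, key=lambda k: pc[k]["mean_snr"]) == "noBline"

    def test_glx_crlb_quality(self, sweep_replicates):
        """At the recommended spacing the Glx fit quality is high
        (CRLB < 4%)."""
        vals = []
        for r in sweep_replicates:
            t = r["table"]
            vals.extend(t.loc[t["config"] == "0.6", "Glx_crlb"])
        assert np.mean(vals) < 4.0

    def test_fitted_group_difference_sign(self, acq, basis):
        """Fitted GABA+ and Glx group differences (young minus old) are
        positive in at least 95% of cohort replicates at the printed group
        distributions (n = 14/14)."""
        from conftest import make_diff

        hits_gaba = hits_glx = 0
        n_rep = 20
        for rep in range(n_rep):
            cohort = synthetic.generate_cohort(CohortSpec(seed=3000 + rep))
            vals = {"young": {"GABA": [], "Glx": []},
                    "old": {"GABA": [], "Glx": []}}
            for s in cohort:
                diff, _, water = make_diff(s, basis, acq, noise_sd=8.0,
                                           seed=3000 + rep)
                fit = fit_linear_combination(
                    diff, basis, BaselineConfig(dkntmn=0.6)
                )
                w_spec = mrs_prep.fid_to_spectrum(water.fids[0], acq)
                w_amp = water_amplitude(w_spec, basis.ppm_axis)
                q = quantify(fit, w_amp, s.f_csf)
                vals[s.group]["GABA"].append(q.gaba_h2o)
                vals[s.group]["Glx"].append(q.glx_h2o)
            hits_gaba += np.mean(vals["young"]["GABA"]) > \
                np.mean(vals["old"]["GABA"])
            hits_glx += np.mean(vals["young"]["Glx"]) > \
                np.mean(vals["old"]["Glx"])
        assert hits_gaba >= 0.95 * n_rep
        assert hits_glx >= 0.95 * n_rep
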