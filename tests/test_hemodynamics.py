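"""Hemodynamics tests: FIR deconvolution, interpolation, biphasic peak
metrics, segment energetics, neuro-sensitization, and cluster-extent
inference."""

import numpy as np
import pytest

from megabold import synthetic
from megabold.hemodynamics import (
    HRFCurve,
    deconvolve_hrf,
    hrf_peak_metrics,
    interpolate_hrf,
    neurosensitize,
    parcellate,
    region_label,
    segment_energetics,
)
from megabold.types import BoldDesign, CohortSpec, substream


@pytest.fixture(scope="module")
def design():
    return BoldDesign()


@pytest.fixture(scope="module")
def stims(design):
    rng = substream(0, "stims")
    return [
        synthetic.stimulus_indicator(design, rng)[0]
        for _ in range(design.n_runs)
    ]


def biphasic_taps(design):
    t = np.arange(design.n_lags) * design.tr
    return np.exp(-0.5 * ((t - 10) / 4) ** 2) - 0.4 * np.exp(
        -0.5 * ((t - 38) / 5) ** 2
    )


class TestDeconvolution:
    def test_exact_recovery_noiseless(self, design, stims):
        """Noiseless BOLD built from a known 13-tap kernel returns the
        taps to machine precision."""
        h = biphasic_taps(design)
        runs = [np.convolve(s, h)[: len(s)][None, :].T + 3.0 for s in stims]
        taps, avg = deconvolve_hrf([r.T for r in runs], stims, design)
        assert taps.shape == (13, 1)
        assert np.abs(taps[:, 0] - h).max() < 1e-8

    def test_lag_count(self, design, stims):
        h = biphasic_taps(design)
        runs = [np.convolve(s, h)[: len(s)][None, :] for s in stims]
        taps, avg = deconvolve_hrf(runs, stims, design)
        assert len(avg.times) == 13
        assert avg.times[-1] == 48.0

    def test_linearity(self, design, stims):
        h = biphasic_taps(design)
        runs = [np.convolve(s, h)[: len(s)][None, :] for s in stims]
        taps1, _ = deconvolve_hrf(runs, stims, design)
        taps3, _ = deconvolve_hrf([3.0 * r for r in runs], stims, design)
        assert np.allclose(taps3, 3.0 * taps1, atol=1e-10)

    def test_singular_design_raises(self, design):
        s = np.ones(design.n_measurements_per_run)   # no jitter at all
        with pytest.raises(ValueError, match="singular|jitter"):
            deconvolve_hrf(
                [np.zeros((1, len(s)))], [s], design
            )

    def test_tap_noise_matches_ls_covariance(self, design, stims):
        """Empirical tap SD agrees with the least-squares covariance
        prediction within 15% over 200 noisy replicates."""
        h = biphasic_taps(design)
        clean = [np.convolve(s, h)[: len(s)] for s in stims]
        sigma = 0.5
        rng = np.random.default_rng(7)
        est = []
        for _ in range(200):
            runs = [
                (c + sigma * rng.standard_normal(len(c)))[None, :]
                for c in clean
            ]
            taps, _ = deconvolve_hrf(runs, stims, design)
            est.append(taps[:, 0])
        emp_sd = np.std(est, axis=0, ddof=1)
        from megabold.hemodynamics import _fir_design

        X = _fir_design(stims, design.n_lags)
        cov = sigma**2 * np.linalg.inv(X.T @ X)
        pred_sd = np.sqrt(np.diag(cov)[: design.n_lags])
        assert np.all(np.abs(emp_sd - pred_sd) < 0.15 * pred_sd)


class TestInterpolation:
    def test_sample_counts(self, design):
        t = np.arange(13) * 4.0
        c = interpolate_hrf(HRFCurve(times=t, values=np.sin(t)))
        assert len(c.fine_times) == 97
        assert c.fine_times[-1] == 48.0

    def test_native_points_preserved(self):
        t = np.arange(13) * 4.0
        rng = np.random.default_rng(0)
        v = rng.normal(size=13)
        c = interpolate_hrf(HRFCurve(times=t, values=v))
        on_native = np.isin(c.fine_times, t)
        assert np.allclose(c.fine_values[on_native], v, atol=1e-12)

    def test_cubic_polynomial_reproduced(self):
        t = np.arange(13) * 4.0
        poly = lambda x: 0.01 * x**3 - 0.2 * x**2 + x - 3   # noqa: E731
        c = interpolate_hrf(HRFCurve(times=t, values=poly(t)))
        assert np.allclose(c.fine_values, poly(c.fine_times), atol=1e-9)

    def test_bad_dt_raises(self):
        t = np.arange(13) * 4.0
        with pytest.raises(ValueError):
            interpolate_hrf(HRFCurve(times=t, values=t), dt=0.7)


def gaussian_curve(center=10.0, sd=2.0, height=1.5, sign=1.0):
    """Curve supplied directly on the 0.5 s extraction grid (peak metrics
    operate on the interpolated form)."""
    t = np.arange(13) * 4.0
    tf = np.arange(97) * 0.5
    g = lambda x: sign * height * np.exp(-0.5 * ((x - center) / sd) ** 2)  # noqa: E731
    return HRFCurve(times=t, values=g(t), fine_times=tf, fine_values=g(tf))


class TestPeakMetrics:
    def test_gaussian_closed_form(self):
        """Gaussian bump: amplitude = height, ttp = center, FWHM =
        2 sqrt(2 ln 2) sigma, within the 0.5 s grid tolerance."""
        m = hrf_peak_metrics(gaussian_curve())
        assert m.amplitude == pytest.approx(1.5, abs=0.02)
        assert m.ttp == pytest.approx(10.0, abs=0.5)
        assert m.fwhm == pytest.approx(2 * np.sqrt(2 * np.log(2)) * 2.0,
                                       abs=0.5)

    def test_sign_equivariance(self):
        pos = hrf_peak_metrics(gaussian_curve())
        neg = hrf_peak_metrics(gaussian_curve(sign=-1.0))
        assert neg.amplitude == pytest.approx(-pos.amplitude)
        assert neg.ttp == pytest.approx(pos.ttp)
        assert neg.fwhm == pytest.approx(pos.fwhm)

    def test_dominant_negative_lobe(self):
        """When the in-window negative lobe is larger in magnitude, the
        returned amplitude is negative and ttp sits at that lobe."""
        t = np.arange(13) * 4.0
        v = 0.5 * np.exp(-0.5 * ((t - 8) / 3) ** 2) \
            - 1.2 * np.exp(-0.5 * ((t - 24) / 3) ** 2)
        m = hrf_peak_metrics(interpolate_hrf(HRFCurve(times=t, values=v)))
        assert m.amplitude < 0
        assert abs(m.ttp - 24.0) < 1.0

    def test_translation_equivariance(self):
        a = hrf_peak_metrics(gaussian_curve(center=10))
        b = hrf_peak_metrics(gaussian_curve(center=16))
        assert b.ttp - a.ttp == pytest.approx(6.0, abs=0.5)
        assert b.amplitude == pytest.approx(a.amplitude, abs=0.02)
        assert b.fwhm == pytest.approx(a.fwhm, abs=0.5)

    def test_no_peak_raises(self):
        t = np.arange(13) * 4.0
        with pytest.raises(ValueError):
            hrf_peak_metrics(
                interpolate_hrf(HRFCurve(times=t, values=t * 0.1))
            )

    def test_half_prominence_on_offset_peak(self):
        """On a bump riding a pedestal, the half-prominence width is
        narrower than the half-height-from-zero width."""
        tf = np.arange(97) * 0.5
        t = np.arange(13) * 4.0
        g = lambda x: 0.6 + np.exp(-0.5 * ((x - 12) / 3) ** 2)  # noqa: E731
        curve = HRFCurve(times=t, values=g(t), fine_times=tf,
                         fine_values=g(tf))
        hh = hrf_peak_metrics(curve)
        hp = hrf_peak_metrics(curve, width_reference="half-prominence")
        assert hp.fwhm < hh.fwhm
        assert hp.ttp == hh.ttp


class TestSegmentEnergetics:
    def test_constant_curve_auc(self):
        times = np.arange(97) * 0.5
        curves = np.full((5, 97), 2.0)
        e = segment_energetics(curves, times)
        assert np.allclose(e.auc, 32.0)          # 16 s x 2.0

    def test_z_normalisation(self):
        times = np.arange(97) * 0.5
        rng = np.random.default_rng(0)
        curves = rng.normal(size=(50, 97))
        e = segment_energetics(curves, times)
        assert np.allclose(e.z.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(e.z.std(axis=1), 1.0, atol=1e-12)

    def test_segment_additivity(self):
        times = np.arange(97) * 0.5
        rng = np.random.default_rng(1)
        curves = rng.normal(size=(8, 97))
        e = segment_energetics(curves, times)
        full = np.trapezoid(curves, times, axis=1)
        assert np.allclose(e.auc.sum(axis=0), full, atol=1e-9)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            segment_energetics(np.zeros((0, 97)), np.arange(97) * 0.5)


class TestNeurosensitize:
    def test_affine_relation_gives_zero(self):
        rng = np.random.default_rng(0)
        cbf = rng.normal(50, 5, size=(10, 20))
        z = 0.3 * cbf - 2.0
        resid, _ = neurosensitize(z, cbf)
        assert np.abs(resid).max() < 1e-10

    def test_orthogonal_cbf_returns_centered(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=(8, 5))
        cbf = np.tile(np.array([[1.0], [-1.0]] * 4), (1, 5))
        z = z - (
            (z * (cbf - cbf.mean(0))).sum(0)
            / ((cbf - cbf.mean(0)) ** 2).sum(0)
        ) * (cbf - cbf.mean(0))
        resid, _ = neurosensitize(z, cbf)
        assert np.allclose(resid, z - z.mean(axis=0), atol=1e-12)

    def test_residual_orthogonality(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=(12, 30))
        cbf = rng.normal(45, 6, size=(12, 30))
        resid, _ = neurosensitize(z, cbf)
        cc = cbf - cbf.mean(axis=0)
        assert np.abs((resid * cc).sum(axis=0)).max() < 1e-10

    def test_per_group_option_orthogonal_within_groups(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=(12, 10))
        cbf = rng.normal(45, 6, size=(12, 10))
        groups = np.array(["a"] * 6 + ["b"] * 6)
        resid, _ = neurosensitize(z, cbf, groups=groups)
        for g in ("a", "b"):
            idx = groups == g
            cc = cbf[idx] - cbf[idx].mean(axis=0)
            assert np.abs((resid[idx] * cc).sum(axis=0)).max() < 1e-10

    def test_z_across_subjects_scope(self):
        from megabold.hemodynamics import z_across_subjects

        rng = np.random.default_rng(6)
        z = z_across_subjects(rng.normal(size=(20, 7)))
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=0), 1.0, atol=1e-12)

    def test_zero_variance_flagged(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=(6, 4))
        cbf = rng.normal(size=(6, 4))
        cbf[:, 2] = 50.0
        resid, flags = neurosensitize(z, cbf)
        assert 2 in flags["zero_variance_voxels"]
        assert np.allclose(resid[:, 2], z[:, 2] - z[:, 2].mean())

    def test_recovery_of_neural_signal(self):
        """With CBF-coupled energetics, the residual decorrelates from CBF
        and correlates better with the stored neural ground truth in at
        least 90% of seeded replicates."""
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            n_sub, n_vox = 12, 25
            neural = rng.normal(size=(n_sub, n_vox))
            cbf = rng.normal(45, 6, size=(n_sub, n_vox))
            z = neural + 0.15 * (cbf - 45.0) \
                + 0.3 * rng.normal(size=(n_sub, n_vox))
            resid, _ = neurosensitize(z, cbf)

            def colcorr(a, b):
                ac = a - a.mean(0)
                bc = b - b.mean(0)
                num = (ac * bc).sum(0)
                den = np.sqrt((ac**2).sum(0) * (bc**2).sum(0))
                return num / den

            assert np.abs(colcorr(resid, cbf)).max() < 1e-10
            hits += np.mean(np.abs(colcorr(resid, neural))) > np.mean(
                np.abs(colcorr(z - z.mean(0), neural))
            )
        assert hits >= 0.90 * n_rep


class TestParcellation:
    def test_all_zero_maps_no_clusters(self):
        maps = np.zeros((6, 6, 6, 6))
        res = parcellate(maps, synthetic.default_affine(), n_null=60,
                         seed=0)
        assert res.clusters == []

    def test_region_labels_from_centroids(self):
        assert region_label(50.2) == "anterior"
        assert region_label(29.3) == "mid"
        assert region_label(18.0) == "posterior"

    def test_signal_cluster_found_and_labelled(self):
        """A strong localized effect survives and is labelled by its
        centroid's y coordinate under the grid affine."""
        rng = np.random.default_rng(0)
        maps = 0.5 * rng.standard_normal((10, 8, 8, 8))
        maps[:, 2:5, 6:8, 3:6] += 3.0
        aff = synthetic.default_affine()
        res = parcellate(maps, aff, n_null=200, seed=1)
        assert len(res.clusters) >= 1
        big = max(res.clusters, key=lambda c: c.size)
        # voxel y in [6, 7.5) -> mm y = 12 + 6*y > 40 -> anterior
        assert big.label == "anterior"

    def test_too_small_null_raises(self):
        with pytest.raises(ValueError):
            parcellate(np.zeros((5, 4, 4, 4)), np.eye(4), n_null=10,
                       seed=0)

    def test_fwe_calibration_larger_grid(self):
        """Empirical familywise rate on pure-noise 12^3 cohorts stays
        within the binomial band around the nominal 5%."""
        n_rep = 120
        fp = 0
        for rep in range(n_rep):
            rng = np.random.default_rng(10_000 + rep)
            maps = rng.standard_normal((10, 12, 12, 12))
            res = parcellate(maps, np.eye(4), n_null=200, seed=rep)
            fp += len(res.clusters) > 0
        phat = fp / n_rep
        assert phat <= 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
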