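"""GLM, HRF, preprocessing, cluster thresholding, group maps, spatial ICA."""
import numpy as np
import pytest

from epiwarp import fmri


class TestHrf:
    def test_peak_time_in_physiological_window(self):
        tr = 0.5
        h = fmri.double_gamma_hrf(tr)
        assert 4.0 <= np.argmax(h) * tr <= 7.0

    def test_zero_at_onset_unit_peak(self):
        h = fmri.double_gamma_hrf(1.0)
        assert h[0] == pytest.approx(0.0, abs=1e-6)
        assert h.max() == pytest.approx(1.0)

    def test_late_tail_small(self):
        h = fmri.double_gamma_hrf(1.0, duration_s=34.0)
        assert abs(h[30]) < 0.05


class TestPreprocess:
    def test_constant_series_zero_mean_after_highpass(self):
        series = np.full((4, 4, 4, 50), 7.0)
        out = fmri.preprocess(series, tr_s=1.0, fwhm_mm=0.0)
        assert np.abs(out).max() < 1e-9

    def test_slow_sinusoid_survives(self):
        t = np.arange(200)
        sig = np.sin(2 * np.pi * 0.05 * t)  # 0.05 Hz, well above 1/100 s cutoff
        out = fmri.preprocess(sig[None, :], tr_s=1.0, highpass_cutoff_s=100.0,
                              fwhm_mm=0.0)[0]
        ratio = np.sqrt(np.sum(out ** 2) / np.sum((sig - sig.mean()) ** 2))
        assert ratio > 0.95

    def test_drift_removed(self):
        t = np.arange(200, dtype=float)
        drift = 0.01 * t
        out = fmri.preprocess(drift[None, :], tr_s=1.0, fwhm_mm=0.0)[0]
        assert np.std(out) < 0.1 * np.std(drift)

    def test_spatial_smoothing_width(self):
        # antisymmetric in time so the temporal-mean removal is a no-op
        series = np.zeros((31, 31, 31, 2))
        series[15, 15, 15, 0] = -1.0
        series[15, 15, 15, 1] = 1.0
        out = fmri.preprocess(series, tr_s=1.0, highpass_cutoff_s=1e9,
                              fwhm_mm=6.0, voxel_size=(1.0, 1.0, 1.0))
        profile = out[:, 15, 15, 1]
        profile = profile - profile.min()
        half = profile.max() / 2.0
        lo = np.interp(half, profile[:16], np.arange(16.0))
        hi = 30.0 - np.interp(half, profile[:14:-1], np.arange(16.0))
        assert (hi - lo) == pytest.approx(6.0, rel=0.05)


class TestFitGlm:
    def make_design(self, n, seed=0):
        rng = np.random.default_rng(seed)
        box = (np.arange(n) % 30) < 15
        reg = np.convolve(box.astype(float), fmri.double_gamma_hrf(1.0))[:n]
        return fmri.GLMDesign(regressor=reg, tr_s=1.0)

    def test_noise_free_effect_recovered_exactly(self):
        n = 60
        design = self.make_design(n)
        beta_true = 3.7
        series = 5.0 + beta_true * design.regressor[None, :] * np.ones((4, n))
        zmap, effect = fmri.fit_glm(series, design)
        np.testing.assert_allclose(effect, beta_true, atol=1e-6)
        assert np.all(zmap.z_values == fmri.Z_CAP)  # exact fit -> capped Z

    def test_confound_only_signal_gives_null_effect(self):
        n = 80
        rng = np.random.default_rng(1)
        conf = rng.standard_normal(n)
        design = self.make_design(n)
        design = fmri.GLMDesign(regressor=design.regressor, tr_s=1.0,
                                confounds=conf)
        series = 2.0 + 1.5 * conf[None, :] * np.ones((3, n))
        _, effect = fmri.fit_glm(series, design)
        np.testing.assert_allclose(effect, 0.0, atol=1e-8)

    def test_null_calibration(self):
        """White noise: |Z| > 1.96 in ~5% of voxels."""
        n, v = 120, 30000
        rng = np.random.default_rng(2)
        series = rng.standard_normal((v, n))
        zmap, _ = fmri.fit_glm(series, self.make_design(n))
        frac = np.mean(np.abs(zmap.z_values) > 1.96)
        assert frac == pytest.approx(0.05, abs=0.012)

    def test_rank_deficient_rejected(self):
        design = fmri.GLMDesign(regressor=np.ones(20), tr_s=1.0)  # = intercept
        with pytest.raises(ValueError):
            fmri.fit_glm(np.random.default_rng(0).random((3, 20)), design)


class TestClusterThreshold:
    def test_empty_suprathreshold(self):
        assert not fmri.cluster_threshold(np.zeros((5, 5, 5)), 2.5, 10).any()

    def test_large_blob_retained_intact(self):
        z = np.zeros((10, 10, 10))
        z[2:6, 2:7, 3:5] = 4.0  # 40 voxels
        mask = fmri.cluster_threshold(z, 2.5, min_extent_vox=20)
        assert mask.sum() == 40

    def test_small_blob_removed(self):
        z = np.zeros((12, 12, 4))
        z[1:6, 1:7, 1] = 4.0   # 30 voxels
        z[9:11, 9:11, 2] = 4.0  # 4 voxels (26-connected component of 4 < 10)
        z[11, 11, 3] = 4.0      # far corner single voxel
        mask = fmri.cluster_threshold(z, 2.5, min_extent_vox=10)
        assert mask.sum() == 30
        assert not mask[9:, 9:, :].any()


class TestGroupMap:
    def test_identical_maps_flagged(self):
        m = np.ones((3, 3))
        with pytest.warns(UserWarning, match="zero between-subject"):
            out = fmri.group_map([m, m, m])
        assert np.all(out.z_values == fmri.Z_CAP)

    def test_null_type_one_error(self):
        rng = np.random.default_rng(4)
        subs = [rng.standard_normal((120, 120)) for _ in range(12)]
        out = fmri.group_map(subs)
        frac = np.mean(np.abs(out.z_values) > 1.96)
        assert frac == pytest.approx(0.05, abs=0.015)

    def test_mean_z_scales_with_sqrt_subjects(self):
        rng = np.random.default_rng(5)
        effect = 0.4
        def sim(n):
            subs = [effect + rng.standard_normal((60, 60)) for _ in range(n)]
            return float(np.mean(fmri.group_map(subs).z_values))
        z4, z16 = sim(4), sim(16)
        assert z16 / z4 == pytest.approx(2.0, rel=0.35)

    def test_nested_runs_averaged_first(self):
        a = np.full((2, 2), 1.0)
        b = np.full((2, 2), 3.0)
        with pytest.warns(UserWarning):
            out = fmri.group_map([[a, b], [a, b], np.full((2, 2), 2.0)])
        assert np.all(out.z_values == fmri.Z_CAP)  # all subjects average to 2

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            fmri.group_map([np.ones((2, 2))])


def planted_network_data(seed=0, with_networks=True):
    rng = np.random.default_rng(seed)
    shape = (16, 16, 8)
    masks = [np.zeros(shape, bool), np.zeros(shape, bool)]
    masks[0][2:7, 2:7, 2:5] = True
    masks[1][9:14, 9:14, 3:6] = True
    n_t = 120
    series = rng.normal(0, 1.0, shape + (n_t,))
    if with_networks:
        for mask, s in zip(masks, (6, 7)):
            tc = np.random.default_rng(s).standard_normal(n_t)
            series[mask] += 3.0 * tc[None, :]
    return series, masks


class TestExtractComponents:
    def test_planted_networks_recovered(self):
        from epiwarp import metrics
        series, masks = planted_network_data()
        maps = fmri.extract_components([series], 2, seed=0)
        for mask in masks:
            best = max(metrics.dice(metrics.threshold_component(m, 3.0), mask)
                       for m in maps)
            assert best > 0.8

    def test_deterministic_under_seed(self):
        series, _ = planted_network_data()
        m1 = fmri.extract_components([series], 2, seed=3)
        m2 = fmri.extract_components([series], 2, seed=3)
        for a, b in zip(m1, m2):
            np.testing.assert_array_equal(a, b)

    def test_absent_network_not_hallucinated(self):
        from epiwarp import metrics
        series, masks = planted_network_data(seed=1, with_networks=False)
        maps = fmri.extract_components([series], 2, seed=0)
        for mask in masks:
            best = max(metrics.dice(metrics.threshold_component(m, 3.0), mask)
                       for m in maps)
            assert best < 0.3

    def test_too_many_components_rejected(self):
        series, _ = planted_network_data()
        with pytest.raises(ValueError):
            fmri.extract_components([series[..., :10]], 15)
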