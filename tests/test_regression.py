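import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sersquant as sq


class TestPLS:
    def test_perfect_univariate_line_one_latent_variable(self):
        X = np.linspace(0, 5, 10)[:, None]
        y = 2.0 * X.ravel()
        model = sq.pls_fit(X, y, n_latent=1)
        np.testing.assert_allclose(model.predict(X), y, atol=1e-10)

    def test_full_rank_pls_equals_ols(self, rng):
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        pls = sq.pls_fit(X, y, n_latent=4)
        ols = sq.mlr_fit(X, y)
        np.testing.assert_allclose(pls.predict(X), ols.predict(X), atol=1e-8)

    def test_constant_response_predicts_mean(self, rng):
        X = rng.normal(size=(8, 3))
        y = np.full(8, 3.3)
        model = sq.pls_fit(X, y, n_latent=2)
        np.testing.assert_allclose(model.coefficients, 0.0, atol=1e-12)
        np.testing.assert_allclose(model.predict(X), 3.3)

    def test_n_latent_beyond_rank_rejected(self, rng):
        X = np.tile(rng.normal(size=(6, 1)), (1, 3))  # rank 1
        with pytest.raises(ValueError, match="rank"):
            sq.pls_fit(X, rng.normal(size=6), n_latent=2)

    def test_matches_sklearn_pls(self, rng):
        skpls = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(20, 6))
        y = X @ rng.normal(size=6) + 0.1 * rng.normal(size=20)
        ours = sq.pls_fit(X, y, n_latent=3)
        ref = skpls.PLSRegression(n_components=3, scale=False).fit(X, y[:, None])
        np.testing.assert_allclose(
            ours.predict(X), ref.predict(X).ravel(), atol=1e-8
        )


class TestMLR:
    def test_exact_line(self):
        X = np.array([[0.0], [1.0], [2.0], [5.0]])
        model = sq.mlr_fit(X, 3.0 * X.ravel() + 1.0)
        np.testing.assert_allclose(model.predict(X), 3.0 * X.ravel() + 1.0, atol=1e-10)

    def test_more_features_than_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            sq.mlr_fit(rng.normal(size=(3, 5)), rng.normal(size=3))

    def test_rank_deficiency_advises_dimension_reduction(self, rng):
        X = np.tile(rng.normal(size=(8, 1)), (1, 2))
        with pytest.raises(ValueError, match="KPCA|PLS"):
            sq.mlr_fit(X, rng.normal(size=8))

    def test_noiseless_multivariate_exact(self, rng):
        X = rng.normal(size=(12, 3))
        beta = np.array([1.5, -2.0, 0.5])
        y = X @ beta + 4.0
        model = sq.mlr_fit(X, y)
        np.testing.assert_allclose(model.predict(X), y, atol=1e-10)


class TestRMSECV:
    def test_perfect_linear_data_zero_error(self):
        X = np.linspace(0, 9, 10)[:, None]
        y = 2.0 * X.ravel() + 1.0
        assert sq.rmsecv(X, y, {"method": "mlr"}) == pytest.approx(0.0, abs=1e-9)

    def test_two_sample_loo_mean_model_hand_value(self):
        X = np.zeros((2, 1))
        y = np.array([0.0, 2.0])
        assert sq.rmsecv(X, y, {"method": "mean"}) == pytest.approx(2.0)

    def test_estimator_consistency_with_known_noise(self, rng):
        n, sigma_noise = 200, 0.3
        X = rng.uniform(0, 10, size=(n, 1))
        y = 1.7 * X.ravel() + sigma_noise * rng.standard_normal(n)
        val = sq.rmsecv(X, y, {"method": "mlr"})
        assert abs(val - sigma_noise) / sigma_noise < 0.25

    def test_invalid_folds_rejected(self):
        X = np.zeros((3, 1))
        y = np.arange(3.0)
        with pytest.raises(ValueError):
            sq.rmsecv(X, y, {"method": "mean"}, folds=5)

    def test_kfold_deterministic(self, rng):
        X = rng.normal(size=(12, 2))
        y = rng.normal(size=12)
        a = sq.rmsecv(X, y, {"method": "mlr"}, folds=4)
        b = sq.rmsecv(X, y, {"method": "mlr"}, folds=4)
        assert a == b


class TestCalibrationCurve:
    def test_points_on_printed_line_recovered_exactly(self):
        # points generated by I = 11644 N + 4536.5
        N = np.array([0.1, 1.0, 5.0])
        I = np.array([5700.9, 16180.5, 62756.5])
        curve = sq.fit_calibration(I, N)
        assert curve.slope == pytest.approx(11644.0)
        assert curve.intercept == pytest.approx(4536.5)
        assert curve.r_squared == pytest.approx(1.0)

    def test_two_distinct_points_exact_line(self):
        curve = sq.fit_calibration([10.0, 20.0], [1.0, 2.0])
        assert curve.slope == pytest.approx(10.0)
        assert curve.r_squared == pytest.approx(1.0)

    def test_all_equal_concentrations_rejected(self):
        with pytest.raises(ValueError):
            sq.fit_calibration([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 1000.0))
    def test_scale_equivariance(self, scale):
        N = np.array([0.1, 0.5, 1.0, 2.0, 5.0])
        I = 100.0 * N + 7.0 + np.array([0.5, -0.3, 0.2, -0.1, 0.4])
        a = sq.fit_calibration(I, N)
        b = sq.fit_calibration(scale * I, N)
        assert b.slope == pytest.approx(scale * a.slope, rel=1e-9)
        assert b.intercept == pytest.approx(scale * a.intercept, rel=1e-9)
        assert b.r_squared == pytest.approx(a.r_squared, rel=1e-9)


class TestLODAndRSD:
    def test_zero_variance_blanks(self):
        curve = sq.CalibrationCurve(50.0, 0.0, 1.0)
        assert sq.lod([100.0, 100.0, 100.0], curve) == pytest.approx(2.0)

    def test_three_sigma_hand_value(self):
        curve = sq.CalibrationCurve(50.0, 0.0, 1.0)
        blanks = [90.0, 100.0, 110.0]  # mean 100, sample SD 10
        assert sq.lod(blanks, curve) == pytest.approx(130.0 / 50.0)

    def test_floor_at_zero_when_intercept_dominates(self):
        curve = sq.CalibrationCurve(50.0, 1e6, 1.0)
        assert sq.lod([100.0, 100.0, 100.0], curve) == 0.0

    def test_monotone_in_blank_sd(self):
        curve = sq.CalibrationCurve(50.0, 0.0, 1.0)
        tight = sq.lod([99.0, 100.0, 101.0], curve)
        wide = sq.lod([90.0, 100.0, 110.0], curve)
        assert wide > tight

    def test_3s_only_rule(self):
        curve = sq.CalibrationCurve(50.0, 0.0, 1.0)
        assert sq.lod([100.0, 100.0, 100.0], curve, rule="3s_only") == pytest.approx(6.0)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            sq.lod([1.0, 2.0, 3.0], sq.CalibrationCurve(-1.0, 0.0, 1.0))

    def test_rsd_hand_values(self):
        assert sq.rsd([9.0, 10.0, 11.0]) == pytest.approx(10.0)
        assert sq.rsd([5.0, 5.0, 5.0]) == 0.0
        with pytest.raises(ValueError):
            sq.rsd([-1.0, 1.0])


class TestDetectPeaks:
    def test_thiram_bands_found_with_dominant_1379(self, clean_thiram):
        s = sq.generate_spectrum(clean_thiram, 1.0)
        peaks = sq.detect_peaks(s)
        centers = [c for c, _ in peaks]
        heights = [h for _, h in peaks]
        assert len(peaks) == 5
        for expected, got in zip([562, 929, 1146, 1379, 1514], centers):
            assert got == pytest.approx(expected, abs=2.0)
        assert centers[int(np.argmax(heights))] == pytest.approx(1379.0, abs=2.0)

    def test_flat_spectrum_no_peaks(self):
        nu = np.arange(550.0, 700.0)
        assert sq.detect_peaks(sq.Spectrum(nu, np.full(nu.shape, 3.0))) == []

    def test_parabolic_refinement_on_gaussian(self):
        nu = np.arange(550.0, 1551.0)
        y = sq.gauss_profile(nu, 12.0, 1000.3)
        peaks = sq.detect_peaks(sq.Spectrum(nu, y))
        assert len(peaks) == 1
        assert peaks[0][0] == pytest.approx(1000.3, abs=0.5)

    def test_offset_invariance(self, clean_thiram):
        s = sq.generate_spectrum(clean_thiram, 1.0)
        shifted = sq.Spectrum(s.wavenumbers, s.intensities + 5000.0, s.sample_id)
        a = sq.detect_peaks(s)
        b = sq.detect_peaks(shifted)
        np.testing.assert_allclose(
            [c for c, _ in a], [c for c, _ in b], atol=1e-9
        )
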