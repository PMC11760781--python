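"""Q-vs-resolution statistical model: trend evaluation, offset calibration,
rolling-window alternative and outlier classification."""

import numpy as np
import pytest

from qscore3d import (
    PUBLISHED_MODEL,
    CalibrationDataset,
    ComputationError,
    ExtrapolationWarning,
    ResolutionStatModel,
    calibrate_offsets,
    classify_entry,
    fit_regression,
    make_calibration_table,
    q_bounds,
    q_mean,
    rolling_window_bounds,
)
from qscore3d.synthetic import FixtureSpec

CUBIC = PUBLISHED_MODEL.coefficients


class TestTrendEvaluation:
    # expected values frozen from direct hand evaluation of the cubic
    @pytest.mark.parametrize("d,expected", [(1.9, 0.7307), (3.0, 0.4972)])
    def test_default_curve_values(self, d, expected):
        assert q_mean(d) == pytest.approx(expected, abs=5e-5)

    def test_constant_polynomial(self):
        model = ResolutionStatModel(coefficients=(0.0, 0.0, 0.0, 1.0))
        for d in (1.0, 4.2, 9.9):
            assert q_mean(d, model) == 1.0

    def test_extrapolation_warns_but_returns(self):
        with pytest.warns(ExtrapolationWarning):
            value = q_mean(0.5)
        assert np.isfinite(value)


class TestBounds:
    def test_published_offsets_at_3A(self):
        peak, low, high = q_bounds(3.0)
        assert peak == pytest.approx(0.5212, abs=5e-5)
        assert low == pytest.approx(0.3712, abs=5e-5)
        assert high == pytest.approx(0.6062, abs=5e-5)

    def test_low_bound_at_5p7A(self):
        _, low, _ = q_bounds(5.7)
        assert low == pytest.approx(0.0694, abs=5e-5)
        assert 0.001 < low  # a Q of 0.001 lies below the band

    def test_zero_offsets_collapse(self):
        model = ResolutionStatModel(coefficients=CUBIC)
        peak, low, high = q_bounds(3.0, model)
        assert peak == low == high

    def test_ordering_over_domain(self):
        for d in np.linspace(1.0, 10.0, 50):
            peak, low, high = q_bounds(d)
            assert low < peak < high


class TestClassification:
    @pytest.mark.parametrize("d,q,label", [
        (1.9, 0.70, "typical"),
        (5.7, 0.001, "outlier_low"),
        (3.5, 0.66, "outlier_high"),
    ])
    def test_archive_style_calls(self, d, q, label):
        assert classify_entry(d, q).label == label

    def test_boundary_is_typical(self):
        """The 95% band is a closed interval: Q exactly on a bound is not an
        outlier."""
        _, low, high = q_bounds(3.0)
        assert classify_entry(3.0, low).label == "typical"
        assert classify_entry(3.0, high).label == "typical"

    def test_report_carries_curve_values(self):
        c = classify_entry(3.0, 0.5)
        assert c.q_low < c.q_mean < c.q_peak < c.q_high


class TestFitRegression:
    def test_noiseless_cubic_recovered(self):
        d = np.linspace(1, 10, 60)
        data = CalibrationDataset(d, np.polyval(CUBIC, d))
        fit = fit_regression(data, 3)
        assert np.allclose(fit.coefficients, CUBIC, atol=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equation_oracle(self, rng):
        d = rng.uniform(1, 10, 200)
        q = np.polyval(CUBIC, d) + rng.normal(0, 0.05, 200)
        q = np.clip(q, -1, 1)
        fit = fit_regression(CalibrationDataset(d, q), 3)
        # closed-form least squares via the normal equations
        X = np.vander(d, 4)
        beta = np.linalg.solve(X.T @ X, X.T @ q)
        assert np.allclose(fit.coefficients, beta, rtol=1e-9)

    def test_linear_fit_has_lower_r2_on_cubic_data(self, rng):
        d = rng.uniform(1, 10, 500)
        q = np.clip(np.polyval(CUBIC, d) + rng.normal(0, 0.03, 500), -1, 1)
        data = CalibrationDataset(d, q)
        assert fit_regression(data, 1).r_squared < fit_regression(data, 3).r_squared

    def test_too_few_distinct_resolutions(self):
        data = CalibrationDataset([2.0, 2.0, 3.0, 3.0], [0.5, 0.5, 0.4, 0.4])
        with pytest.raises(ComputationError):
            fit_regression(data, 3)


class TestCalibrateOffsets:
    def _dataset(self, residuals, rng):
        d = rng.uniform(1, 10, len(residuals))
        q = np.clip(np.polyval(CUBIC, d) + residuals, -1, 1)
        return CalibrationDataset(d, q)

    def test_symmetric_uniform_residuals(self, rng):
        """Residuals ~ U(-0.1, 0.1): quantile offsets approach ±0.095 and the
        peak offset approaches 0 (closed-form quantiles of the generator)."""
        data = self._dataset(rng.uniform(-0.1, 0.1, 20000), rng)
        model = calibrate_offsets(data, ResolutionStatModel(coefficients=CUBIC))
        assert model.offset_low == pytest.approx(-0.095, abs=0.004)
        assert model.offset_high == pytest.approx(0.095, abs=0.004)
        # the mode of a uniform density is weakly identified: any offset in
        # the support ties up to sampling noise, so only loosely near 0
        assert abs(model.offset_peak) < 0.06

    def test_left_skew_gives_asymmetric_offsets(self):
        """Skewed-low residuals reproduce |offset_low| > offset_high, the
        sign pattern of the archive calibration."""
        table = make_calibration_table(FixtureSpec(rng_seed=3, n_rows=8000))
        model = calibrate_offsets(table, ResolutionStatModel(coefficients=CUBIC))
        assert abs(model.offset_low) > model.offset_high > 0

    def test_in_sample_coverage_by_construction(self, rng):
        data = self._dataset(rng.normal(0, 0.05, 5000), rng)
        model = calibrate_offsets(data, ResolutionStatModel(coefficients=CUBIC))
        resid = data.q - np.polyval(CUBIC, data.d)
        frac = np.mean((resid >= model.offset_low) & (resid <= model.offset_high))
        assert frac == pytest.approx(0.95, abs=1.0 / len(data) + 1e-9)

    def test_needs_enough_points(self, rng):
        data = self._dataset(rng.normal(0, 0.05, 20), rng)
        with pytest.raises(ComputationError):
            calibrate_offsets(data, ResolutionStatModel(coefficients=CUBIC))


class TestRollingWindow:
    def test_agrees_with_polynomial_method_on_its_own_generator(self):
        """Data from the default cubic + noise: rolling-window curves track
        the regression-plus-offset curves within noise tolerance."""
        table = make_calibration_table(FixtureSpec(rng_seed=5, n_rows=12000))
        fit = fit_regression(table, 3)
        model = calibrate_offsets(table, fit)
        curve = rolling_window_bounds(table, window_width=0.5)
        mid = curve[(curve.d > 2.0) & (curve.d < 9.0) & np.isfinite(curve.q_low)]
        trend = np.polyval(np.asarray(model.coefficients), mid.d.to_numpy())
        # windowed quantiles also absorb the trend's slope across the window,
        # so agreement is within noise + window-curvature tolerance
        assert np.allclose(mid.q_low.to_numpy(), trend + model.offset_low, atol=0.05)
        assert np.allclose(mid.q_high.to_numpy(), trend + model.offset_high, atol=0.05)

    def test_constant_q_gives_flat_curves(self, rng):
        d = rng.uniform(1, 10, 500)
        data = CalibrationDataset(d, np.full(500, 0.42))
        curve = rolling_window_bounds(data, window_width=1.0)
        ok = np.isfinite(curve.q_peak)
        assert np.allclose(curve.q_low[ok], 0.42)
        assert np.allclose(curve.q_high[ok], 0.42)
        assert np.allclose(curve.q_peak[ok], 0.42, atol=5e-3)

    def test_sparse_regions_flagged_as_gaps(self, rng):
        d = np.concatenate([rng.uniform(2.0, 2.5, 300), [8.0] * 5])
        q = np.clip(np.polyval(CUBIC, d), -1, 1)
        curve = rolling_window_bounds(CalibrationDataset(d, q), window_width=0.4,
                                      query_d=np.array([2.25, 8.0]))
        assert np.isfinite(curve.q_low.iloc[0])
        assert np.isnan(curve.q_low.iloc[1])
        assert curve.n.iloc[1] == 5


class TestSerialization:
    def test_json_roundtrip(self, tmp_path):
        path = tmp_path / "model.json"
        PUBLISHED_MODEL.to_json(path)
        back = ResolutionStatModel.from_json(path)
        assert back == PUBLISHED_MODEL
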