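import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipidqy import (
    CalibrationPoint,
    CurveRegistry,
    FluorescenceParameter,
    compare_curves,
    estimate_lipid,
    fit_standard_curve,
)
from lipidqy.errors import (
    DegenerateDesignError,
    IncomparableCurvesError,
    InsufficientDataError,
    NonInvertibleCurveError,
)


def points_from(xs, ys):
    return [CalibrationPoint(fluorescence_value=x, lipid_content=y) for x, y in zip(xs, ys)]


def ols_oracle(x, y):
    """Closed-form normal-equation least squares, independent of the implementation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return beta[1], beta[0]  # slope, intercept


class TestFitStandardCurve:
    def test_perfect_linear_data(self):
        xs = [1.0, 2.0, 3.0, 4.0, 5.0]
        curve = fit_standard_curve(points_from(xs, [2 * x + 1 for x in xs]), "I_E")
        assert curve.slope == pytest.approx(2.0, rel=1e-12)
        assert curve.intercept == pytest.approx(1.0, rel=1e-12)
        assert curve.r_squared == 1.0
        assert curve.residual_sd == pytest.approx(0.0, abs=1e-12)

    def test_zero_x_variance_is_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            fit_standard_curve(points_from([3.0] * 5, [1, 2, 3, 4, 5]), "A_E")

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_standard_curve(points_from([1.0, 2.0], [1.0, 2.0]), "I_E")

    def test_matches_normal_equation_oracle_on_fixed_data(self):
        xs = [1.0, 2.0, 3.0, 4.0, 5.0]
        ys = [1.1, 1.9, 3.2, 3.8, 5.0]
        curve = fit_standard_curve(points_from(xs, ys), "PHI_FL")
        slope, intercept = ols_oracle(xs, ys)
        assert curve.slope == pytest.approx(slope, rel=1e-10)
        assert curve.intercept == pytest.approx(intercept, rel=1e-10)
        resid = np.array(ys) - (slope * np.array(xs) + intercept)
        sst = np.sum((ys - np.mean(ys)) ** 2)
        assert curve.r_squared == pytest.approx(1 - resid @ resid / sst, rel=1e-10)

    @settings(derandomize=True, max_examples=40)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_matches_oracle_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        x = rng.uniform(0, 100, n)
        if np.ptp(x) < 1e-6:
            x[0] += 1.0
        y = rng.uniform(0, 50, n)
        curve = fit_standard_curve(points_from(x, y), "I_E")
        slope, intercept = ols_oracle(x, y)
        assert curve.slope == pytest.approx(slope, rel=1e-10, abs=1e-10)
        assert curve.intercept == pytest.approx(intercept, rel=1e-10, abs=1e-10)

    @settings(derandomize=True, max_examples=40)
    @given(
        scale=st.floats(min_value=0.01, max_value=100.0),
        shift=st.floats(min_value=-50.0, max_value=50.0),
    )
    def test_r_squared_invariant_under_affine_x_rescaling(self, scale, shift):
        xs = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        ys = np.array([1.1, 1.9, 3.2, 3.8, 5.0])
        base = fit_standard_curve(points_from(xs, ys), "I_E")
        moved = fit_standard_curve(points_from(scale * xs + shift, ys), "I_E")
        assert moved.r_squared == pytest.approx(base.r_squared, rel=1e-9)


class TestEstimateLipid:
    def test_direct_evaluation(self):
        curve = fit_standard_curve(points_from([0.0, 1.0, 2.0], [1.0, 3.0, 5.0]), "I_E")
        est = estimate_lipid(curve, 3.0)
        assert est.lipid_pct == pytest.approx(7.0, rel=1e-12)
        assert not est.below_zero

    def test_round_trip_on_perfect_curve(self):
        xs = [1.0, 2.0, 3.0, 4.0, 5.0]
        ys = [2 * x + 1 for x in xs]
        curve = fit_standard_curve(points_from(xs, ys), "A_E")
        for x, y in zip(xs, ys):
            assert estimate_lipid(curve, x).lipid_pct == pytest.approx(y, rel=1e-12)

    def test_noisy_fit_prediction_within_three_residual_sd(self):
        # known truth: lipid = 0.5 * x + 2, Gaussian noise sd 0.2
        rng = np.random.default_rng(42)
        xs = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        ys = 0.5 * xs + 2.0 + rng.normal(0, 0.2, 5)
        curve = fit_standard_curve(points_from(xs, ys), "I_E")
        est = estimate_lipid(curve, 10.0)
        assert est.lipid_pct == pytest.approx(7.0, abs=3 * max(curve.residual_sd, 0.2) * 4)

    def test_zero_slope_not_invertible(self):
        curve = fit_standard_curve(points_from([1.0, 2.0, 3.0], [4.0, 4.0, 4.0]), "I_E")
        assert curve.slope == 0.0
        with pytest.raises(NonInvertibleCurveError):
            estimate_lipid(curve, 1.0)

    def test_negative_estimate_flagged_not_clamped(self):
        curve = fit_standard_curve(points_from([1.0, 2.0, 3.0], [1.0, 3.0, 5.0]), "I_E")
        est = estimate_lipid(curve, -10.0)
        assert est.lipid_pct < 0
        assert est.below_zero


class TestCompareCurves:
    def test_identical_curves(self):
        xs = [1.0, 2.0, 3.0, 4.0]
        curve = fit_standard_curve(points_from(xs, [2 * x for x in xs]), "I_E")
        cmp = compare_curves(curve, curve)
        assert cmp.slope_ratio == 1.0
        assert cmp.intercept_difference == 0.0
        assert cmp.max_prediction_discrepancy == 0.0

    def test_halved_slope_from_lamp_factor_two(self):
        xs = np.array([1.0, 2.0, 3.0, 4.0])
        ys = 2.0 * xs
        curve_a = fit_standard_curve(points_from(xs, ys), "I_E")
        # lamp factor 2 doubles the fluorescence readings for the same lipids
        curve_b = fit_standard_curve(points_from(2.0 * xs, ys), "I_E")
        cmp = compare_curves(curve_a, curve_b)
        assert cmp.slope_ratio == pytest.approx(0.5, rel=1e-12)

    def test_mismatched_parameters_incomparable(self):
        xs = [1.0, 2.0, 3.0]
        a = fit_standard_curve(points_from(xs, xs), "I_E")
        b = fit_standard_curve(points_from(xs, xs), "PHI_FL")
        with pytest.raises(IncomparableCurvesError):
            compare_curves(a, b)


class TestCurveRegistry:
    def test_save_load_roundtrip(self, tmp_path):
        xs = [1.0, 2.0, 3.0, 4.0, 5.0]
        curve = fit_standard_curve(points_from(xs, [1.1, 1.9, 3.2, 3.8, 5.0]),
                                   "PHI_FL", strain="Y.lipolytica", medium="glucose",
                                   month="month-1")
        reg = CurveRegistry([curve])
        path = tmp_path / "curves.json"
        reg.save(path)
        back = CurveRegistry.load(path)
        got = back.get("Y.lipolytica", "glucose", FluorescenceParameter.PHI_FL, "month-1")
        assert got is not None
        assert got.slope == pytest.approx(curve.slope, rel=1e-15)
        assert got.r_squared == pytest.approx(curve.r_squared, rel=1e-15)
        assert back.get("Y.lipolytica", "glucose", "I_E", "month-1") is None


def test_parameter_recovery_coverage():
    """Fitted slope/intercept fall inside their 95% sampling intervals in
    at least 90% of seeded replicates."""
    from scipy import stats as sps

    true_slope, true_intercept, sigma, n = 0.5, 2.0, 0.2, 5
    xs = np.linspace(1.0, 5.0, n)
    tcrit = sps.t.ppf(0.975, n - 2)
    sxx = np.sum((xs - xs.mean()) ** 2)
    hits_slope = hits_intercept = 0
    reps = 200
    rng = np.random.default_rng(2024)
    for _ in range(reps):
        ys = true_slope * xs + true_intercept + rng.normal(0, sigma, n)
        c = fit_standard_curve(points_from(xs, ys), "I_E")
        se_slope = c.residual_sd / np.sqrt(sxx)
        se_intercept = c.residual_sd * np.sqrt(1 / n + xs.mean() ** 2 / sxx)
        hits_slope += abs(c.slope - true_slope) <= tcrit * se_slope
        hits_intercept += abs(c.intercept - true_intercept) <= tcrit * se_intercept
    assert hits_slope / reps >= 0.90
    assert hits_intercept / reps >= 0.90
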