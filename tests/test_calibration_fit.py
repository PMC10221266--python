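"""OLS and functional-model calibration fitting, diagnostics, evaluation."""

import numpy as np
import pytest

from bapscal import (
    CalibrationDataset,
    DomainError,
    InsufficientDataError,
    PolynomialCalibration,
    SingularDesignError,
    UndefinedStatisticError,
    durbin_watson,
    evaluate_calibration,
    fit_functional,
    fit_ols,
    relative_se_b,
    residual_trend_test,
    t_critical,
)
from bapscal.calibration_fit import LinearFit


def _make_fit(b, se_b, a=0.0, se_a=0.0, df=7):
    return LinearFit(
        a=a, b=b, se_a=se_a, se_b=se_b, ci_a=(a, a), ci_b=(b, b),
        r_squared=1.0, residuals=np.zeros(df + 2), sigma2=0.0, dw=2.0, df=df,
    )


class TestFitOls:
    def test_exact_line(self, exact_line_dataset):
        fit = fit_ols(exact_line_dataset)
        assert fit.a == pytest.approx(1.0, abs=1e-12)
        assert fit.b == pytest.approx(2.0, abs=1e-12)
        assert fit.se_b == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_recovers_known_slope_within_ci(self):
        rng = np.random.default_rng(7)
        x = np.linspace(0.4, 2.0, 9)
        y = 700.0 + 250.0 * x + rng.normal(0.0, 0.4, size=9)
        fit = fit_ols(CalibrationDataset.from_arrays(x[:, None], y))
        assert fit.ci_b[0] <= 250.0 <= fit.ci_b[1]
        assert fit.df == 7

    def test_nine_points_use_t_crit_2365(self, noisy_pressure_dataset):
        fit = fit_ols(noisy_pressure_dataset)
        assert fit.df == 7
        width = fit.ci_b[1] - fit.ci_b[0]
        assert width == pytest.approx(2.0 * 2.364624251592784 * fit.se_b, rel=1e-12)

    def test_residuals_sum_to_zero(self, noisy_pressure_dataset):
        fit = fit_ols(noisy_pressure_dataset)
        assert abs(fit.residuals.sum()) < 1e-10

    def test_affine_rescaling_of_signal(self, noisy_pressure_dataset):
        """Rescaling x maps (a, b) through the corresponding affine transform."""
        alpha, beta = 3.7, -0.9
        fit = fit_ols(noisy_pressure_dataset)
        x = noisy_pressure_dataset.signal_means * alpha + beta
        y = noisy_pressure_dataset.measurands
        fit2 = fit_ols(CalibrationDataset.from_arrays(x[:, None], y))
        assert fit2.b == pytest.approx(fit.b / alpha, rel=1e-10)
        assert fit2.a == pytest.approx(fit.a - fit.b / alpha * beta, rel=1e-10)

    def test_constant_signal_is_singular(self):
        ds = CalibrationDataset.from_arrays([[1.0], [1.0], [1.0]], [1.0, 2.0, 3.0])
        with pytest.raises(SingularDesignError):
            fit_ols(ds)

    def test_needs_three_points(self):
        with pytest.raises(InsufficientDataError):
            CalibrationDataset.from_arrays([[0.0], [1.0]], [0.0, 1.0])


class TestTCritical:
    def test_df7_two_tailed_95(self):
        assert round(t_critical(7, 0.95), 3) == 2.365
        assert round(t_critical(7, 0.95), 2) == 2.36

    def test_normal_limit(self):
        assert t_critical(10**8, 0.95) == pytest.approx(1.960, abs=1e-3)

    def test_df1(self):
        assert t_critical(1, 0.95) == pytest.approx(12.706, abs=1e-3)

    def test_invalid_inputs(self):
        with pytest.raises(DomainError):
            t_critical(0)
        with pytest.raises(DomainError):
            t_critical(7, 1.5)


class TestDurbinWatson:
    def test_constant_residuals_give_zero(self):
        assert durbin_watson([0.5] * 6) == 0.0

    def test_alternating_residuals(self):
        assert durbin_watson([1.0, -1.0, 1.0, -1.0]) == pytest.approx(3.0)

    def test_white_noise_near_two(self):
        e = np.random.default_rng(0).normal(size=5000)
        assert durbin_watson(e) == pytest.approx(2.0, abs=0.1)

    def test_all_zero_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            durbin_watson([0.0, 0.0, 0.0])

    def test_needs_two_residuals(self):
        with pytest.raises(InsufficientDataError):
            durbin_watson([1.0])


class TestFunctionalModel:
    def test_identical_replicates_reduce_to_ols(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0.4, 2.0, 9)
        y = 700.0 + 250.0 * x + rng.normal(0.0, 0.4, size=9)
        z = np.repeat(x[:, None], 5, axis=1)
        ds = CalibrationDataset.from_arrays(z, y)
        ols, fun = fit_ols(ds), fit_functional(ds)
        assert fun.a == pytest.approx(ols.a, abs=1e-8)
        assert fun.b == pytest.approx(ols.b, abs=1e-8)
        assert fun.sigma_z2 == 0.0

    def test_close_to_ols_for_small_signal_noise(self):
        rng = np.random.default_rng(1)
        x = np.linspace(0.4, 2.0, 9)
        y = 700.0 + 250.0 * x + rng.normal(0.0, 0.4, size=9)
        z = x[:, None] + rng.normal(0.0, 0.002, size=(9, 10))
        ds = CalibrationDataset.from_arrays(z, y)
        ols, fun = fit_ols(ds), fit_functional(ds)
        assert fun.b == pytest.approx(ols.b, rel=1e-3)
        assert fun.x_hat.shape == (9,)

    def test_parameter_recovery(self):
        """Repeated fits on generative data centre on the true coefficients."""
        a_true, b_true, sigma, sigma_z = 700.0, 250.0, 0.4, 0.002
        x = np.linspace(0.4, 2.0, 9)
        est = np.empty((200, 2))
        for s in range(200):
            rng = np.random.default_rng(s)
            y = a_true + b_true * x + rng.normal(0.0, sigma, size=9)
            z = x[:, None] + rng.normal(0.0, sigma_z, size=(9, 10))
            f = fit_functional(CalibrationDataset.from_arrays(z, y))
            est[s] = (f.a, f.b)
        se = est.std(axis=0, ddof=1) / np.sqrt(200)
        assert abs(est[:, 0].mean() - a_true) < 3 * se[0]
        assert abs(est[:, 1].mean() - b_true) < 3 * se[1]

    def test_null_slope_centred_on_zero(self):
        x = np.linspace(0.4, 2.0, 9)
        slopes = []
        for s in range(100):
            rng = np.random.default_rng(1000 + s)
            y = 5.0 + rng.normal(0.0, 0.3, size=9)
            z = x[:, None] + rng.normal(0.0, 0.01, size=(9, 5))
            slopes.append(fit_functional(CalibrationDataset.from_arrays(z, y)).b)
        slopes = np.asarray(slopes)
        assert abs(slopes.mean()) < 3 * slopes.std(ddof=1) / 10

    def test_single_replicate_insufficient(self, noisy_pressure_dataset):
        with pytest.raises(InsufficientDataError):
            fit_functional(noisy_pressure_dataset)


class TestEvaluateCalibration:
    def test_raw_signal_identity_configuration(self):
        cal = PolynomialCalibration(a=0.0, b=1.0)
        assert evaluate_calibration(cal, 0.42) == 0.42

    def test_linear_pressure_calibration(self):
        cal = PolynomialCalibration(a=699.6, b=250.1)
        assert evaluate_calibration(cal, 1.2) == pytest.approx(999.72)

    def test_zero_polynomial(self):
        cal = PolynomialCalibration(a=0.0, b=0.0)
        assert evaluate_calibration(cal, 123.4) == 0.0

    def test_quartic_horner(self):
        cal = PolynomialCalibration(a=1.0, b=2.0, c=3.0, d=4.0, e=5.0)
        x = 0.7
        assert evaluate_calibration(cal, x) == pytest.approx(
            1 + 2 * x + 3 * x**2 + 4 * x**3 + 5 * x**4
        )

    def test_non_finite_signal_rejected(self):
        with pytest.raises(DomainError):
            evaluate_calibration(PolynomialCalibration(), float("nan"))


class TestRelativeSeB:
    @pytest.mark.parametrize(
        "se_b, b, lo, hi",
        [(1.04, 250.1, 0.41, 0.42), (0.0020, 0.52, 0.38, 0.39), (0.0, 5.0, 0.0, 0.0)],
    )
    def test_percent_of_slope(self, se_b, b, lo, hi):
        assert lo <= round(relative_se_b(_make_fit(b, se_b)), 2) <= hi

    def test_zero_slope_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            relative_se_b(_make_fit(0.0, 1.0))


class TestResidualTrend:
    def test_quadratic_response_flagged(self):
        x = np.linspace(0.4, 2.0, 9)
        y = -3.7 + 14.8 * x + 1.5 * x**2  # pronounced curvature, no noise
        ds = CalibrationDataset.from_arrays(
            x[:, None], y + np.random.default_rng(0).normal(0, 0.02, 9)
        )
        _, _, nonlinear = residual_trend_test(ds)
        assert nonlinear

    def test_error_rates_on_linear_and_curved_data(self):
        """Trend test keeps its size on straight lines and has power on curvature."""
        x = np.linspace(0.4, 2.0, 9)
        fp = tp = 0
        n = 200
        for s in range(n):
            rng = np.random.default_rng(s)
            noise = rng.normal(0.0, 0.05, size=9)
            lin = CalibrationDataset.from_arrays(x[:, None], -3.7 + 14.8 * x + noise)
            quad = CalibrationDataset.from_arrays(
                x[:, None], -3.7 + 14.8 * x + 0.6 * x**2 + noise
            )
            fp += residual_trend_test(lin)[2]
            tp += residual_trend_test(quad)[2]
        # size within a binomial 2-sigma band around alpha, power high
        assert fp / n <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n)
        assert tp / n > 0.9
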