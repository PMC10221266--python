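"""Calibration-function fitting and diagnostics.

Sensor calibration relates the raw voltage signal x to the measurand y
(pressure in hPa, O2 in Vol%, CO2 in umol mL-1) through a polynomial
``y = a + b x + c x^2 + d x^3 + e x^4``; in practice a straight line
suffices for all three BaPS sensors, so the workhorse here is ordinary
least squares on per-point signal means, with coefficient standard errors,
95% confidence intervals, residual diagnostics (Durbin-Watson, quadratic
trend check) and the residual variance.

Because the signal itself is noisy, OLS is cross-checked with the
*functional* errors-in-variables model: the true signal variates x_i are
fixed but unknown, observed l times each as z_ij = x_i + g_ij with
g ~ N(0, sigma_z^2), while y_i = a + b x_i + e_i with e ~ N(0, sigma^2).
All five parameter groups (a, b, sigma^2, sigma_z^2, x_1..x_k) are
estimated by maximum likelihood.  When the signal noise vanishes the
functional estimates coincide with OLS, which justifies the simpler model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    DomainError,
    FitFailureError,
    InsufficientDataError,
    SingularDesignError,
    UndefinedStatisticError,
)

__all__ = [
    "CalibrationPoint",
    "CalibrationDataset",
    "PolynomialCalibration",
    "LinearFit",
    "FunctionalFit",
    "fit_ols",
    "t_critical",
    "durbin_watson",
    "fit_functional",
    "evaluate_calibration",
    "relative_se_b",
    "residual_trend_test",
]

SENSOR_KINDS = ("pressure", "o2", "co2")

#: Measurand unit per sensor kind, for report labelling.
MEASURAND_UNITS = {"pressure": "hPa", "o2": "Vol%", "co2": "umol mL-1"}


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration level: replicate signal readings and the reference value.

    ``me_y`` is the standard deviation assigned to the reference measurand
    (0 when unknown).
    """

    signals_v: tuple[float, ...]
    measurand: float
    me_y: float = 0.0

    def __post_init__(self) -> None:
        if len(self.signals_v) < 1:
            raise InsufficientDataError("each calibration point needs >= 1 replicate")
        if self.me_y < 0:
            raise DomainError("me_y must be >= 0")

    @property
    def signal_mean(self) -> float:
        return float(np.mean(self.signals_v))


@dataclass(frozen=True)
class CalibrationDataset:
    """Paired signal replicates and reference measurands for one sensor."""

    points: tuple[CalibrationPoint, ...]
    sensor_kind: str = "pressure"

    def __post_init__(self) -> None:
        if self.sensor_kind not in SENSOR_KINDS:
            raise DomainError(f"sensor_kind must be one of {SENSOR_KINDS}")
        if len(self.points) < 3:
            raise InsufficientDataError("calibration needs at least 3 points")

    @property
    def k(self) -> int:
        """Number of calibration points."""
        return len(self.points)

    @property
    def signal_means(self) -> np.ndarray:
        return np.array([p.signal_mean for p in self.points])

    @property
    def measurands(self) -> np.ndarray:
        return np.array([p.measurand for p in self.points])

    @property
    def me_y(self) -> np.ndarray:
        return np.array([p.me_y for p in self.points])

    @classmethod
    def from_arrays(cls, signals, measurands, me_y=None, sensor_kind="pressure"):
        """Build a dataset from a (k, l) replicate matrix or a length-k vector."""
        signals = np.atleast_2d(np.asarray(signals, dtype=float))
        measurands = np.asarray(measurands, dtype=float)
        if signals.shape[0] != measurands.shape[0]:
            signals = signals.T
        me_y = np.zeros_like(measurands) if me_y is None else np.asarray(me_y, float)
        points = tuple(
            CalibrationPoint(tuple(row.tolist()), float(y), float(e))
            for row, y, e in zip(signals, measurands, me_y)
        )
        return cls(points=points, sensor_kind=sensor_kind)


@dataclass(frozen=True)
class PolynomialCalibration:
    """Quartic calibration function y = a + b x + c x^2 + d x^3 + e x^4."""

    a: float = 0.0
    b: float = 1.0
    c: float = 0.0
    d: float = 0.0
    e: float = 0.0

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.a, self.b, self.c, self.d, self.e])):
            raise DomainError("calibration coefficients must be finite")

    @property
    def is_linear(self) -> bool:
        return self.c == self.d == self.e == 0.0


@dataclass(frozen=True)
class LinearFit:
    """An OLS calibration line with its error statistics."""

    a: float
    b: float
    se_a: float
    se_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    r_squared: float
    residuals: np.ndarray
    sigma2: float
    dw: float
    df: int
    sensor_kind: str = "pressure"
    level: float = 0.95

    def predict(self, x) -> np.ndarray:
        return self.a + self.b * np.asarray(x, dtype=float)

    def as_calibration(self) -> PolynomialCalibration:
        return PolynomialCalibration(a=self.a, b=self.b)


@dataclass(frozen=True)
class FunctionalFit:
    """Maximum-likelihood fit of the functional errors-in-variables model."""

    a: float
    b: float
    sigma2: float
    sigma_z2: float
    x_hat: np.ndarray
    loglik: float
    n_iter: int = 0


def t_critical(df: int, level: float = 0.95) -> float:
    """Two-tailed Student-t critical value at the given confidence level."""
    if df < 1:
        raise DomainError("df must be >= 1")
    if not 0 < level < 1:
        raise DomainError("level must lie in (0, 1)")
    return float(stats.t.ppf(0.5 + level / 2.0, df))


def durbin_watson(residuals) -> float:
    """Durbin-Watson statistic sum((e_i - e_{i-1})^2) / sum(e_i^2).

    Residuals must be ordered by the regressor.  Values near 2 indicate no
    first-order autocorrelation; near 0, positive; near 4, negative.
    """
    e = np.asarray(residuals, dtype=float)
    if e.size < 2:
        raise InsufficientDataError("Durbin-Watson needs >= 2 residuals")
    denom = float(np.sum(e**2))
    if denom == 0.0:
        raise UndefinedStatisticError("Durbin-Watson undefined for all-zero residuals")
    return float(np.sum(np.diff(e) ** 2) / denom)


def fit_ols(ds: CalibrationDataset, level: float = 0.95) -> LinearFit:
    """Fit the calibration line y = a + b*x by ordinary least squares.

    Signal replicates are collapsed to their per-point mean.  Standard
    errors follow the classical OLS formulas with residual variance
    ``sigma2 = SSR/(k-2)``; confidence intervals are
    ``coef +/- t_crit(k-2, level) * se``.  Residuals (ordered by signal)
    also yield the Durbin-Watson statistic, reported as NaN when the fit is
    exact.
    """
    x = ds.signal_means
    y = ds.measurands
    k = ds.k
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise SingularDesignError("all calibration points share one signal level")

    b = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    a = float(y.mean() - b * x.mean())
    resid = y - (a + b * x)
    df = k - 2
    sigma2 = float(np.sum(resid**2) / df)
    se_b = float(np.sqrt(sigma2 / sxx))
    se_a = float(np.sqrt(sigma2 * (1.0 / k + x.mean() ** 2 / sxx)))
    tc = t_critical(df, level)

    syy = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if syy == 0.0 else 1.0 - float(np.sum(resid**2)) / syy

    order = np.argsort(x)
    e_ordered = resid[order]
    dw = float("nan") if np.all(e_ordered == 0.0) else durbin_watson(e_ordered)

    return LinearFit(
        a=a,
        b=b,
        se_a=se_a,
        se_b=se_b,
        ci_a=(a - tc * se_a, a + tc * se_a),
        ci_b=(b - tc * se_b, b + tc * se_b),
        r_squared=r2,
        residuals=resid,
        sigma2=sigma2,
        dw=dw,
        df=df,
        sensor_kind=ds.sensor_kind,
        level=level,
    )


def _profiled_x(a, b, s2, sz2, zbar, l, y):
    """ML values of the latent signal variates given the other parameters."""
    return (b * (y - a) / s2 + l * zbar / sz2) / (b**2 / s2 + l / sz2)


def _neg_loglik(theta, y, z, zbar, l):
    a, b, log_s2, log_sz2 = theta
    s2 = np.exp(log_s2)
    sz2 = np.exp(log_sz2)
    x = _profiled_x(a, b, s2, sz2, zbar, l, y)
    k = y.size
    ll = -0.5 * k * np.log(2 * np.pi * s2) - np.sum((y - a - b * x) ** 2) / (2 * s2)
    ll += -0.5 * k * l * np.log(2 * np.pi * sz2) - np.sum((z - x[:, None]) ** 2) / (
        2 * sz2
    )
    return -ll


def _deming_slope(zbar: np.ndarray, y: np.ndarray, delta: float) -> float:
    """ML slope of a line with errors in both variables, ratio delta = s2_y/s2_x."""
    xc = zbar - zbar.mean()
    yc = y - y.mean()
    sxx = float(np.sum(xc**2))
    syy = float(np.sum(yc**2))
    sxy = float(np.sum(xc * yc))
    if sxy == 0.0:
        return 0.0
    disc = syy - delta * sxx
    return (disc + np.sqrt(disc**2 + 4.0 * delta * sxy**2)) / (2.0 * sxy)


def fit_functional(
    ds: CalibrationDataset, tol: float = 1e-10, max_iter: int = 500
) -> FunctionalFit:
    """Fit the functional errors-in-variables model by maximum likelihood.

    Requires >= 2 replicates per point so that the signal-noise variance
    sigma_z^2 is identified — it is estimated from the within-point
    replicate scatter, the only part of the data that carries information
    about it independently of the line.  Given sigma_z^2, the ML
    stationarity equations are solved by iterating (i) the
    errors-in-variables (Deming) slope on the per-point signal means with
    error-variance ratio delta = sigma^2 / (sigma_z^2 / l) and (ii) the
    moment update sigma^2 = SSR/(k-2) - b^2 sigma_z^2 / l, until the
    log-likelihood changes by less than ``tol``.  The latent variates x_i
    are profiled in closed form.

    The joint likelihood over (a, b, sigma^2, sigma_z^2, x_1..x_k) is
    unbounded (sigma^2 -> 0 with x_i chasing an exact fit), a classical
    property of functional-model likelihoods; the iteration above returns
    the interior stationary point, which is the conventional
    functional-model estimate and collapses onto OLS as the replicate
    scatter vanishes.
    """
    l_counts = {len(p.signals_v) for p in ds.points}
    if min(l_counts) < 2:
        raise InsufficientDataError(
            "functional model needs >= 2 signal replicates per point"
        )
    if len(l_counts) > 1:
        raise InsufficientDataError(
            "functional model requires a balanced replicate count"
        )
    l = l_counts.pop()
    z = np.array([p.signals_v for p in ds.points], dtype=float)
    zbar = z.mean(axis=1)
    y = ds.measurands
    k = ds.k

    ols = fit_ols(ds)
    ssw = float(np.sum((z - zbar[:, None]) ** 2))
    sz2 = ssw / (k * (l - 1))  # within-replicate signal-noise variance
    scale_z2 = float(np.var(zbar)) + 1e-30
    if sz2 <= 1e-14 * scale_z2:
        # replicates are identical: the EIV model degenerates to OLS
        return FunctionalFit(
            a=ols.a,
            b=ols.b,
            sigma2=max(ols.sigma2 * (k - 2) / k, 0.0),
            sigma_z2=0.0,
            x_hat=zbar.copy(),
            loglik=float("inf"),
        )

    tau2 = sz2 / l  # error variance of the mean signal
    a, b = ols.a, ols.b
    s2 = max(ols.sigma2, 1e-30)
    prev_ll = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        delta = s2 / tau2
        b = _deming_slope(zbar, y, delta)
        a = float(y.mean() - b * zbar.mean())
        ssr = float(np.sum((y - a - b * zbar) ** 2))
        # residual variance about the means contains sigma^2 + b^2*tau2
        s2 = max(ssr / max(k - 2, 1) - b**2 * tau2, 1e-12 * (float(np.var(y)) + 1e-30))
        ll = -_neg_loglik(np.array([a, b, np.log(s2), np.log(sz2)]), y, z, zbar, l)
        if abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
            prev_ll = ll
            break
        prev_ll = ll
    else:  # pragma: no cover - iteration is contractive in practice
        raise FitFailureError(
            f"functional-model iteration did not converge in {max_iter} steps"
        )

    x_hat = _profiled_x(a, b, s2, sz2, zbar, l, y)
    return FunctionalFit(
        a=float(a),
        b=float(b),
        sigma2=float(s2),
        sigma_z2=float(sz2),
        x_hat=np.asarray(x_hat),
        loglik=float(prev_ll),
        n_iter=n_iter,
    )


def evaluate_calibration(cal: PolynomialCalibration, signal):
    """Evaluate the quartic calibration polynomial at a signal (Horner form)."""
    x = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DomainError("signal must be finite")
    result = cal.a + x * (cal.b + x * (cal.c + x * (cal.d + x * cal.e)))
    return float(result) if np.isscalar(signal) else result


def relative_se_b(fit: LinearFit) -> float:
    """Relative standard error of the slope, 100*se_b/|b|, in percent."""
    if fit.b == 0:
        raise UndefinedStatisticError("relative slope error undefined for b = 0")
    return 100.0 * fit.se_b / abs(fit.b)


def residual_trend_test(ds: CalibrationDataset, alpha: float = 0.05):
    """Check the linear calibration for residual curvature.

    Fits y = a + b*x + c*x^2 on the per-point signal means and performs a
    Wald t-test on the quadratic coefficient.  Returns
    ``(t_statistic, p_value, nonlinear)`` where ``nonlinear`` is True when
    the quadratic term is significant at ``alpha`` — evidence that the
    straight-line calibration is inadequate.
    """
    x = ds.signal_means
    y = ds.measurands
    k = ds.k
    if k < 4:
        raise InsufficientDataError("curvature test needs >= 4 points")
    X = np.column_stack([np.ones(k), x, x**2])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        raise SingularDesignError("signal levels do not identify a quadratic term")
    resid = y - X @ coef
    df = k - 3
    s2 = float(np.sum(resid**2) / df)
    cov = s2 * np.linalg.inv(X.T @ X)
    se_c = float(np.sqrt(cov[2, 2]))
    if se_c == 0.0:
        raise UndefinedStatisticError("quadratic coefficient has zero standard error")
    t_stat = float(coef[2] / se_c)
    p = 2.0 * float(stats.t.sf(abs(t_stat), df))
    return t_stat, p, p < alpha
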