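"""Calibration validation against reference gases and temporal stability.

A fresh calibration is cross-checked by flushing the chamber with two
certified reference gas mixtures, relating the recorded signal means to
the known concentrations, and comparing the resulting two-point slope with
the calibration slope via a t statistic on the slope's standard error.

Repeated calibrations over the years form a coefficient history whose
summary statistics (mean, s.d., CV%) and monotone-trend classification
distinguish a *stable* sensor from one with *signal-strength drift*
(intercept trending, slope steady — typically early aging) or *response
drift* (slope trending — sensitivity loss requiring replacement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calibration_fit import LinearFit, t_critical
from .errors import DomainError, InsufficientDataError, UndefinedStatisticError

__all__ = [
    "ReferenceGas",
    "SlopeComparison",
    "CoefficientSummary",
    "StabilityRecord",
    "reference_slope",
    "slope_comparison_test",
    "stability_summary",
    "classify_drift",
    "mann_kendall",
    "DRIFT_CLASSES",
]

DRIFT_CLASSES = ("stable", "signal-strength drift", "response drift")


@dataclass(frozen=True)
class ReferenceGas:
    """A certified reference mixture: O2 and CO2 in Vol%, remainder N2."""

    frac_O2: float
    frac_CO2: float
    rel_accuracy: float = 0.02
    label: str = ""

    def __post_init__(self) -> None:
        if self.frac_O2 < 0 or self.frac_CO2 < 0:
            raise DomainError("fractions must be >= 0")
        if self.frac_O2 + self.frac_CO2 > 100.0:
            raise DomainError("O2 + CO2 cannot exceed 100 Vol%")

    @property
    def frac_N2(self) -> float:
        return 100.0 - self.frac_O2 - self.frac_CO2


@dataclass(frozen=True)
class SlopeComparison:
    """Outcome of the calibration-slope vs reference-slope check."""

    t: float
    t_crit: float
    significant: bool
    difference: float
    within_ci: bool
    alpha: float


@dataclass(frozen=True)
class CoefficientSummary:
    mean: float
    sd: float
    cv_pct: float


@dataclass(frozen=True)
class StabilityRecord:
    """Summary of a dated calibration-coefficient series for one sensor."""

    entries: pd.DataFrame
    summary_a: CoefficientSummary
    summary_b: CoefficientSummary
    drift_class: str | None = None


def reference_slope(pairs) -> float:
    """Two-point slope (d measurand / d signal) from two reference-gas readings.

    ``pairs`` is a sequence of two (signal_mean_v, known_concentration)
    tuples.  The slope has measurand units per volt.
    """
    (x1, y1), (x2, y2) = pairs
    if x1 == x2:
        raise UndefinedStatisticError("reference signals are identical; slope undefined")
    return (y2 - y1) / (x2 - x1)


def slope_comparison_test(
    fit: LinearFit, ref_slope: float, alpha: float = 0.05
) -> SlopeComparison:
    """Compare the calibration slope with a reference-gas slope.

    Computes ``t = |b - ref_slope| / se_b`` against the two-tailed critical
    value at ``fit.df`` degrees of freedom, and additionally reports
    whether the reference slope falls within the fitted slope's confidence
    interval.  The test is symmetric in the sign of the difference.
    """
    if fit.se_b <= 0:
        raise UndefinedStatisticError("slope test degenerate: se_b must be > 0")
    diff = fit.b - ref_slope
    t = abs(diff) / fit.se_b
    tc = t_critical(fit.df, 1.0 - alpha)
    within = fit.ci_b[0] <= ref_slope <= fit.ci_b[1]
    return SlopeComparison(
        t=float(t),
        t_crit=tc,
        significant=bool(t > tc),
        difference=float(diff),
        within_ci=bool(within),
        alpha=alpha,
    )


def _summarize(values: np.ndarray) -> CoefficientSummary:
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    cv = 100.0 * sd / abs(mean) if mean != 0 else float("inf")
    return CoefficientSummary(mean=mean, sd=sd, cv_pct=cv)


def _as_history(entries) -> pd.DataFrame:
    df = pd.DataFrame(entries, columns=["date", "a", "b"]) if not isinstance(
        entries, pd.DataFrame
    ) else entries[["date", "a", "b"]].copy()
    df["date"] = pd.to_datetime(df["date"])
    return df.sort_values("date").reset_index(drop=True)


def stability_summary(entries) -> StabilityRecord:
    """Per-coefficient mean, sample s.d. (n-1) and CV% of a dated (a, b) series.

    The CV denominator uses |mean| so that negative intercepts still yield
    a positive relative variability.
    """
    df = _as_history(entries)
    if len(df) < 2:
        raise InsufficientDataError("stability summary needs >= 2 calibrations")
    return StabilityRecord(
        entries=df,
        summary_a=_summarize(df["a"].to_numpy()),
        summary_b=_summarize(df["b"].to_numpy()),
    )


def mann_kendall(values, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Mann-Kendall monotone-trend test.

    Returns ``(s_statistic, p_value, significant)``.  Implemented through
    Kendall's tau of the series against its time order, which shares the S
    statistic and p-value with the classical formulation.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise InsufficientDataError("trend test needs >= 4 entries")
    res = stats.kendalltau(np.arange(v.size), v)
    if np.isnan(res.statistic):  # constant series: no trend
        return 0.0, 1.0, False
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha)


def classify_drift(entries, alpha: float = 0.05) -> str:
    """Classify a coefficient history as stable / signal-strength drift / response drift.

    A monotone trend in the slope series b signals *response drift*
    (changed sensitivity, the severe case, checked first); a trend in the
    intercept series a alone signals *signal-strength drift* (offset
    wandering, typically incipient aging); otherwise the sensor is
    *stable*.  Because two series are tested, each trend test runs at
    alpha/2 (Bonferroni) so the overall false-alarm probability on a
    stable sensor stays at ``alpha``.
    """
    df = _as_history(entries)
    if len(df) < 4:
        raise InsufficientDataError("drift classification needs >= 4 calibrations")
    _, _, trend_a = mann_kendall(df["a"].to_numpy(), alpha=alpha / 2.0)
    _, _, trend_b = mann_kendall(df["b"].to_numpy(), alpha=alpha / 2.0)
    if trend_b:
        return "response drift"
    if trend_a:
        return "signal-strength drift"
    return "stable"
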