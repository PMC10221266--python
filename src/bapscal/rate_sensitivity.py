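"""Simplified turnover-rate model and calibration-sensitivity analysis.

A BaPS incubation separates microbial respiration from gross nitrification
by balancing the chamber's gas budget,

    dn = dO2 + dCO2 + dX,

where dn is the change of the total molecule number (from P, T, V_head via
the ideal gas law), dO2 and dCO2 the changes of the species pools, and dX
the residual of other gases.  Respiration consumes O2 and produces CO2 in
the ratio of the respiratory quotient RQ; nitrification consumes O2
without producing CO2.  The model implemented here is a deliberately
simple separation:

  * total CO2 production = headspace dCO2 + a dissolved flux given by the
    soil solution's CO2 dissolution capacity spread over the analysis
    window;
  * respiratory O2 consumption = CO2 production / RQ;
  * the remaining O2 consumption is attributed to nitrification at a fixed
    stoichiometry (default 2 mol O2 per mol N, NH4+ + 2 O2 -> NO3- + H2O +
    2 H+).

It is *not* the manufacturer's full rate algorithm (which additionally
models carbonate chemistry and N-gas sources); it exists to quantify how
calibration-coefficient perturbations propagate into rates, for which a
transparent, documented forward model is what matters.  All assumptions
are carried in :class:`SoilParams` and echoed in reports.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .calibration_fit import PolynomialCalibration, evaluate_calibration
from .constants import M_C, M_N, PA_PER_HPA, R
from .errors import DomainError, InsufficientDataError

__all__ = [
    "IncubationSeries",
    "SoilParams",
    "RateResult",
    "GasBalanceTerms",
    "gas_balance_terms",
    "turnover_rates",
    "perturbation_sensitivity",
    "multi_calibration_summary",
    "apply_calibrations",
]


@dataclass(frozen=True)
class SoilParams:
    """Soil and stoichiometry parameters of the simplified rate model."""

    RQ: float = 0.84  # mol CO2 produced per mol O2 respired
    co2_dissolution_capacity: float = 0.33  # mmol CO2 per L soil solution
    soil_solution_volume: float = 0.25  # L
    soil_dry_weight: float = 1.0  # kg
    nitrification_O2_stoich: float = 2.0  # mol O2 per mol N oxidized

    def __post_init__(self) -> None:
        if self.RQ <= 0 or self.nitrification_O2_stoich <= 0:
            raise DomainError("RQ and nitrification stoichiometry must be > 0")
        if self.soil_dry_weight <= 0 or self.soil_solution_volume < 0:
            raise DomainError("soil dry weight must be > 0 and solution volume >= 0")
        if self.co2_dissolution_capacity < 0:
            raise DomainError("dissolution capacity must be >= 0")


@dataclass(frozen=True)
class IncubationSeries:
    """Calibrated incubation time series.

    ``data`` columns: ``timestamp_h``, ``p_hpa``, ``t_head_k``, ``t_soil_k``,
    ``o2_volpct``, ``co2_umol_ml``.  ``V_head_ml`` is the chamber headspace
    volume.
    """

    data: pd.DataFrame
    V_head_ml: float

    REQUIRED = ("timestamp_h", "p_hpa", "t_head_k", "o2_volpct", "co2_umol_ml")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise DomainError(f"incubation series missing columns: {missing}")
        t = self.data["timestamp_h"].to_numpy()
        if t.size < 2:
            raise InsufficientDataError("incubation series needs >= 2 time points")
        if np.any(np.diff(t) <= 0):
            raise DomainError("timestamps must be strictly increasing")
        if self.V_head_ml <= 0:
            raise DomainError("V_head must be > 0")
        phys = {
            "p_hpa": (500.0, 1500.0),
            "t_head_k": (250.0, 350.0),
            "o2_volpct": (0.0, 100.0),
            "co2_umol_ml": (-0.01, 10.0),
        }
        for col, (lo, hi) in phys.items():
            v = self.data[col].to_numpy()
            if np.any(v < lo) or np.any(v > hi):
                raise DomainError(f"column {col} outside physical range [{lo}, {hi}]")

    @property
    def duration_h(self) -> float:
        t = self.data["timestamp_h"].to_numpy()
        return float(t[-1] - t[0])


@dataclass(frozen=True)
class GasBalanceTerms:
    """OLS slopes of the molecule-number series, in umol h-1."""

    delta_n: float
    delta_O2: float
    delta_CO2: float
    delta_X: float


@dataclass(frozen=True)
class RateResult:
    """Separated turnover rates with the underlying gas-balance terms."""

    respiration: float  # ugC kg-1 sdw h-1
    gross_nitrification: float  # ugN kg-1 sdw h-1
    delta_n: float  # umol h-1
    delta_O2: float
    delta_CO2: float
    delta_X: float
    co2_production_total: float  # umol h-1, gaseous + dissolved
    negative_rate_flag: bool = False


def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    t = t - t.mean()
    return float(np.sum(t * (y - y.mean())) / np.sum(t**2))


def gas_balance_terms(series: IncubationSeries) -> GasBalanceTerms:
    """Gas-balance slopes dn, dO2, dCO2 and the residual dX in umol h-1.

    The total molecule number n(t) follows from the ideal gas law on P, T
    and V_head; the species amounts from the calibrated concentrations.
    Slopes are estimated by OLS over the full analysis window, and dX is
    defined by closure of the balance.
    """
    d = series.data
    t = d["timestamp_h"].to_numpy(dtype=float)
    V_m3 = series.V_head_ml * 1e-6
    P = d["p_hpa"].to_numpy(dtype=float) * PA_PER_HPA
    T = d["t_head_k"].to_numpy(dtype=float)

    n_umol = P * V_m3 / (R * T) * 1e6
    n_o2_umol = d["o2_volpct"].to_numpy(dtype=float) / 100.0 * n_umol
    n_co2_umol = d["co2_umol_ml"].to_numpy(dtype=float) * series.V_head_ml

    dn = _ols_slope(t, n_umol)
    do2 = _ols_slope(t, n_o2_umol)
    dco2 = _ols_slope(t, n_co2_umol)
    return GasBalanceTerms(
        delta_n=dn, delta_O2=do2, delta_CO2=dco2, delta_X=dn - do2 - dco2
    )


def turnover_rates(series: IncubationSeries, soil: SoilParams) -> RateResult:
    """Separate respiration and gross nitrification from an incubation series.

    Total CO2 production combines the headspace dCO2 slope with the
    dissolved-CO2 flux (dissolution capacity x soil-solution volume,
    applied uniformly over the analysis window).  Respiratory O2
    consumption is CO2 production / RQ; any excess O2 consumption is
    attributed to nitrification and converted with the configured O2:N
    stoichiometry.  Rates are normalized to soil dry weight.  Negative
    computed rates are reported with ``negative_rate_flag`` set, never
    clipped.
    """
    terms = gas_balance_terms(series)
    dur = series.duration_h

    co2_aq_umol_h = (
        soil.co2_dissolution_capacity * 1000.0 * soil.soil_solution_volume / dur
    )
    co2_production = terms.delta_CO2 + co2_aq_umol_h  # umol h-1
    o2_consumption = -terms.delta_O2  # umol h-1, positive when O2 declines
    o2_respiratory = co2_production / soil.RQ
    o2_nitrification = o2_consumption - o2_respiratory
    nitrif_n_umol_h = o2_nitrification / soil.nitrification_O2_stoich

    respiration = co2_production * M_C / soil.soil_dry_weight  # ug C kg-1 h-1
    nitrification = nitrif_n_umol_h * M_N / soil.soil_dry_weight  # ug N kg-1 h-1

    return RateResult(
        respiration=respiration,
        gross_nitrification=nitrification,
        delta_n=terms.delta_n,
        delta_O2=terms.delta_O2,
        delta_CO2=terms.delta_CO2,
        delta_X=terms.delta_X,
        co2_production_total=co2_production,
        negative_rate_flag=bool(respiration < 0 or nitrification < 0),
    )


def apply_calibrations(
    raw: pd.DataFrame,
    cal_pressure: PolynomialCalibration,
    cal_o2: PolynomialCalibration,
    cal_co2: PolynomialCalibration,
    V_head_ml: float,
) -> IncubationSeries:
    """Convert a raw-signal incubation log into a calibrated series.

    ``raw`` columns: ``timestamp_h``, ``p_signal_v``, ``o2_signal_v``,
    ``co2_signal_v``, ``t_head_k`` (and optionally ``t_soil_k``).
    """
    required = ("timestamp_h", "p_signal_v", "o2_signal_v", "co2_signal_v", "t_head_k")
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise DomainError(f"raw incubation log missing columns: {missing}")
    data = pd.DataFrame(
        {
            "timestamp_h": raw["timestamp_h"],
            "p_hpa": evaluate_calibration(cal_pressure, raw["p_signal_v"].to_numpy()),
            "t_head_k": raw["t_head_k"],
            "t_soil_k": raw.get("t_soil_k", raw["t_head_k"]),
            "o2_volpct": evaluate_calibration(cal_o2, raw["o2_signal_v"].to_numpy()),
            "co2_umol_ml": evaluate_calibration(cal_co2, raw["co2_signal_v"].to_numpy()),
        }
    )
    return IncubationSeries(data=data, V_head_ml=V_head_ml)


def perturbation_sensitivity(
    raw: pd.DataFrame,
    base_calibrations: dict[str, PolynomialCalibration],
    perturbations,
    soil: SoilParams,
    V_head_ml: float,
) -> pd.DataFrame:
    """Rate deviations under perturbed calibration coefficients.

    ``perturbations`` is a sequence of records
    ``{"label": str, "sensor": "pressure"|"o2"|"co2", "da": float, "db": float}``
    (da and db in measurand units / measurand units per volt).  For each
    record the named sensor's calibration is shifted, the rates are
    recomputed from the raw signals, and the absolute and percentage
    deviations from the base rates are tabulated.
    """
    base_series = apply_calibrations(
        raw,
        base_calibrations["pressure"],
        base_calibrations["o2"],
        base_calibrations["co2"],
        V_head_ml,
    )
    base = turnover_rates(base_series, soil)

    rows = []
    for p in perturbations:
        cals = dict(base_calibrations)
        c = cals[p["sensor"]]
        cals[p["sensor"]] = replace(
            c, a=c.a + p.get("da", 0.0), b=c.b + p.get("db", 0.0)
        )
        series = apply_calibrations(
            raw, cals["pressure"], cals["o2"], cals["co2"], V_head_ml
        )
        r = turnover_rates(series, soil)
        rows.append(
            {
                "label": p.get("label", f"{p['sensor']} perturbation"),
                "sensor": p["sensor"],
                "da": p.get("da", 0.0),
                "db": p.get("db", 0.0),
                "respiration": r.respiration,
                "nitrification": r.gross_nitrification,
                "d_respiration": r.respiration - base.respiration,
                "d_nitrification": r.gross_nitrification - base.gross_nitrification,
                "d_respiration_pct": 100.0
                * (r.respiration - base.respiration)
                / abs(base.respiration)
                if base.respiration != 0
                else float("nan"),
                "d_nitrification_pct": 100.0
                * (r.gross_nitrification - base.gross_nitrification)
                / abs(base.gross_nitrification)
                if base.gross_nitrification != 0
                else float("nan"),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["base_respiration"] = base.respiration
    out.attrs["base_nitrification"] = base.gross_nitrification
    return out


def multi_calibration_summary(rates) -> tuple[float, float, float]:
    """Mean, sample s.d. (n-1) and CV% of rates computed under several calibrations.

    ``rates`` may be scalars or :class:`RateResult` objects (in which case
    pass the attribute of interest beforehand).
    """
    values = np.asarray(
        [r.respiration if isinstance(r, RateResult) else float(r) for r in rates],
        dtype=float,
    )
    if values.size < 2:
        raise InsufficientDataError("summary needs >= 2 rates")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    cv = 100.0 * sd / abs(mean) if mean != 0 else float("inf")
    return mean, sd, cv
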