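"""Synthetic forward models: calibration runs, coefficient histories, incubations.

Everything the analysis modules consume can be generated here with known
ground truth: calibration datasets built by running the gas-exchange
protocol, inverting a true sensor response to signals and adding replicate
noise; dated coefficient histories with controlled drift in intercept
(signal strength) or slope (response); and incubation time series forward-
integrated from known respiration and nitrification rates, so that the
rate model can be validated by round trip.

Determinism: one :class:`numpy.random.SeedSequence` per run, with child
streams spawned per sensor in a fixed order, so a fixed seed yields
bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration_fit import CalibrationDataset, PolynomialCalibration
from .constants import M_C, M_N, PA_PER_HPA, R
from .errors import DomainError
from .gas_model import CalibrationProtocol
from .gas_model import run_protocol
from .rate_sensitivity import IncubationSeries, SoilParams

__all__ = [
    "SensorTruth",
    "SimConfig",
    "DEFAULT_TRUTHS",
    "signal_from_measurand",
    "simulate_calibration_run",
    "simulate_coefficient_history",
    "simulate_incubation",
]


@dataclass(frozen=True)
class SensorTruth:
    """Generative sensor response y = a + b x (+ c x^2) with noise and drift.

    ``me_x_true`` is the signal noise s.d. in volts; ``drift_a`` and
    ``drift_b`` are relative coefficient drifts per year used by the
    history generator; ``nonlin_c`` adds mild curvature for exercising the
    linearity diagnostics (zero by default — the straight line is adequate
    for all three sensors in practice).
    """

    a_true: float
    b_true: float
    nonlin_c: float = 0.0
    me_x_true: float = 0.0
    drift_a: float = 0.0
    drift_b: float = 0.0

    def __post_init__(self) -> None:
        if self.me_x_true < 0:
            raise DomainError("me_x_true must be >= 0")
        if self.b_true == 0:
            raise DomainError("b_true must be nonzero")


#: Typical instrument responses and noise floors (a, b in measurand units
#: and measurand units per volt; noise 0.2 mV pressure, 0.15 mV O2, 7 mV CO2).
DEFAULT_TRUTHS = {
    "pressure": SensorTruth(a_true=699.6, b_true=250.1, me_x_true=0.0002),
    "o2": SensorTruth(a_true=-3.69, b_true=14.83, me_x_true=0.00015),
    "co2": SensorTruth(a_true=-0.015, b_true=0.52, me_x_true=0.007),
}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a simulated calibration run."""

    seed: int = 0
    n_points: int = 9
    replicates_per_point: int = 10
    protocol: CalibrationProtocol = field(default_factory=CalibrationProtocol)
    me_y_sd: dict = field(default_factory=dict)  # measurand error s.d. per sensor
    pressure_range_hpa: tuple[float, float] = (990.0, 1030.0)

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise DomainError("n_points must be >= 3")
        if self.replicates_per_point < 1:
            raise DomainError("replicates_per_point must be >= 1")


def signal_from_measurand(truth: SensorTruth, y) -> np.ndarray:
    """Invert the true sensor response to the signal that produces ``y``.

    For a linear truth this is (y - a)/b; with curvature the quadratic is
    solved for the root continuous with the linear case.
    """
    y = np.asarray(y, dtype=float)
    if truth.nonlin_c == 0.0:
        return (y - truth.a_true) / truth.b_true
    a, b, c = truth.a_true - y, truth.b_true, truth.nonlin_c
    disc = b**2 - 4 * c * a
    if np.any(disc < 0):
        raise DomainError("measurand outside the range of the quadratic response")
    # root that tends to (y - a)/b as c -> 0
    return (-b + np.sqrt(disc)) / (2 * c)


def _sensor_streams(seed: int, names=("pressure", "o2", "co2")):
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def simulate_calibration_run(
    truths: dict[str, SensorTruth] | None = None, cfg: SimConfig = SimConfig()
):
    """Simulate one full calibration of all three sensors.

    The O2/CO2 measurands come from running the gas-exchange protocol
    (``cfg.n_points - 1`` exchanges, step 0 included); pressure levels span
    ``cfg.pressure_range_hpa`` uniformly.  True signals are obtained by
    inverting the true responses, then each point is logged
    ``replicates_per_point`` times with N(0, me_x_true) noise.  Optional
    reference-value errors N(0, me_y_sd[sensor]) shift each measurand and
    are recorded as the point's me_y.

    Returns ``(log, datasets)``: a tidy sensor-log DataFrame (columns
    ``timestamp``, ``sensor_id``, ``signal_v``) and a dict of
    :class:`CalibrationDataset` per sensor.
    """
    truths = dict(DEFAULT_TRUTHS) if truths is None else truths
    rngs = _sensor_streams(cfg.seed)

    protocol = CalibrationProtocol(
        initial=cfg.protocol.initial,
        injected=cfg.protocol.injected,
        n_steps=cfg.n_points - 1,
        dP_pa=cfg.protocol.dP_pa,
        P_pa=cfg.protocol.P_pa,
        T_k=cfg.protocol.T_k,
        V_head_m3=cfg.protocol.V_head_m3,
    )
    conc = run_protocol(protocol)
    measurands = {
        "pressure": np.linspace(*cfg.pressure_range_hpa, cfg.n_points),
        "o2": conc["o2_volpct"],
        "co2": conc["co2_umol_ml"],
    }

    datasets: dict[str, CalibrationDataset] = {}
    log_rows = []
    t0 = pd.Timestamp("2015-07-01 09:00:00")
    minute = 0
    for sensor, truth in truths.items():
        rng = rngs[sensor]
        y_true = measurands[sensor]
        me_y_sd = float(cfg.me_y_sd.get(sensor, 0.0))
        y_obs = y_true + (
            rng.normal(0.0, me_y_sd, size=y_true.shape) if me_y_sd > 0 else 0.0
        )
        x_true = signal_from_measurand(truth, y_true)
        z = x_true[:, None] + (
            rng.normal(0.0, truth.me_x_true, size=(y_true.size, cfg.replicates_per_point))
            if truth.me_x_true > 0
            else np.zeros((y_true.size, cfg.replicates_per_point))
        )
        datasets[sensor] = CalibrationDataset.from_arrays(
            z, y_obs, me_y=np.full(y_true.shape, me_y_sd), sensor_kind=sensor
        )
        for i in range(y_true.size):
            for j in range(cfg.replicates_per_point):
                log_rows.append(
                    {
                        "timestamp": (t0 + pd.Timedelta(minutes=minute)).isoformat(),
                        "sensor_id": sensor,
                        "signal_v": z[i, j],
                    }
                )
                minute += 1
    return pd.DataFrame(log_rows), datasets


def simulate_coefficient_history(
    truth: SensorTruth,
    n_years: float = 4.0,
    per_year_calibrations: int = 2,
    seed: int = 0,
    scatter_a: float = 0.0,
    scatter_b: float = 0.0,
    start="2012-05-01",
) -> pd.DataFrame:
    """A dated (a, b) calibration series with controlled drift and scatter.

    Coefficients drift linearly in time at the relative per-year rates
    ``truth.drift_a`` / ``truth.drift_b``; ``scatter_a`` / ``scatter_b``
    add independent between-calibration noise (absolute s.d.).
    """
    n = int(round(n_years * per_year_calibrations))
    if n < 2:
        raise DomainError("history needs >= 2 calibrations")
    rng = np.random.default_rng(seed)
    years = np.linspace(0.0, n_years, n)
    a = truth.a_true * (1.0 + truth.drift_a * years)
    b = truth.b_true * (1.0 + truth.drift_b * years)
    if scatter_a > 0:
        a = a + rng.normal(0.0, scatter_a, size=n)
    if scatter_b > 0:
        b = b + rng.normal(0.0, scatter_b, size=n)
    dates = pd.Timestamp(start) + pd.to_timedelta(years * 365.25, unit="D")
    return pd.DataFrame({"date": dates, "a": a, "b": b})


def simulate_incubation(
    respiration: float,
    gross_nitrification: float,
    soil: SoilParams,
    truths: dict[str, SensorTruth] | None = None,
    seed: int = 0,
    duration_h: float = 24.0,
    n_samples: int = 145,
    P0_hpa: float = 1013.25,
    T_k: float = 293.15,
    V_head_ml: float = 1000.0,
    o2_0_volpct: float = 20.5,
    co2_0_umol_ml: float = 0.02,
    delta_X_umol_h: float = 0.0,
    noise: bool = True,
):
    """Forward-simulate a BaPS incubation with known turnover rates.

    Integrates the constant molar fluxes implied by ``respiration``
    (ugC kg-1 sdw h-1) and ``gross_nitrification`` (ugN kg-1 sdw h-1)
    under the same separation model the rate module inverts: total CO2
    production splits into a headspace flux and the dissolved flux set by
    the soil's dissolution capacity over the window; O2 consumption is the
    respiratory part (CO2/RQ) plus the nitrification demand (stoichiometry
    x N rate).  The resulting state series is converted to true measurands,
    then to raw signals through the true sensor responses, with
    N(0, me_x_true) noise unless ``noise=False``.

    Returns ``(raw, truth_series)``: the raw-signal DataFrame and the
    noise-free calibrated :class:`IncubationSeries`.
    """
    if duration_h <= 0 or n_samples < 2:
        raise DomainError("need positive duration and >= 2 samples")
    truths = dict(DEFAULT_TRUTHS) if truths is None else truths
    rngs = _sensor_streams(seed)

    co2_prod_umol_h = respiration * soil.soil_dry_weight / M_C
    co2_aq_umol_h = (
        soil.co2_dissolution_capacity * 1000.0 * soil.soil_solution_volume / duration_h
    )
    co2_gas_umol_h = co2_prod_umol_h - co2_aq_umol_h
    o2_resp_umol_h = co2_prod_umol_h / soil.RQ
    o2_nit_umol_h = (
        gross_nitrification
        * soil.soil_dry_weight
        / M_N
        * soil.nitrification_O2_stoich
    )
    d_o2 = -(o2_resp_umol_h + o2_nit_umol_h)
    d_n = d_o2 + co2_gas_umol_h + delta_X_umol_h

    t = np.linspace(0.0, duration_h, n_samples)
    V_m3 = V_head_ml * 1e-6
    n0_umol = P0_hpa * PA_PER_HPA * V_m3 / (R * T_k) * 1e6
    n_umol = n0_umol + d_n * t
    n_o2 = o2_0_volpct / 100.0 * n0_umol + d_o2 * t
    n_co2 = co2_0_umol_ml * V_head_ml + co2_gas_umol_h * t
    if n_o2.min() < 0 or n_co2.min() < 0 or n_umol.min() <= 0:
        raise DomainError("rates deplete a gas pool within the simulated window")

    p_hpa = n_umol * 1e-6 * R * T_k / V_m3 / PA_PER_HPA
    o2_volpct = n_o2 / n_umol * 100.0
    co2_umol_ml = n_co2 / V_head_ml
    co2_volpct = co2_umol_ml * R * T_k / (p_hpa * PA_PER_HPA) * 100.0
    if co2_volpct.max() > 3.0:
        warnings.warn(
            "simulated CO2 exceeds the 3 Vol% sensor range; readings beyond "
            "it would be truncated on the real instrument",
            stacklevel=2,
        )

    truth_series = IncubationSeries(
        data=pd.DataFrame(
            {
                "timestamp_h": t,
                "p_hpa": p_hpa,
                "t_head_k": np.full_like(t, T_k),
                "t_soil_k": np.full_like(t, T_k),
                "o2_volpct": o2_volpct,
                "co2_umol_ml": co2_umol_ml,
            }
        ),
        V_head_ml=V_head_ml,
    )

    def to_signal(sensor: str, y: np.ndarray) -> np.ndarray:
        truth = truths[sensor]
        x = signal_from_measurand(truth, y)
        if noise and truth.me_x_true > 0:
            x = x + rngs[sensor].normal(0.0, truth.me_x_true, size=x.shape)
        return x

    raw = pd.DataFrame(
        {
            "timestamp_h": t,
            "p_signal_v": to_signal("pressure", p_hpa),
            "o2_signal_v": to_signal("o2", o2_volpct),
            "co2_signal_v": to_signal("co2", co2_umol_ml),
            "t_head_k": np.full_like(t, T_k),
            "t_soil_k": np.full_like(t, T_k),
        }
    )
    return raw, truth_series
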