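"""Measurement-error quantification and propagation.

Two error channels affect a calibration data pair: noise in the recorded
sensor signal (me_x, the s.d. of the raw signal under constant conditions)
and uncertainty of the reference value assigned to the calibration point
(me_y).  For the pressure sensor me_y follows directly from the manometer's
relative accuracy; for the O2 and CO2 concentrations — which are *derived*
through the gas mole balance — me_y is estimated by Monte Carlo: every
input of the balance (V_head, P, dP_out, dP_in, T, T_out, T_in) is replaced
by a normal draw and the per-step concentration spread across simulated
runs gives the error.

The module also decomposes the residual variance of a fitted calibration
into the known me_y part and the irreducible "individual" part t^2, and
propagates the *systematic* relative accuracy of the calibration gas
cylinders (gasE) to concentrations and calibration coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .calibration_fit import CalibrationDataset, fit_ols
from .errors import DomainError, InconsistentBudgetError, InsufficientDataError
from .gas_model import CalibrationProtocol, GasMixture, run_protocol

__all__ = [
    "NoiseEstimate",
    "McInputSpec",
    "McConcentrationErrors",
    "McCoefficientErrors",
    "VarianceDecomposition",
    "GasErrorScenario",
    "estimate_sensor_noise",
    "noise_to_measurand",
    "detection_limit",
    "pressure_me_y",
    "mc_concentration_errors",
    "decompose_variance",
    "propagate_gas_error",
    "mc_gas_error_sd",
    "mc_coefficient_errors",
]


@dataclass(frozen=True)
class NoiseEstimate:
    """Sensor noise me_x: s.d. of the raw signal under constant conditions."""

    me_x: float
    n_readings: int
    segment_span: float = float("nan")
    equivalent_measurand_error: float = float("nan")


@dataclass(frozen=True)
class McInputSpec:
    """Input standard deviations for the Monte Carlo error analysis (SI units).

    The defaults are documented instrument-level assumptions: chamber
    volume known to ~10 mL, absolute pressure to ~20 Pa (barometer), each
    pressure difference to ~5 Pa (pressure-sensor noise floor), and
    temperatures to 0.1 K.  When ``include_slope_error`` is set, the
    relative standard error of the pressure-calibration slope is added in
    quadrature to the dP uncertainties, since dP readings are themselves
    produced through that calibration.
    """

    sd_V_head: float = 1e-5  # m3 (10 mL)
    sd_P: float = 20.0  # Pa
    sd_dP_out: float = 5.0  # Pa
    sd_dP_in: float = 5.0  # Pa
    sd_T: float = 0.1  # K
    sd_T_out: float = 0.1  # K
    sd_T_in: float = 0.1  # K
    include_slope_error: bool = True
    slope_rel_error: float = 0.0042  # se_b/b of the pressure calibration
    n_sim: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        sds = (
            self.sd_V_head,
            self.sd_P,
            self.sd_dP_out,
            self.sd_dP_in,
            self.sd_T,
            self.sd_T_out,
            self.sd_T_in,
            self.slope_rel_error,
        )
        if any(s < 0 for s in sds):
            raise DomainError("all standard deviations must be >= 0")
        if self.n_sim < 1:
            raise DomainError("n_sim must be >= 1")

    def scaled(self, factor: float) -> "McInputSpec":
        """A copy with every input s.d. multiplied by ``factor``."""
        return replace(
            self,
            sd_V_head=self.sd_V_head * factor,
            sd_P=self.sd_P * factor,
            sd_dP_out=self.sd_dP_out * factor,
            sd_dP_in=self.sd_dP_in * factor,
            sd_T=self.sd_T * factor,
            sd_T_out=self.sd_T_out * factor,
            sd_T_in=self.sd_T_in * factor,
            slope_rel_error=self.slope_rel_error * factor,
        )


@dataclass(frozen=True)
class McConcentrationErrors:
    """Per-step me_y of the derived concentrations (steps 0..n)."""

    me_y_o2_volpct: np.ndarray
    me_y_co2_umol_ml: np.ndarray
    me_y_co2_volpct: np.ndarray
    n_sim: int
    n_rejected: int

    @property
    def mean_me_y_o2(self) -> float:
        return float(np.mean(self.me_y_o2_volpct))

    @property
    def mean_me_y_co2(self) -> float:
        return float(np.mean(self.me_y_co2_umol_ml))


@dataclass(frozen=True)
class McCoefficientErrors:
    """Empirical s.d. of refitted calibration coefficients per sensor."""

    sd_a_o2: float
    sd_b_o2: float
    sd_a_co2: float
    sd_b_co2: float
    n_sim: int


@dataclass(frozen=True)
class VarianceDecomposition:
    """Split of residual variance sigma^2 into me_y^2 and the individual part t^2."""

    sigma2: float
    me_y2: float
    t2: float

    @property
    def t(self) -> float:
        return float(np.sqrt(self.t2))

    @property
    def explained_fraction(self) -> float:
        """Share of sigma^2 attributable to the known measurement error."""
        return self.me_y2 / self.sigma2 if self.sigma2 > 0 else 0.0


@dataclass(frozen=True)
class GasErrorScenario:
    """Systematic concentration/coefficient deviations from gas-cylinder accuracy."""

    rel_gas_error: float
    sd_o2_volpct: np.ndarray
    sd_co2_volpct: np.ndarray
    sd_co2_umol_ml: np.ndarray
    rel_da: float
    rel_db: float


def estimate_sensor_noise(
    log, segment_span: float = float("nan"), slope: float | None = None
) -> NoiseEstimate:
    """Estimate me_x as the sample s.d. (n-1 denominator) of a constant-condition log.

    ``log`` is the raw signal series (V) recorded while the measurand was
    held constant.  If the calibration ``slope`` is given, the noise is
    also expressed in measurand units.
    """
    x = np.asarray(log, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("sensor-noise estimation needs >= 2 readings")
    me_x = float(np.std(x, ddof=1))
    equiv = noise_to_measurand(me_x, slope) if slope is not None else float("nan")
    return NoiseEstimate(
        me_x=me_x,
        n_readings=int(x.size),
        segment_span=segment_span,
        equivalent_measurand_error=equiv,
    )


def noise_to_measurand(me_x: float, b: float) -> float:
    """Express signal noise in measurand units: |b| * me_x."""
    return abs(b) * me_x


def detection_limit(me_x_equivalent: float) -> float:
    """Smallest reliably detectable measurand change: three times the noise level."""
    return 3.0 * me_x_equivalent


def pressure_me_y(dP, rel_accuracy: float = 0.002):
    """me_y of a manometer-referenced pressure value: rel_accuracy * |dP|.

    ``dP`` may be a scalar or an array of measured pressure differences; an
    array input additionally makes the protocol-level mean available via
    ``np.mean`` on the result, matching the practice of using one averaged
    me_y across the narrow calibration range.
    """
    if rel_accuracy < 0:
        raise DomainError("rel_accuracy must be >= 0")
    dP = np.asarray(dP, dtype=float)
    result = rel_accuracy * np.abs(dP)
    return float(result) if result.ndim == 0 else result


def _draw_protocol_inputs(rng, protocol: CalibrationProtocol, spec: McInputSpec):
    n = protocol.n_steps
    sd_dp_out = np.hypot(
        spec.sd_dP_out,
        spec.slope_rel_error * protocol.dP_pa if spec.include_slope_error else 0.0,
    )
    sd_dp_in = np.hypot(
        spec.sd_dP_in,
        spec.slope_rel_error * protocol.dP_pa if spec.include_slope_error else 0.0,
    )
    return {
        "V_head": rng.normal(protocol.V_head_m3, spec.sd_V_head),
        "P": rng.normal(protocol.P_pa, spec.sd_P),
        "T": rng.normal(protocol.T_k, spec.sd_T),
        "dP_out": rng.normal(protocol.dP_pa, sd_dp_out, size=n),
        "dP_in": rng.normal(protocol.dP_pa, sd_dp_in, size=n),
        "T_out": rng.normal(protocol.T_k, spec.sd_T_out, size=n),
        "T_in": rng.normal(protocol.T_k, spec.sd_T_in, size=n),
    }


def _feasible(draw) -> bool:
    return (
        draw["V_head"] > 0
        and draw["P"] > 0
        and draw["T"] > 0
        and np.all(draw["dP_out"] >= 0)
        and np.all(draw["dP_in"] >= 0)
        and np.all(draw["T_out"] > 0)
        and np.all(draw["T_in"] > 0)
    )


def _simulate_runs(protocol: CalibrationProtocol, spec: McInputSpec):
    """Yield per-run concentration arrays; physically infeasible draws are rejected."""
    rng = np.random.default_rng(spec.seed)
    n_rejected = 0
    o2 = np.empty((spec.n_sim, protocol.n_steps + 1))
    co2_vol = np.empty_like(o2)
    co2_uml = np.empty_like(o2)
    for s in range(spec.n_sim):
        while True:
            draw = _draw_protocol_inputs(rng, protocol, spec)
            if _feasible(draw):
                break
            n_rejected += 1
        res = run_protocol(protocol, **draw)
        o2[s] = res["o2_volpct"]
        co2_vol[s] = res["co2_volpct"]
        co2_uml[s] = res["co2_umol_ml"]
    if n_rejected > 0.01 * spec.n_sim:
        warnings.warn(
            f"{n_rejected} of {spec.n_sim + n_rejected} Monte Carlo draws were "
            "physically infeasible and redrawn; input s.d.s may be too large",
            stacklevel=3,
        )
    return o2, co2_vol, co2_uml, n_rejected


def mc_concentration_errors(
    protocol: CalibrationProtocol, spec: McInputSpec
) -> McConcentrationErrors:
    """Monte Carlo me_y of the derived O2 and CO2 concentrations.

    For each of ``spec.n_sim`` simulated calibration runs every input of
    the mole balance is drawn from its normal distribution and the full
    stepwise balance is evaluated; the s.d. across runs of each step's
    concentration is its me_y.  Results are reproducible under a fixed
    seed.  Draws producing negative pools or non-physical states are
    rejected, counted, and redrawn (with a warning above a 1% rejection
    rate).
    """
    if spec.n_sim < 2:
        raise InsufficientDataError("me_y estimation needs n_sim >= 2")
    o2, co2_vol, co2_uml, n_rej = _simulate_runs(protocol, spec)
    return McConcentrationErrors(
        me_y_o2_volpct=np.std(o2, axis=0, ddof=1),
        me_y_co2_umol_ml=np.std(co2_uml, axis=0, ddof=1),
        me_y_co2_volpct=np.std(co2_vol, axis=0, ddof=1),
        n_sim=spec.n_sim,
        n_rejected=n_rej,
    )


def decompose_variance(sigma2: float, me_y: float) -> VarianceDecomposition:
    """Split residual variance: t^2 = sigma^2 - me_y^2.

    ``sigma2`` is the residual variance of the calibration fit (squared
    measurand units) and ``me_y`` the known measurement-error s.d. of the
    reference values.  The remainder t^2 is the irreducible "individual
    part" of the observations.  A me_y^2 exceeding sigma^2 is flagged as an
    inconsistent budget (the stated measurement error is overstated).
    """
    if sigma2 < 0 or me_y < 0:
        raise DomainError("sigma2 and me_y must be >= 0")
    me_y2 = me_y**2
    if me_y2 > sigma2:
        raise InconsistentBudgetError(
            f"me_y^2 = {me_y2!r} exceeds residual variance sigma^2 = {sigma2!r}"
        )
    return VarianceDecomposition(sigma2=sigma2, me_y2=me_y2, t2=sigma2 - me_y2)


def _perturbed_mixture(mix: GasMixture, factor: float) -> GasMixture:
    """Scale the non-N2 components by ``factor``; N2 takes up the remainder."""
    o2 = mix.frac_O2 * factor
    co2 = mix.frac_CO2 * factor
    return GasMixture(frac_O2=o2, frac_CO2=co2, frac_N2=1.0 - o2 - co2,
                      rel_accuracy=mix.rel_accuracy)


def propagate_gas_error(
    protocol: CalibrationProtocol, rel_gas_error: float
) -> GasErrorScenario:
    """Systematic effect of calibration-gas composition accuracy (gasE).

    The filler states a relative accuracy (e.g. 2%) for each cylinder.
    Because every O2 concentration in the protocol is proportional to the
    initial O2 fraction and every CO2 concentration to the injected CO2
    fraction, a relative cylinder error translates one-to-one into a
    relative error of each step's concentration — and, since the reference
    values enter the calibration fit linearly, into the same relative error
    of both calibration coefficients.  Treating the stated accuracy as a
    1-sigma level, the per-step concentration s.d. is
    ``rel_gas_error * concentration``; the exact scenario envelope is
    verified internally by recomputing the mole balance with perturbed
    cylinders.
    """
    if rel_gas_error < 0:
        raise DomainError("rel_gas_error must be >= 0")
    nominal = run_protocol(protocol)
    sd_o2 = rel_gas_error * nominal["o2_volpct"]
    sd_co2_vol = rel_gas_error * nominal["co2_volpct"]
    sd_co2_uml = rel_gas_error * nominal["co2_umol_ml"]

    # cross-check the first-order scaling against exact perturbed runs
    if rel_gas_error > 0:
        up_init = run_protocol(
            protocol, initial=_perturbed_mixture(protocol.initial, 1 + rel_gas_error)
        )
        up_inj = run_protocol(
            protocol, injected=_perturbed_mixture(protocol.injected, 1 + rel_gas_error)
        )
        exact_o2 = np.abs(up_init["o2_volpct"] - nominal["o2_volpct"])
        exact_co2 = np.abs(up_inj["co2_umol_ml"] - nominal["co2_umol_ml"])
        if not (
            np.allclose(exact_o2, sd_o2, rtol=1e-9, atol=1e-12)
            and np.allclose(exact_co2, sd_co2_uml, rtol=1e-9, atol=1e-15)
        ):  # pragma: no cover - guards the linearity assumption
            sd_o2, sd_co2_uml = exact_o2, exact_co2

    return GasErrorScenario(
        rel_gas_error=rel_gas_error,
        sd_o2_volpct=sd_o2,
        sd_co2_volpct=sd_co2_vol,
        sd_co2_umol_ml=sd_co2_uml,
        rel_da=rel_gas_error,
        rel_db=rel_gas_error,
    )


def mc_gas_error_sd(
    protocol: CalibrationProtocol,
    rel_gas_error: float,
    n_sim: int = 1000,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Monte Carlo cross-check of :func:`propagate_gas_error`.

    Draws the initial O2 fraction and injected CO2 fraction from normal
    distributions with relative s.d. ``rel_gas_error``, reruns the mole
    balance, and returns the per-step concentration s.d. across draws.
    """
    rng = np.random.default_rng(seed)
    if n_sim < 2:
        raise InsufficientDataError("n_sim must be >= 2")
    o2 = np.empty((n_sim, protocol.n_steps + 1))
    co2 = np.empty_like(o2)
    for s in range(n_sim):
        while True:
            f_init = rng.normal(1.0, rel_gas_error)
            f_inj = rng.normal(1.0, rel_gas_error)
            try:
                init = _perturbed_mixture(protocol.initial, f_init)
                inj = _perturbed_mixture(protocol.injected, f_inj)
                break
            except DomainError:
                continue
        res = run_protocol(protocol, initial=init, injected=inj)
        o2[s] = res["o2_volpct"]
        co2[s] = res["co2_umol_ml"]
    return {
        "sd_o2_volpct": np.std(o2, axis=0, ddof=1),
        "sd_co2_umol_ml": np.std(co2, axis=0, ddof=1),
    }


def mc_coefficient_errors(
    protocol: CalibrationProtocol,
    spec: McInputSpec,
    truth_o2=(-3.7, 14.8),
    truth_co2=(-0.015, 0.52),
) -> McCoefficientErrors:
    """Impact of the me_y errors on the O2 and CO2 calibration coefficients.

    For every simulated calibration run the perturbed per-step
    concentrations are refit against the *fixed* true signals (obtained by
    inverting the supplied true linear responses at the nominal
    concentrations), and the empirical s.d. of intercept and slope across
    runs is returned.  ``truth_o2``/``truth_co2`` are (a, b) pairs of
    typical sensor responses in Vol% and umol mL-1 per volt.
    """
    if spec.n_sim < 2:
        raise InsufficientDataError("coefficient s.d. needs n_sim >= 2")
    nominal = run_protocol(protocol)
    x_o2 = (nominal["o2_volpct"] - truth_o2[0]) / truth_o2[1]
    x_co2 = (nominal["co2_umol_ml"] - truth_co2[0]) / truth_co2[1]

    o2, _, co2_uml, _ = _simulate_runs(protocol, spec)
    coeffs = np.empty((spec.n_sim, 4))
    for s in range(spec.n_sim):
        ds_o2 = CalibrationDataset.from_arrays(
            x_o2[:, None], o2[s], sensor_kind="o2"
        )
        ds_co2 = CalibrationDataset.from_arrays(
            x_co2[:, None], co2_uml[s], sensor_kind="co2"
        )
        f1, f2 = fit_ols(ds_o2), fit_ols(ds_co2)
        coeffs[s] = (f1.a, f1.b, f2.a, f2.b)
    sd = np.std(coeffs, axis=0, ddof=1)
    return McCoefficientErrors(
        sd_a_o2=float(sd[0]),
        sd_b_o2=float(sd[1]),
        sd_a_co2=float(sd[2]),
        sd_b_co2=float(sd[3]),
        n_sim=spec.n_sim,
    )
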