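"""Ideal-gas mole-balance engine for stepwise headspace gas exchange.

The O2 and CO2 sensors of a BaPS incubation chamber are calibrated by
repeatedly removing a small gas volume from the headspace and replacing it
with a CO2/N2 mixture.  Starting from synthetic air, each removal/injection
cycle lowers the O2 concentration and raises the CO2 concentration by a
known amount, so the true gas composition at every step can be computed
from pressure changes alone via mole balances.  This module implements that
computation: the ideal gas law, the per-step exchange balance, the
closed-form concentration recursion valid under idealized (isothermal,
isobaric) conditions, Vol% <-> umol mL-1 conversion, and headspace-volume
determination by volume extension.

All quantities are SI internally (Pa, m3, K, mol).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import R
from .errors import DomainError, InfeasibleProtocolError

__all__ = [
    "GasMixture",
    "GasState",
    "ExchangeStep",
    "CalibrationProtocol",
    "moles_from_state",
    "apply_exchange",
    "idealized_concentrations",
    "volpct_to_umol_per_ml",
    "umol_per_ml_to_volpct",
    "headspace_volume",
    "vhead_uncertainty",
    "run_protocol",
    "SYNTHETIC_AIR",
    "CO2_CALIBRATION_GAS",
]

_FRACTION_ATOL = 1e-9


@dataclass(frozen=True)
class GasMixture:
    """A three-component gas mixture given as volume fractions (Vol%/100).

    ``rel_accuracy`` is the relative concentration accuracy stated on the
    cylinder certificate (e.g. 0.02 for +/-2%).
    """

    frac_O2: float
    frac_CO2: float
    frac_N2: float
    rel_accuracy: float = 0.0

    def __post_init__(self) -> None:
        fracs = (self.frac_O2, self.frac_CO2, self.frac_N2)
        if any(f < -_FRACTION_ATOL or f > 1 + _FRACTION_ATOL for f in fracs):
            raise DomainError(f"gas fractions must lie in [0, 1], got {fracs}")
        if abs(sum(fracs) - 1.0) > _FRACTION_ATOL:
            raise DomainError(f"gas fractions must sum to 1, got {sum(fracs)!r}")
        if self.rel_accuracy < 0:
            raise DomainError("rel_accuracy must be >= 0")

    def as_array(self) -> np.ndarray:
        """Fractions in the fixed species order (O2, CO2, N2)."""
        return np.array([self.frac_O2, self.frac_CO2, self.frac_N2])


#: Synthetic air used as the starting atmosphere (20.5% O2, 79.5% N2, +/-2%).
SYNTHETIC_AIR = GasMixture(frac_O2=0.205, frac_CO2=0.0, frac_N2=0.795, rel_accuracy=0.02)

#: CO2/N2 mixture injected at each exchange (20.5% CO2, 79.5% N2, +/-2%).
CO2_CALIBRATION_GAS = GasMixture(frac_O2=0.0, frac_CO2=0.205, frac_N2=0.795, rel_accuracy=0.02)


@dataclass(frozen=True)
class GasState:
    """Headspace composition at one protocol step.

    Amounts are in mol, ``P`` in Pa, ``T`` in K, ``V_head`` in m3.  The
    state is always self-consistent: species amounts sum to ``n_total`` and
    ``n_total`` satisfies the ideal gas law for (P, T, V_head).
    """

    n_O2: float
    n_CO2: float
    n_N2: float
    P: float
    T: float
    V_head: float

    def __post_init__(self) -> None:
        if self.P <= 0 or self.T <= 0 or self.V_head <= 0:
            raise DomainError("P, T and V_head must be > 0")
        if min(self.n_O2, self.n_CO2, self.n_N2) < 0:
            raise DomainError("species amounts must be >= 0")
        n_gas = moles_from_state(self.P, self.V_head, self.T)
        if not math.isclose(self.n_total, n_gas, rel_tol=1e-9, abs_tol=1e-15):
            raise DomainError(
                f"state inconsistent with ideal gas law: "
                f"sum of species = {self.n_total!r}, P*V/(R*T) = {n_gas!r}"
            )

    @property
    def n_total(self) -> float:
        return self.n_O2 + self.n_CO2 + self.n_N2

    @property
    def fractions(self) -> np.ndarray:
        """Mole fractions in species order (O2, CO2, N2)."""
        return np.array([self.n_O2, self.n_CO2, self.n_N2]) / self.n_total

    @property
    def volpct(self) -> np.ndarray:
        """Concentrations in Vol% (O2, CO2, N2)."""
        return self.fractions * 100.0

    @property
    def co2_umol_per_ml(self) -> float:
        """CO2 amount related to the headspace volume, in umol mL-1."""
        # mol / m3 == umol / mL exactly
        return self.n_CO2 / self.V_head

    @classmethod
    def from_mixture(
        cls, mixture: GasMixture, P: float, T: float, V_head: float
    ) -> "GasState":
        """Build a state holding ``mixture`` at the given P, T, V_head."""
        n = moles_from_state(P, V_head, T)
        f = mixture.as_array()
        return cls(
            n_O2=n * f[0], n_CO2=n * f[1], n_N2=n * f[2], P=P, T=T, V_head=V_head
        )


@dataclass(frozen=True)
class ExchangeStep:
    """One removal/injection cycle.

    ``dP_out`` and ``dP_in`` are unsigned pressure magnitudes (Pa); the
    direction is carried by the operation.  ``T_out`` / ``T_in`` are the
    headspace temperatures prevailing during removal and injection.
    """

    dP_out: float
    dP_in: float
    T_out: float
    T_in: float
    injected: GasMixture

    def __post_init__(self) -> None:
        if self.dP_out < 0 or self.dP_in < 0:
            raise DomainError("dP_out and dP_in must be >= 0")
        if self.T_out <= 0 or self.T_in <= 0:
            raise DomainError("T_out and T_in must be > 0")


def moles_from_state(P: float, V: float, T: float) -> float:
    """Amount of gas n = P*V/(R*T) in mol.

    ``V = 0`` is allowed and yields 0 mol; non-positive P or T raise
    :class:`DomainError`.
    """
    if P <= 0 or T <= 0:
        raise DomainError(f"P and T must be > 0, got P={P!r}, T={T!r}")
    if V < 0:
        raise DomainError(f"V must be >= 0, got {V!r}")
    return P * V / (R * T)


def apply_exchange(state: GasState, step: ExchangeStep) -> GasState:
    """Apply one removal/injection cycle and return the new headspace state.

    Removal extracts ``n_out = dP_out*V_head/(R*T_out)`` mol proportionally
    to the current mole fractions (well-mixed headspace); injection adds
    ``n_in = dP_in*V_head/(R*T_in)`` mol with the injected mixture's
    composition.  The returned state's pressure is recomputed from the
    ideal gas law at the state temperature.
    """
    n_out = step.dP_out * state.V_head / (R * step.T_out)
    n_in = step.dP_in * state.V_head / (R * step.T_in)

    pools = np.array([state.n_O2, state.n_CO2, state.n_N2])
    removed = n_out * state.fractions
    if n_out > state.n_total * (1 + 1e-12):
        raise InfeasibleProtocolError(
            f"removal of {n_out!r} mol exceeds headspace pool of {state.n_total!r} mol"
        )
    new_pools = pools - removed + n_in * step.injected.as_array()
    if new_pools.min() < -1e-15:
        raise InfeasibleProtocolError("removal exceeds a species pool")
    new_pools = np.clip(new_pools, 0.0, None)

    n_new = float(new_pools.sum())
    P_new = n_new * R * state.T / state.V_head
    return GasState(
        n_O2=float(new_pools[0]),
        n_CO2=float(new_pools[1]),
        n_N2=float(new_pools[2]),
        P=P_new,
        T=state.T,
        V_head=state.V_head,
    )


def idealized_concentrations(
    i: int,
    dP: float,
    P: float,
    initial: GasMixture = SYNTHETIC_AIR,
    injected: GasMixture = CO2_CALIBRATION_GAS,
) -> tuple[float, float, float]:
    """Closed-form headspace concentrations after ``i`` idealized exchanges.

    Under constant temperature and pressure with equal removal and
    injection increments dP, each species concentration follows the affine
    recursion ``c_{i+1} = c_i*(1 - dP/P) + c_inj*dP/P``, whose closed form
    is ``c_i = c_inj + (c_0 - c_inj)*(1 - dP/P)**i``.  Returns
    (O2, CO2, N2) in Vol%; the fractions sum to 100 exactly.
    """
    if i < 0:
        raise DomainError("exchange count must be >= 0")
    if not 0 <= dP < P:
        raise DomainError(f"dP must satisfy 0 <= dP < P, got dP={dP!r}, P={P!r}")
    r = (1.0 - dP / P) ** i
    c0 = initial.as_array()
    cinj = injected.as_array()
    c = cinj + (c0 - cinj) * r
    o2, co2, n2 = (c * 100.0).tolist()
    return o2, co2, n2


def volpct_to_umol_per_ml(c: float, P: float, T: float) -> float:
    """Convert a concentration from Vol% to umol mL-1 at the given P and T.

    Multiplies the volume fraction by the molar density P/(R*T); since
    1 mol m-3 equals 1 umol mL-1, no further scaling is needed.
    """
    if P <= 0 or T <= 0:
        raise DomainError("P and T must be > 0")
    return (c / 100.0) * P / (R * T)


def umol_per_ml_to_volpct(c: float, P: float, T: float) -> float:
    """Inverse of :func:`volpct_to_umol_per_ml`."""
    if P <= 0 or T <= 0:
        raise DomainError("P and T must be > 0")
    return c * 100.0 * R * T / P


def headspace_volume(P0, dP, dV) -> float:
    """Headspace volume from isothermal volume extension (Boyle's law).

    Extending the chamber volume by a known ``dV`` (syringe pull) at
    constant temperature drops the pressure from P0 to P0 - dP, so
    ``V_head = (P0 - dP) * dV / dP``.  Arguments may be scalars or
    same-length sequences of replicate measurements (typically triplicate);
    replicate volumes are averaged arithmetically.  Any consistent volume
    unit may be used for dV; the result carries that unit.
    """
    P0 = np.atleast_1d(np.asarray(P0, dtype=float))
    dP = np.atleast_1d(np.asarray(dP, dtype=float))
    dV = np.atleast_1d(np.asarray(dV, dtype=float))
    if np.any(dP <= 0):
        raise DomainError("dP must be > 0: no pressure drop means the volume is immeasurable")
    if np.any(dP >= P0):
        raise DomainError("dP must be < P0 (pressure cannot drop below vacuum)")
    if np.any(dV <= 0):
        raise DomainError("extension volume dV must be > 0")
    return float(np.mean((P0 - dP) * dV / dP))


def vhead_uncertainty(
    syringe_rel_error: float, pressure_slope_rel_error: float, V_head: float
) -> float:
    """First-order Gaussian propagation of V_head error components.

    Two relative error sources enter the volume-extension formula: the
    syringe volume accuracy (relative error on dV, which maps one-to-one
    onto V_head) and the relative standard error of the pressure
    calibration slope (relative error on the measured dP, whose first-order
    sensitivity is ~ -1 for dP << P0).  The components are independent and
    add in quadrature; the result is an absolute s.d. in the unit of
    ``V_head``.
    """
    if syringe_rel_error < 0 or pressure_slope_rel_error < 0:
        raise DomainError("relative errors must be >= 0")
    return V_head * math.hypot(syringe_rel_error, pressure_slope_rel_error)


@dataclass(frozen=True)
class CalibrationProtocol:
    """A complete O2/CO2 calibration run description.

    ``n_steps`` removal/injection cycles of nominal increment ``dP_pa`` are
    applied to a chamber initially holding ``initial`` gas at ``P_pa``,
    ``T_k`` and ``V_head_m3``.  The defaults — eight ~2% exchanges in a
    1 L chamber — sweep O2 from 20.5 down to ~17.5 Vol% and CO2 from 0 up
    to ~3 Vol%, i.e. the full measuring range of both sensors, with the
    nine-point regression this yields.
    """

    initial: GasMixture = SYNTHETIC_AIR
    injected: GasMixture = CO2_CALIBRATION_GAS
    n_steps: int = 8
    dP_pa: float = 2000.0
    P_pa: float = 101325.0
    T_k: float = 293.15
    V_head_m3: float = 1e-3

    def __post_init__(self) -> None:
        if self.n_steps < 0:
            raise DomainError("n_steps must be >= 0")
        if not 0 <= self.dP_pa < self.P_pa:
            raise DomainError("dP_pa must satisfy 0 <= dP < P")
        if self.P_pa <= 0 or self.T_k <= 0 or self.V_head_m3 <= 0:
            raise DomainError("P, T and V_head must be > 0")


def run_protocol(
    protocol: CalibrationProtocol,
    *,
    V_head: float | None = None,
    P: float | None = None,
    T: float | None = None,
    dP_out=None,
    dP_in=None,
    T_out=None,
    T_in=None,
    initial: GasMixture | None = None,
    injected: GasMixture | None = None,
) -> dict[str, np.ndarray]:
    """Run the stepwise mole balance and return per-step true concentrations.

    Keyword overrides replace the protocol's nominal values; ``dP_out``,
    ``dP_in``, ``T_out`` and ``T_in`` may be scalars or per-step arrays.
    This is the entry point the Monte Carlo error analysis perturbs.

    Returns arrays of length ``n_steps + 1`` (step 0 = initial atmosphere)
    with keys ``o2_volpct``, ``co2_volpct``, ``n2_volpct``, ``co2_umol_ml``
    and ``p_pa``.
    """
    V = protocol.V_head_m3 if V_head is None else V_head
    P0 = protocol.P_pa if P is None else P
    T0 = protocol.T_k if T is None else T
    init = protocol.initial if initial is None else initial
    inj = protocol.injected if injected is None else injected
    n = protocol.n_steps

    dP_out = np.broadcast_to(
        np.asarray(protocol.dP_pa if dP_out is None else dP_out, dtype=float), (n,)
    )
    dP_in = np.broadcast_to(
        np.asarray(protocol.dP_pa if dP_in is None else dP_in, dtype=float), (n,)
    )
    T_out = np.broadcast_to(np.asarray(T0 if T_out is None else T_out, dtype=float), (n,))
    T_in = np.broadcast_to(np.asarray(T0 if T_in is None else T_in, dtype=float), (n,))

    state = GasState.from_mixture(init, P=P0, T=T0, V_head=V)
    out = {
        "o2_volpct": np.empty(n + 1),
        "co2_volpct": np.empty(n + 1),
        "n2_volpct": np.empty(n + 1),
        "co2_umol_ml": np.empty(n + 1),
        "p_pa": np.empty(n + 1),
    }

    def record(k: int, s: GasState) -> None:
        o2, co2, n2 = s.volpct
        out["o2_volpct"][k] = o2
        out["co2_volpct"][k] = co2
        out["n2_volpct"][k] = n2
        out["co2_umol_ml"][k] = s.co2_umol_per_ml
        out["p_pa"][k] = s.P

    record(0, state)
    for k in range(n):
        step = ExchangeStep(
            dP_out=float(dP_out[k]),
            dP_in=float(dP_in[k]),
            T_out=float(T_out[k]),
            T_in=float(T_in[k]),
            injected=inj,
        )
        state = apply_exchange(state, step)
        record(k + 1, state)
    return out
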