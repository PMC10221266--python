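"""Mole-balance engine: ideal gas law, exchange steps, closed forms, volumes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bapscal import (
    CO2_CALIBRATION_GAS,
    SYNTHETIC_AIR,
    CalibrationProtocol,
    DomainError,
    ExchangeStep,
    GasMixture,
    GasState,
    InfeasibleProtocolError,
    apply_exchange,
    headspace_volume,
    idealized_concentrations,
    moles_from_state,
    run_protocol,
    umol_per_ml_to_volpct,
    vhead_uncertainty,
    volpct_to_umol_per_ml,
)

R = 8.314


class TestMolesFromState:
    @pytest.mark.parametrize(
        "P, V, T, expected",
        [
            (101325.0, 1e-3, 298.15, 0.04087),
            (100000.0, 1e-3, 293.15, 0.04103),
        ],
    )
    def test_ideal_gas_arithmetic(self, P, V, T, expected):
        assert moles_from_state(P, V, T) == pytest.approx(expected, abs=1e-5)

    def test_zero_volume_holds_no_gas(self):
        assert moles_from_state(101325.0, 0.0, 293.15) == 0.0

    @pytest.mark.parametrize("P, T", [(-1.0, 293.15), (0.0, 293.15), (1e5, 0.0), (1e5, -5.0)])
    def test_unphysical_inputs_rejected(self, P, T):
        with pytest.raises(DomainError):
            moles_from_state(P, 1e-3, T)


class TestApplyExchange:
    def _state(self, P=100000.0, T=293.15, V=1e-3, mixture=SYNTHETIC_AIR):
        return GasState.from_mixture(mixture, P=P, T=T, V_head=V)

    def test_one_percent_exchange_composition(self):
        """Removing and injecting 1% of the pressure shifts O2 down and CO2 up."""
        state = self._state()
        step = ExchangeStep(
            dP_out=1000.0, dP_in=1000.0, T_out=293.15, T_in=293.15,
            injected=CO2_CALIBRATION_GAS,
        )
        new = apply_exchange(state, step)
        o2, co2, n2 = new.volpct
        assert o2 == pytest.approx(20.295, abs=1e-9)
        assert co2 == pytest.approx(0.205, abs=1e-9)
        assert n2 == pytest.approx(79.5, abs=1e-9)

    def test_null_step_is_identity(self):
        state = self._state()
        step = ExchangeStep(0.0, 0.0, 293.15, 293.15, CO2_CALIBRATION_GAS)
        new = apply_exchange(state, step)
        assert np.allclose(new.volpct, state.volpct, rtol=1e-12)
        assert new.n_total == pytest.approx(state.n_total, rel=1e-12)

    def test_exchanging_identical_mixture_is_fixed_point(self):
        state = self._state()
        step = ExchangeStep(800.0, 800.0, 293.15, 293.15, SYNTHETIC_AIR)
        new = apply_exchange(state, step)
        assert np.allclose(new.volpct, state.volpct, rtol=1e-12)
        assert new.n_total == pytest.approx(state.n_total, rel=1e-12)

    def test_removal_exceeding_pool_is_infeasible(self):
        state = self._state()
        step = ExchangeStep(2e5, 0.0, 293.15, 293.15, CO2_CALIBRATION_GAS)
        with pytest.raises(InfeasibleProtocolError):
            apply_exchange(state, step)

    @given(
        dP=st.floats(0.0, 5000.0),
        frac_o2=st.floats(0.0, 0.3),
        frac_co2=st.floats(0.0, 0.2),
        n_steps=st.integers(1, 6),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_species_conservation(self, dP, frac_o2, frac_co2, n_steps):
        """Removed + final pool equals initial pool + injected, per species."""
        state = GasState.from_mixture(SYNTHETIC_AIR, P=101325.0, T=293.15, V_head=1e-3)
        injected = GasMixture(frac_o2, frac_co2, 1.0 - frac_o2 - frac_co2)
        removed = np.zeros(3)
        added = np.zeros(3)
        initial = np.array([state.n_O2, state.n_CO2, state.n_N2])
        for _ in range(n_steps):
            step = ExchangeStep(dP, dP, 293.15, 293.15, injected)
            n_out = step.dP_out * state.V_head / (R * step.T_out)
            removed += n_out * state.fractions
            added += (step.dP_in * state.V_head / (R * step.T_in)) * injected.as_array()
            state = apply_exchange(state, step)
        final = np.array([state.n_O2, state.n_CO2, state.n_N2])
        np.testing.assert_allclose(removed + final, initial + added, rtol=1e-12, atol=1e-18)


class TestIdealizedConcentrations:
    def test_no_exchange_returns_initial_air(self):
        assert idealized_concentrations(0, 1000.0, 100000.0) == pytest.approx(
            (20.5, 0.0, 79.5)
        )

    def test_single_exchange(self):
        o2, co2, n2 = idealized_concentrations(1, 1000.0, 100000.0)
        assert (o2, co2, n2) == pytest.approx((20.295, 0.205, 79.5), abs=1e-12)

    def test_converges_to_injected_mixture(self):
        o2, co2, n2 = idealized_concentrations(5000, 1000.0, 100000.0)
        assert (o2, co2, n2) == pytest.approx((0.0, 20.5, 79.5), abs=1e-6)

    def test_fractions_sum_to_100(self):
        for i in range(12):
            assert sum(idealized_concentrations(i, 900.0, 101325.0)) == pytest.approx(
                100.0, abs=1e-9
            )

    def test_dp_not_below_pressure(self):
        with pytest.raises(DomainError):
            idealized_concentrations(1, 1e5, 1e5)

    def test_equals_stepwise_mole_balance(self):
        """Closed form must agree with the iterated exchange under ideal conditions."""
        res = run_protocol(CalibrationProtocol(n_steps=8, dP_pa=1000.0, P_pa=101325.0))
        for i in range(9):
            o2, co2, n2 = idealized_concentrations(i, 1000.0, 101325.0)
            assert res["o2_volpct"][i] == pytest.approx(o2, rel=1e-10)
            assert res["co2_volpct"][i] == pytest.approx(co2, rel=1e-10, abs=1e-12)

    def test_n2_invariance_under_standard_protocol(self):
        """Injected N2 fraction equals the initial one, so [N2] never moves."""
        res = run_protocol(CalibrationProtocol(n_steps=10))
        np.testing.assert_allclose(res["n2_volpct"], 79.5, rtol=1e-10)

    def test_o2_decreasing_co2_increasing(self):
        res = run_protocol(CalibrationProtocol(n_steps=10))
        assert np.all(np.diff(res["o2_volpct"]) < 0)
        assert np.all(np.diff(res["co2_volpct"]) > 0)


class TestUnitConversion:
    def test_pure_gas_molar_density(self):
        assert volpct_to_umol_per_ml(100.0, 100000.0, 293.15) == pytest.approx(
            41.03, abs=5e-3
        )

    def test_zero_concentration(self):
        assert volpct_to_umol_per_ml(0.0, 101325.0, 293.15) == 0.0

    def test_round_trip(self):
        c = 1.234
        back = umol_per_ml_to_volpct(
            volpct_to_umol_per_ml(c, 98000.0, 290.0), 98000.0, 290.0
        )
        assert back == pytest.approx(c, rel=1e-12)


class TestHeadspaceVolume:
    def test_boyle_expansion(self):
        assert headspace_volume(100000.0, 1000.0, 10.0) == pytest.approx(990.0)

    def test_halved_pressure_symmetry(self):
        assert headspace_volume(100000.0, 50000.0, 750.0) == pytest.approx(750.0)

    def test_triplicates_averaged(self):
        v = headspace_volume(
            [100000.0, 100000.0, 100000.0], [1000.0, 1010.0, 990.0], [10.0, 10.0, 10.0]
        )
        expected = np.mean([99000.0 / 1000, 98990.0 / 1010, 99010.0 / 990]) * 10
        assert v == pytest.approx(expected)

    @pytest.mark.parametrize("dP", [0.0, -5.0, 100000.0, 150000.0])
    def test_unmeasurable_or_unphysical_drop(self, dP):
        with pytest.raises(DomainError):
            headspace_volume(100000.0, dP, 10.0)


class TestVheadUncertainty:
    def test_syringe_dominated_magnitude(self):
        sd = vhead_uncertainty(0.01, 0.0042, 1000.0)
        assert 1.0 < sd < 15.0
        assert sd == pytest.approx(10.0, abs=2.0)  # dominated by the 1% syringe term

    def test_no_error_sources(self):
        assert vhead_uncertainty(0.0, 0.0, 1000.0) == 0.0

    def test_scales_with_dominant_term(self):
        base = vhead_uncertainty(0.01, 0.0042, 1000.0)
        doubled = vhead_uncertainty(0.02, 0.0042, 1000.0)
        assert doubled / base == pytest.approx(2.0, rel=0.07)


class TestGasStateInvariants:
    def test_state_rejects_inconsistent_totals(self):
        with pytest.raises(DomainError):
            GasState(n_O2=1.0, n_CO2=0.0, n_N2=0.0, P=101325.0, T=293.15, V_head=1e-3)

    def test_mixture_fractions_validated(self):
        with pytest.raises(DomainError):
            GasMixture(0.5, 0.5, 0.5)
        with pytest.raises(DomainError):
            GasMixture(-0.1, 0.4, 0.7)
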