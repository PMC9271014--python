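import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oysterdeb.core import (
    OrganismState,
    acceleration_factor,
    compound_parameters,
    compute_fluxes,
    state_derivatives,
)
from oysterdeb.params import DEBParams


class TestComputeFluxes:
    def test_no_food_maintenance_persists(self, flat, flat_juvenile):
        fx = compute_fluxes(flat, flat_juvenile, f=0.0, T_corr=1.0)
        assert fx.p_X == 0.0 and fx.p_A == 0.0
        assert fx.p_S > 0.0

    def test_somatic_maintenance_from_tabulated_rate(self, flat):
        # [p_M] = 15.68 J/d/cm^3 and p_T = 0, so p_S = 15.68 J/d at V = 1
        st_ = OrganismState(E=flat.E_m, V=1.0, E_H=flat.E_Hp)
        fx = compute_fluxes(flat, st_, f=1.0, T_corr=1.0)
        assert fx.p_S == pytest.approx(15.68, rel=1e-12)

    def test_assimilation_formula(self, flat):
        # p_A = s * {p_Am}/s_M_ref * f * V^(2/3) * TC, by direct evaluation
        st_ = OrganismState(E=flat.E_m, V=1.0, E_H=flat.E_Hp)
        fx = compute_fluxes(flat, st_, f=1.0, T_corr=1.0, s=5.9)
        assert fx.p_A == pytest.approx(5.9 * flat.p_Am_base, rel=1e-12)
        # at the reference acceleration the printed rate is recovered
        assert 5.9 * flat.p_Am_base == pytest.approx(flat.p_Am, rel=1e-2)

    def test_no_feeding_before_birth(self, flat):
        embryo = OrganismState(E=1e-3, V=1e-8, E_H=flat.E_Hb / 2.0)
        fx = compute_fluxes(flat, embryo, f=1.0, T_corr=1.0, s=1.0)
        assert fx.p_A == 0.0 and fx.p_X == 0.0

    @settings(derandomize=True, max_examples=80)
    @given(
        e=st.floats(0.05, 1.0),
        V=st.floats(1e-6, 300.0),
        f=st.floats(0.0, 1.0),
        tc=st.floats(0.05, 3.0),
        s=st.floats(1.0, 6.0),
    )
    def test_kappa_rule_balance(self, flat, e, V, f, tc, s):
        st_ = OrganismState(E=e * flat.E_m * V, V=V, E_H=flat.E_Hp)
        fx = compute_fluxes(flat, st_, f=f, T_corr=tc, s=s)
        scale = max(abs(fx.p_C), 1.0)
        assert abs(fx.p_G + fx.p_S - flat.kap * fx.p_C) / scale < 1e-12
        assert abs(fx.p_R + fx.p_J - (1.0 - flat.kap) * fx.p_C) / scale < 1e-12

    def test_invalid_inputs_rejected(self, flat, flat_juvenile):
        with pytest.raises(ValueError):
            compute_fluxes(flat, flat_juvenile, f=1.2, T_corr=1.0)
        with pytest.raises(ValueError):
            compute_fluxes(flat, flat_juvenile, f=0.5, T_corr=-1.0)
        with pytest.raises(ValueError):
            OrganismState(E=-1.0, V=1.0, E_H=0.0)

    def test_starvation_flag(self, flat):
        st_ = OrganismState(E=0.01 * flat.E_m * 8.0, V=8.0, E_H=flat.E_Hp)
        fx = compute_fluxes(flat, st_, f=0.0, T_corr=1.0)
        assert fx.starving


class TestStateDerivatives:
    def test_maturity_ceiling_for_adults(self, flat, flat_adult):
        d = state_derivatives(flat, flat_adult, f=0.9, T_corr=1.0)
        assert d.dE_H == 0.0
        assert d.dE_R == pytest.approx(d.fluxes.p_R)

    def test_weak_homeostasis_reserve_equilibrium(self, flat):
        # at e = f the reserve DENSITY is stationary: d(E/V)/dt = 0,
        # i.e. dE = [E] dV while the animal still grows
        f = 0.7
        V = 1.3
        st_ = OrganismState(E=f * flat.E_m * V, V=V, E_H=flat.E_Hp)
        d = state_derivatives(flat, st_, f=f, T_corr=1.0, s=flat.s_M_ref)
        de_density = d.dE / V - (st_.E / V) * d.dV / V
        assert abs(de_density) / (st_.E / V) < 1e-12
        assert d.dV > 0.0

    def test_starvation_pays_from_buffer_then_structure(self, flat):
        V = 8.0
        hungry = OrganismState(E=0.01 * flat.E_m * V, V=V, E_H=flat.E_Hp, E_R=100.0)
        d = state_derivatives(flat, hungry, f=0.0, T_corr=1.0)
        assert d.starving and d.dV == 0.0 and d.dE_R < 0.0
        broke = hungry.replace(E_R=0.0)
        d2 = state_derivatives(flat, broke, f=0.0, T_corr=1.0)
        assert d2.dV < 0.0  # shrinking structure at cost E_G

    def test_ageing_states_grow_from_zero(self, flat, flat_adult):
        d = state_derivatives(flat, flat_adult, f=1.0, T_corr=1.0)
        assert d.dq > 0.0
        assert d.dh == pytest.approx(flat_adult.q - (d.dV / flat_adult.V) * flat_adult.h)


class TestAccelerationFactor:
    def test_piecewise_stages(self, flat):
        assert acceleration_factor(flat, flat.E_Hs / 2.0, 1e-9) == 1.0
        assert acceleration_factor(flat, flat.E_Hj * 2.0, 1e-3) == flat.s_M_ref
        mid = acceleration_factor(flat, (flat.E_Hs + flat.E_Hj) / 2.0, 8e-6, L_s=1e-2)
        assert mid == pytest.approx(8e-6 ** (1 / 3) / 1e-2)

    def test_window_requires_settlement_length(self, flat):
        with pytest.raises(ValueError):
            acceleration_factor(flat, (flat.E_Hs + flat.E_Hj) / 2.0, 1e-6)


class TestCompoundParameters:
    def test_reserve_capacity_of_both_species(self, flat, gigas):
        assert compound_parameters(flat)["E_m"] == pytest.approx(91.0 / 0.020)  # 4550
        assert compound_parameters(gigas)["E_m"] == pytest.approx(372.0 / 0.0054, rel=1e-6)
        assert compound_parameters(flat)["E_m"] < compound_parameters(gigas)["E_m"]

    def test_allocation_contrast(self, flat, gigas):
        assert flat.kap == 0.92
        assert gigas.kap == 0.26
        assert flat.kap > gigas.kap

    def test_unit_zoom_definition(self):
        # z = kap * p_Am / p_M = 1 by construction -> L_m = 1 cm
        p = DEBParams(p_Am=100.0, v=0.02, kap=0.5, p_M=50.0, E_G=2000.0,
                      k_J=0.002, kap_R=0.95, s_M_ref=1.0)
        cp = compound_parameters(p)
        assert cp["L_m_base"] == pytest.approx(1.0)
        assert cp["z"] == pytest.approx(1.0)

    def test_lifecycle_acceleration_close_to_reference(self, flat):
        cp = compound_parameters(flat, f=1.0, s_M="lifecycle")
        assert cp["s_M"] == pytest.approx(5.9, rel=0.10)
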