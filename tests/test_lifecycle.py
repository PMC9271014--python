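import math

import numpy as np
import pytest

from oysterdeb.core import OrganismState
from oysterdeb.environment import Forcing
from oysterdeb.lifecycle import (
    BroodState,
    apply_spawning,
    brood_duration,
    brooding_multiplier,
    detect_events,
    embryo_solution,
    initial_reserve,
    lifecycle_acceleration,
    lifespan,
)
from oysterdeb.simulate import SimOptions, simulate


class TestInitialReserve:
    def test_fixed_point_property(self, flat):
        # the defining property: re-integration reaches E_Hb at density e_b
        for e_b in (0.6, 1.0):
            E0 = initial_reserve(flat, e_b=e_b)
            sol = embryo_solution(flat, E_0=E0)
            assert sol.reached
            assert abs(sol.scaled_reserve_density(flat) - e_b) < 1e-6

    def test_monotone_in_birth_density(self, flat):
        e_grid = [0.4, 0.6, 0.8, 1.0]
        E0s = [initial_reserve(flat, e_b=e) for e in e_grid]
        assert all(b > a for a, b in zip(E0s, E0s[1:]))

    def test_egg_cost_exceeds_maturation_floor(self, flat):
        # the egg must at least pay the maturation bill E_Hb/(1-kap)
        E0 = initial_reserve(flat, e_b=1.0)
        assert E0 > flat.E_Hb / (1.0 - flat.kap)

    def test_invalid_e_b(self, flat):
        with pytest.raises(ValueError):
            initial_reserve(flat, e_b=0.0)


@pytest.fixture(scope="module")
def larval_traj(flat, flat_birth):
    return simulate(
        flat, Forcing.constant(19.95, f=1.0), flat_birth.state,
        horizon=2000.0, age_offset=flat_birth.age,
        options=SimOptions(spawning=False, stop_at="metamorphosis"),
    )


class TestEvents:

    def test_event_ordering_follows_thresholds(self, flat, larval_traj):
        ev = detect_events(larval_traj, flat)
        names = [e.name for e in ev]
        assert names == ["release", "settlement", "metamorphosis"]
        ages = [e.age for e in ev]
        assert all(b > a for a, b in zip(ages, ages[1:]))
        lengths = [e.length for e in ev]
        assert all(b >= a for a, b in zip(lengths, lengths[1:]))

    def test_acceleration_factor_near_published_value(self, flat):
        s_M = lifecycle_acceleration(flat, f=1.0)
        assert s_M == pytest.approx(5.9, rel=0.10)

    def test_gigas_acceleration(self, gigas):
        assert lifecycle_acceleration(gigas, f=1.0) == pytest.approx(4.8, rel=0.10)

    def test_event_ages_stable_under_tighter_tolerance(self, flat, flat_birth):
        kw = dict(horizon=300.0, age_offset=flat_birth.age)
        t1 = simulate(flat, Forcing.constant(19.95, f=1.0), flat_birth.state,
                      options=SimOptions(spawning=False, stop_at="settlement"), **kw)
        t2 = simulate(flat, Forcing.constant(19.95, f=1.0), flat_birth.state,
                      options=SimOptions(spawning=False, stop_at="settlement",
                                         rtol=1e-10, atol=1e-12), **kw)
        a1 = {e.name: e.age for e in detect_events(t1, flat)}
        a2 = {e.name: e.age for e in detect_events(t2, flat)}
        for name in a1:
            assert a1[name] == pytest.approx(a2[name], rel=1e-4)

    def test_release_age_matches_embryo_solution(self, flat):
        # consistency: the trajectory's release crossing equals the inner
        # embryo integration continued to E_Hr
        birth = embryo_solution(flat, e_b=1.0)
        to_release = embryo_solution(flat, E_0=birth.E_0, target=flat.E_Hr)
        assert to_release.age > birth.age  # release strictly after birth
        assert brood_duration(flat) == pytest.approx(to_release.age, rel=1e-6)


class TestSpawning:
    def test_buffer_fraction_arithmetic(self, flat, flat_adult):
        st = flat_adult.replace(E_R=100.0)
        new, rec = apply_spawning(st, flat, E_0=0.02)
        assert new.E_R == pytest.approx(55.0)  # kap_R = 0.45
        assert rec.energy == pytest.approx(45.0)
        assert rec.eggs == pytest.approx(45.0 / 0.02)

    def test_zero_efficiency_is_noop(self, flat, flat_adult):
        p = flat.replace(kap_R=0.0)
        new, rec = apply_spawning(flat_adult, p, E_0=0.02)
        assert new.E_R == flat_adult.E_R
        assert rec.energy == 0.0

    def test_spawning_before_puberty_rejected(self, flat, flat_juvenile):
        with pytest.raises(ValueError):
            apply_spawning(flat_juvenile, flat)

    def test_egg_count_linear_in_released_energy(self, flat, flat_adult):
        _, r1 = apply_spawning(flat_adult.replace(E_R=100.0), flat, E_0=0.02)
        _, r2 = apply_spawning(flat_adult.replace(E_R=200.0), flat, E_0=0.02)
        assert r2.eggs == pytest.approx(2.0 * r1.eggs)

    def test_flat_oyster_spawning_starts_brooding(self, flat, gigas, flat_adult):
        new, _ = apply_spawning(flat_adult, flat, E_0=0.02, t=12.0)
        assert new.brooding and new.brood_start == 12.0
        g_adult = OrganismState(E=0.9 * gigas.E_m, V=1.0, E_H=gigas.E_Hp, E_R=50.0)
        new_g, _ = apply_spawning(g_adult, gigas, E_0=1e-3)
        assert not new_g.brooding  # broadcast spawner


class TestBrooding:
    def test_multiplier_states(self):
        assert brooding_multiplier(BroodState(active=True)) == 0.8
        assert brooding_multiplier(BroodState(active=False)) == 1.0
        assert brooding_multiplier(None) == 1.0

    def test_multiplier_reverts_at_recorded_end(self):
        b = BroodState(active=True, start=0.0, end=10.0)
        assert brooding_multiplier(b, t=5.0) == 0.8
        assert brooding_multiplier(b, t=10.0) == 1.0

    def test_brood_duration_shorter_when_warm(self, flat):
        assert brood_duration(flat, T_C=25.0) < brood_duration(flat, T_C=15.0)


class TestLifespan:
    def test_no_ageing_no_death(self, flat):
        p = flat.replace(h_a=1e-30)
        assert math.isinf(lifespan(p, f=0.9, horizon=20_000.0))

    def test_warmer_is_shorter(self, flat):
        cold = lifespan(flat, f=0.9, T_C=12.0)
        warm = lifespan(flat, f=0.9, T_C=24.0)
        assert warm < cold

    def test_magnitude_of_predicted_lifespan(self, flat):
        # printed model prediction is 1.19e4 d
        am = lifespan(flat, f=0.9)
        assert am == pytest.approx(1.19e4, rel=0.30)
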