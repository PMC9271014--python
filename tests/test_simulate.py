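import numpy as np
import pytest

from oysterdeb.core import OrganismState
from oysterdeb.environment import Forcing
from oysterdeb.observables import dry_weight
from oysterdeb.simulate import SimOptions, init_from_weight, run_scenario, simulate


class TestInitFromWeight:
    def test_round_trip_is_identity(self, flat):
        for w in (0.1, 0.87, 25.0):
            st = init_from_weight(flat, w, wet=True)
            ww = dry_weight(st, flat) / flat.aux.dw_ww_ratio
            assert ww == pytest.approx(w, rel=1e-9)

    def test_zero_reserve_boundary(self, flat):
        st = init_from_weight(flat, 1.0, wet=False, e=0.0, E_R=0.0)
        assert st.E == 0.0
        assert flat.aux.d_V * st.V == pytest.approx(1.0, rel=1e-12)

    def test_matches_dense_grid_inversion(self, flat):
        # brute-force oracle: scan V and pick the best weight match
        target = 2.5
        st = init_from_weight(flat, target, wet=False, e=0.8)
        V_grid = np.linspace(1e-6, 30.0, 400_001)
        w_grid = flat.aux.d_V * V_grid + flat.aux.w_E * 0.8 * flat.E_m * V_grid / flat.aux.mu_E
        V_best = V_grid[np.argmin(np.abs(w_grid - target))]
        assert st.V == pytest.approx(V_best, rel=1e-4)

    def test_infeasible_weight_rejected(self, flat):
        with pytest.raises(ValueError):
            init_from_weight(flat, 1e-6, wet=False, E_R=10.0)


class TestSimulate:
    def test_deterministic_byte_for_byte(self, flat, flat_juvenile):
        fc = Forcing.constant(18.0, f=0.8)
        t1 = simulate(flat, fc, flat_juvenile, horizon=60.0)
        t2 = simulate(flat, fc, flat_juvenile, horizon=60.0)
        assert t1.time == t2.time
        assert all(np.array_equal(a, b) for a, b in zip(t1._rows, t2._rows))

    def test_growth_orders_with_food(self, flat):
        st = init_from_weight(flat, 0.87, wet=True, e=0.8)
        out = {}
        for f in (0.84, 0.52):
            tr = simulate(flat, Forcing.constant(20.0, f=f), st, horizon=42.0,
                          options=SimOptions(spawning=False))
            out[f] = dry_weight(tr.final_state, flat) - dry_weight(st, flat)
        assert out[0.84] > out[0.52] > 0.0

    def test_starvation_ends_with_death_flag(self, flat, flat_birth):
        tr = simulate(flat, Forcing.constant(19.95, f=0.0), flat_birth.state,
                      horizon=2000.0, options=SimOptions(spawning=False))
        assert tr.died and tr.death_time is not None
        E = tr.column("E")
        assert np.all(np.diff(E) <= 1e-9)  # reserve declines monotonically

    def test_grid_independence(self, flat, flat_juvenile):
        fc = Forcing.constant(18.0, f=0.8)
        t1 = simulate(flat, fc, flat_juvenile, horizon=30.0,
                      t_eval=np.arange(0.0, 30.1, 1.0))
        t2 = simulate(flat, fc, flat_juvenile, horizon=30.0,
                      t_eval=np.arange(0.0, 30.1, 0.5))
        w1 = {t: dry_weight(t1.state_at_index(i), flat) for i, t in enumerate(t1.time)}
        w2 = {t: dry_weight(t2.state_at_index(i), flat) for i, t in enumerate(t2.time)}
        for t in w1:
            assert w1[t] == pytest.approx(w2[t], rel=1e-9)

    def test_maturity_monotone_until_puberty(self, flat, flat_birth):
        tr = simulate(flat, Forcing.constant(19.95, f=1.0), flat_birth.state,
                      horizon=400.0, options=SimOptions(spawning=False))
        EH = tr.column("E_H")
        assert np.all(np.diff(EH) >= -1e-12)
        assert np.all(EH <= flat.E_Hp * (1.0 + 1e-9))

    def test_mid_acceleration_start_requires_L_s(self, flat):
        mid = OrganismState(E=1e-2, V=8e-6, E_H=(flat.E_Hs + flat.E_Hj) / 2.0)
        with pytest.raises(ValueError, match="L_s"):
            simulate(flat, Forcing.constant(19.95, f=1.0), mid, horizon=10.0)

    def test_chl_forcing_requires_K_X(self, flat):
        p = flat.replace(K_X=None)
        st = init_from_weight(p, 1.0, wet=True)
        with pytest.raises(ValueError, match="K_X"):
            simulate(p, Forcing.constant(15.0, chl=2.0), st, horizon=5.0)


@pytest.fixture(scope="module")
def spawning_traj(flat):
    st = init_from_weight(flat, 40.0, wet=True, e=0.95)
    # warm, food-rich water: buffer builds and the trigger fires
    return simulate(flat, Forcing.constant(20.0, f=0.95), st, horizon=500.0,
                    options=SimOptions(spawn_buffer_frac=0.02))


class TestSpawningInSimulation:

    def test_spawn_records_and_buffer_drop(self, spawning_traj):
        assert len(spawning_traj.spawns) >= 1
        rec = spawning_traj.spawns[0]
        assert rec.energy > 0 and rec.eggs > 0

    def test_spawning_starts_brooding_for_flat_oyster(self, spawning_traj):
        names = [e.name for e in spawning_traj.events]
        assert "spawning" in names
        assert "brood_release" in names  # incubation ended within the run

    def test_energy_balance_includes_spawned_energy(self, spawning_traj):
        bal = spawning_traj.energy_balance()
        assert abs(bal["relative"]) < 1e-6

    def test_cold_water_blocks_spawning(self, flat):
        st = init_from_weight(flat, 40.0, wet=True, e=0.95)
        tr = simulate(flat, Forcing.constant(10.0, f=0.95), st, horizon=200.0,
                      options=SimOptions(spawn_buffer_frac=0.02))
        assert len(tr.spawns) == 0


class TestRunScenario:
    def test_self_consistent_observations_give_zero_mre(self, flat):
        fc = Forcing.constant(18.0, f=0.8)
        st = init_from_weight(flat, 1.0, wet=True, e=0.8)
        tr = simulate(flat, fc, st, horizon=42.0, options=SimOptions(spawning=False))
        days = [7.0, 14.0, 21.0, 28.0, 35.0, 42.0]
        t = np.asarray(tr.time)
        dws = [dry_weight(tr.state_at_index(int(np.argmin(np.abs(t - d)))), flat)
               for d in days]
        res = run_scenario({
            "species": "o_edulis",
            "forcing": fc,
            "init": {"wet_weight_g": 1.0, "e": 0.8},
            "days": 42.0,
            "options": {"spawning": False},
            "observations": [{
                "name": "self", "kind": "growth", "x": days, "y": dws,
                "context": {"init": {"wet_weight_g": 1.0, "e": 0.8},
                            "options": SimOptions(spawning=False)},
            }],
        })
        assert res.errors["MRE"] == pytest.approx(0.0, abs=1e-9)

    def test_outputs_written(self, flat, tmp_path):
        res = run_scenario({
            "species": "o_edulis",
            "forcing": Forcing.constant(18.0, f=0.8),
            "init": {"wet_weight_g": 1.0},
            "days": 10.0,
            "out_dir": tmp_path,
        })
        assert (tmp_path / "observables.csv").exists()
        assert (tmp_path / "run_manifest.json").exists()
        assert len(res.observables) >= 10
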