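import math

import numpy as np
import pytest

from oysterdeb.estimation import (
    UniVariateDataset,
    ZeroVariateDatum,
    calibrate_KX,
    estimate,
    loss_mre,
    predict_all,
    predict_dataset,
)
from oysterdeb.environment import functional_response
from oysterdeb.synthetic import SyntheticSpec, generate_growth_series


def _zv(name, value, weight=1.0, **ctx):
    return ZeroVariateDatum(name=name, value=value, weight=weight, context=ctx)


class TestLossMRE:
    def test_perfect_predictions_give_zero(self):
        ds = [_zv("Li", 10.0), _zv("Wdi", 5.0)]
        assert loss_mre(ds, {"Li": [10.0], "Wdi": [5.0]}) == 0.0

    def test_single_datum_hand_case(self):
        # Y = 2, Yhat = 1, beta = 1: sqrt(((2-1)/2)^2) = 0.5
        ds = [_zv("Li", 2.0)]
        assert loss_mre(ds, {"Li": [1.0]}) == pytest.approx(0.5)

    def test_weight_scale_invariance(self):
        d1 = [_zv("Li", 2.0, weight=1.0), _zv("Wdi", 3.0, weight=2.0)]
        d2 = [_zv("Li", 2.0, weight=5.0), _zv("Wdi", 3.0, weight=10.0)]
        preds = {"Li": [1.5], "Wdi": [4.0]}
        assert loss_mre(d1, preds) == pytest.approx(loss_mre(d2, preds), rel=1e-14)

    def test_dataset_order_invariance(self):
        d = [_zv("Li", 2.0), _zv("Wdi", 3.0, weight=0.3)]
        preds = {"Li": [1.5], "Wdi": [4.0]}
        assert loss_mre(d, preds) == loss_mre(d[::-1], preds)

    def test_uni_variate_points_share_unit_weight(self):
        # a 4-point series with default weights counts like one datum
        uni = UniVariateDataset(name="g", kind="growth",
                               x=[1, 2, 3, 4], y=[1.0, 1.0, 1.0, 1.0])
        zv = _zv("Li", 1.0)
        preds = {"g": np.full(4, 2.0), "Li": [2.0]}
        assert loss_mre([uni], {"g": preds["g"]}) == pytest.approx(
            loss_mre([zv], {"Li": preds["Li"]})
        )

    def test_error_paths(self):
        with pytest.raises(ValueError):
            _zv("Li", 0.0)  # Y = 0 undefined
        ds = [_zv("Li", 2.0, weight=0.0)]
        with pytest.raises(ValueError):
            loss_mre(ds, {"Li": [1.0]})  # total weight 0
        with pytest.raises(KeyError):
            loss_mre([_zv("Li", 2.0)], {})
        with pytest.raises(ValueError):
            loss_mre([_zv("Li", 2.0)], {"Li": [1.0, 2.0]})  # length mismatch

    def test_symmetric_variant(self):
        ds = [_zv("Li", 2.0)]
        # |2-1| / ((2+1)/2) = 2/3
        assert loss_mre(ds, {"Li": [1.0]}, symmetric=True) == pytest.approx(2.0 / 3.0)


class TestPredictDispatch:
    def test_unknown_trait_lists_registry(self, flat):
        with pytest.raises(KeyError, match="registered"):
            predict_dataset(flat, _zv("no_such_trait", 1.0))

    def test_unknown_kind_lists_registry(self, flat):
        ds = UniVariateDataset(name="x", kind="no_such_kind", x=[1.0], y=[1.0])
        with pytest.raises(KeyError, match="registered"):
            predict_dataset(flat, ds)

    def test_growth_series_predicts_itself(self, flat):
        ds, _ = generate_growth_series(SyntheticSpec(
            flat, {"kind": "constant", "T_C": 18.0, "f": 0.8},
            schedule=[10.0, 20.0, 30.0], init={"wet_weight_g": 1.0}, name="self"))
        pred = predict_dataset(flat, ds)
        assert np.allclose(pred, ds.y, rtol=1e-9)

    def test_zero_variate_age_at_birth_dispatches_to_embryo(self, flat):
        from oysterdeb.lifecycle import embryo_solution

        val = predict_dataset(flat, _zv("ab", 10.0))[0]
        assert val == pytest.approx(embryo_solution(flat, e_b=1.0).age, rel=1e-9)

    def test_fecundity_series_uses_reproduction_rate(self, flat):
        from oysterdeb.observables import reproduction_rate

        ds = UniVariateDataset(name="fec", kind="fecundity_vs_length",
                               x=[5.0, 8.0], y=[1.0, 1.0],
                               context={"f": 1.0, "per_year": False})
        pred = predict_dataset(flat, ds)
        expect = [reproduction_rate(flat, f=1.0, L=5.0 * flat.del_M),
                  reproduction_rate(flat, f=1.0, L=8.0 * flat.del_M)]
        assert np.allclose(pred, expect, rtol=1e-9)

    def test_respiration_series_shape(self, flat):
        ds = UniVariateDataset(name="resp", kind="respiration_vs_T",
                               x=[10.0, 15.0, 20.0, 25.0], y=[1.0, 1.0, 1.0, 1.0],
                               context={"f": 0.8, "init": {"wet_weight_g": 1.0}})
        pred = predict_dataset(flat, ds)
        assert np.all(np.diff(pred) > 0)  # rising within the tolerance range


class TestEstimate:
    def test_zero_free_parameters_returns_init(self, flat):
        ds, _ = generate_growth_series(SyntheticSpec(
            flat, {"kind": "constant", "T_C": 18.0, "f": 0.8},
            schedule=[10.0, 30.0], init={"wet_weight_g": 1.0}, name="g"))
        res = estimate(flat, [ds], free=())
        assert res.params == flat
        assert res.mre == pytest.approx(0.0, abs=1e-12)

    def test_trace_non_increasing(self, flat):
        ds, _ = generate_growth_series(SyntheticSpec(
            flat, {"kind": "constant", "T_C": 18.0, "f": 0.8},
            schedule=[10.0, 30.0, 60.0], init={"wet_weight_g": 1.0}, name="g"))
        init = flat.replace(p_Am=flat.p_Am * 1.15)
        res = estimate(init, [ds], free=("p_Am",), max_iterations=60, restarts=1)
        assert all(b <= a + 1e-15 for a, b in zip(res.trace, res.trace[1:]))
        assert res.mre < 1e-3

    def test_three_parameter_subset_recovery(self, flat):
        # identifiable 3-subset {v, kap, p_M} from noise-free data
        sched = np.linspace(15, 180, 6)
        d1, _ = generate_growth_series(SyntheticSpec(
            flat, {"kind": "constant", "T_C": 19.95, "f": 0.8},
            sched, {"wet_weight_g": 1.0}, name="g1"))
        d2, _ = generate_growth_series(SyntheticSpec(
            flat, {"kind": "constant", "T_C": 19.95, "f": 0.5},
            sched, {"wet_weight_g": 1.0}, name="g2", response="length_cm"))
        from oysterdeb.synthetic import generate_zero_variate_table

        zv = generate_zero_variate_table(flat, [("Li", {"f": 1.0}), ("rB", {"f": 0.8})])
        free = ("v", "kap", "p_M")
        rng = np.random.default_rng(7)
        pert = {n: getattr(flat, n) * rng.uniform(0.85, 1.15) for n in free}
        pert["kap"] = min(pert["kap"], 0.99)  # fractions stay in (0, 1)
        init = flat.replace(**pert)
        res = estimate(init, [d1, d2] + zv, free=free, max_iterations=400, restarts=2)
        assert res.mre < 0.01
        for n in free:
            assert getattr(res.params, n) == pytest.approx(getattr(flat, n), rel=0.05)

    def test_infeasible_start_raises_with_dataset_name(self, flat):
        bad = UniVariateDataset(name="badgrowth", kind="growth",
                                x=[5.0], y=[1.0], context={})  # no init rule
        with pytest.raises((RuntimeError, ValueError)):
            estimate(flat, [bad], free=("p_Am",))


@pytest.fixture(scope="module")
def chl_datasets(flat):
    sched = np.linspace(7, 42, 4)
    out = []
    for chl in (2.0, 10.0):
        ds, _ = generate_growth_series(SyntheticSpec(
            flat, {"kind": "constant", "T_C": 20.0, "chl": chl},
            sched, {"wet_weight_g": 0.87}, name=f"chl{chl:g}"))
        out.append(ds)
    return out


class TestCalibrateKX:

    def test_recovers_true_half_saturation(self, flat, chl_datasets):
        k = calibrate_KX(flat.replace(K_X=5.0), chl_datasets)
        assert k == pytest.approx(1.84, rel=0.02)

    def test_implied_food_levels_match_published(self, flat, chl_datasets):
        k = calibrate_KX(flat.replace(K_X=5.0), chl_datasets)
        assert round(functional_response(2.0, k), 2) == pytest.approx(0.52)
        assert round(functional_response(10.0, k), 2) == pytest.approx(0.84)

    def test_scale_equivariance(self, flat):
        # doubling the chlorophyll everywhere doubles the recovered K_X
        sched = np.linspace(7, 42, 4)
        doubled = []
        for chl in (4.0, 20.0):
            ds, _ = generate_growth_series(SyntheticSpec(
                flat.replace(K_X=3.68), {"kind": "constant", "T_C": 20.0, "chl": chl},
                sched, {"wet_weight_g": 0.87}, name=f"chl{chl:g}"))
            doubled.append(ds)
        k2 = calibrate_KX(flat.replace(K_X=5.0), doubled)
        assert k2 == pytest.approx(2.0 * 1.84, rel=0.02)

    def test_non_chl_dataset_rejected(self, flat):
        ds, _ = generate_growth_series(SyntheticSpec(
            flat, {"kind": "constant", "T_C": 20.0, "f": 0.8},
            [10.0], {"wet_weight_g": 1.0}, name="fmode"))
        with pytest.raises(ValueError):
            calibrate_KX(flat, [ds])
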