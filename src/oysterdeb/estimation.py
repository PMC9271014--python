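"""Parameter estimation: datasets, the MRE loss and the covariation fit.

The loss is the weighted root-mean squared relative error

    MRE = sqrt( sum_ij beta_ij ((Y_ij - Yhat_ij)/Y_ij)^2 / sum_ij beta_ij )

over all zero-variate data (single trait values, each its own dataset)
and uni-variate datasets (paired series). By convention each dataset
carries unit total weight: beta = 1 per zero-variate datum and 1/m_i per
point of a uni-variate dataset with m_i points, so datasets — not
points — are the weighting unit. A symmetric-relative-error variant
(denominator |Y| + |Yhat|)/2 per point, mean of absolute values) is
available for cross-checking against parameter sets estimated under
that convention.

Minimisation follows the covariation approach: all free parameters are
varied simultaneously by the Nelder-Mead simplex (standard reflection /
expansion / contraction coefficients 1, 2, 0.5, 0.5) in log10 space
(logit space for the fractions kap, kap_X, kap_R), with restarts from
the best vertex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .core import OrganismState, compound_parameters
from .environment import Forcing, functional_response
from .params import DEBParams

__all__ = [
    "ZeroVariateDatum",
    "UniVariateDataset",
    "EstimationResult",
    "loss_mre",
    "predict_dataset",
    "estimate",
    "calibrate_KX",
    "register_zero_variate",
    "register_uni_variate",
    "dataset_from_dict",
]


# ---------------------------------------------------------------------------
# dataset model

@dataclass(frozen=True)
class ZeroVariateDatum:
    """A single observed trait value with estimation weight and context.

    ``context`` may carry ``T_C`` (deg C), ``f`` and ``e_b``; unspecified
    entries default to the reference temperature and ad-libitum food.
    """

    name: str
    value: float
    unit: str = ""
    weight: float = 1.0
    context: Mapping[str, float] = field(default_factory=dict)
    ref: str = ""

    def __post_init__(self) -> None:
        if self.value == 0:
            raise ValueError(f"zero-variate datum {self.name!r}: relative error undefined for Y=0")
        if self.weight < 0:
            raise ValueError("weights must be non-negative")

    @property
    def y(self) -> np.ndarray:
        return np.array([self.value])

    @property
    def weights(self) -> np.ndarray:
        return np.array([self.weight])


@dataclass(frozen=True)
class UniVariateDataset:
    """A paired observation series (e.g. dry weight versus time).

    ``kind`` selects the prediction route: ``growth`` (response vs time
    under the context's forcing and initial state), ``age_length``,
    ``respiration_vs_T`` or ``fecundity_vs_length``. Per-point weights
    default to 1/m so the dataset carries unit total weight.
    """

    name: str
    kind: str
    x: np.ndarray
    y: np.ndarray
    weights: Optional[np.ndarray] = None
    context: Mapping[str, object] = field(default_factory=dict)
    response: str = "dw_g"
    ref: str = ""

    def __post_init__(self) -> None:
        x = np.atleast_1d(np.asarray(self.x, dtype=float))
        y = np.atleast_1d(np.asarray(self.y, dtype=float))
        if x.shape != y.shape or x.size < 1:
            raise ValueError(f"dataset {self.name!r}: x and y must be equal-length, non-empty")
        if np.any(y == 0):
            raise ValueError(f"dataset {self.name!r}: relative error undefined for Y=0")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if self.weights is None:
            w = np.full(x.size, 1.0 / x.size)
        else:
            w = np.broadcast_to(np.asarray(self.weights, dtype=float), x.shape).astype(float)
            if np.any(w < 0):
                raise ValueError("weights must be non-negative")
        object.__setattr__(self, "weights", w)


Dataset = Union[ZeroVariateDatum, UniVariateDataset]


# ---------------------------------------------------------------------------
# loss

def loss_mre(
    datasets: Sequence[Dataset],
    predictions: Mapping[str, np.ndarray],
    symmetric: bool = False,
) -> float:
    """Weighted root-mean squared relative error between data and predictions.

    ``predictions`` maps dataset name to the matched prediction array
    (one value per observation). With ``symmetric=True`` the mean of
    absolute symmetric relative errors |Y-Yhat| / ((|Y|+|Yhat|)/2) is
    returned instead.
    """
    num = 0.0
    den = 0.0
    for ds in datasets:
        if ds.name not in predictions:
            raise KeyError(f"no prediction supplied for dataset {ds.name!r}")
        yhat = np.atleast_1d(np.asarray(predictions[ds.name], dtype=float))
        y = ds.y
        if yhat.shape != y.shape:
            raise ValueError(
                f"dataset {ds.name!r}: {y.size} observations but {yhat.size} predictions"
            )
        w = ds.weights
        if symmetric:
            denom = (np.abs(y) + np.abs(yhat)) / 2.0
            num += float(np.sum(w * np.abs(y - yhat) / denom))
        else:
            num += float(np.sum(w * ((y - yhat) / y) ** 2))
        den += float(np.sum(w))
    if den <= 0:
        raise ValueError("total weight must be positive")
    return num / den if symmetric else math.sqrt(num / den)


# ---------------------------------------------------------------------------
# prediction dispatch

_ZERO_VARIATE: dict[str, Callable[[DEBParams, Mapping], float]] = {}
_UNI_VARIATE: dict[str, Callable[[DEBParams, UniVariateDataset], np.ndarray]] = {}


def register_zero_variate(name: str):
    def deco(fn):
        _ZERO_VARIATE[name] = fn
        return fn
    return deco


def register_uni_variate(kind: str):
    def deco(fn):
        _UNI_VARIATE[kind] = fn
        return fn
    return deco


def _ctx_f(params: DEBParams, ctx: Mapping) -> float:
    if "f" in ctx:
        return float(ctx["f"])
    if "chl" in ctx:
        if params.K_X is None:
            raise ValueError("chlorophyll context requires params.K_X")
        return functional_response(float(ctx["chl"]), params.K_X)
    return 1.0


@register_zero_variate("ab")
def _predict_ab(params, ctx):
    from .lifecycle import embryo_solution

    sol = embryo_solution(params, e_b=float(ctx.get("e_b", 1.0)), T_C=ctx.get("T_C"))
    return sol.age


@register_zero_variate("Lb")
def _predict_Lb(params, ctx):
    from .lifecycle import embryo_solution
    from .observables import physical_length

    sol = embryo_solution(params, e_b=float(ctx.get("e_b", 1.0)), T_C=ctx.get("T_C"))
    return physical_length(sol.state.V, params, E_H=sol.state.E_H)


@register_zero_variate("Wd0")
def _predict_Wd0(params, ctx):
    from .lifecycle import initial_reserve

    E_0 = initial_reserve(params, e_b=float(ctx.get("e_b", 1.0)), T_C=ctx.get("T_C"))
    return params.aux.w_E * E_0 / params.aux.mu_E


@register_zero_variate("Li")
def _predict_Li(params, ctx):
    f = _ctx_f(params, ctx)
    return compound_parameters(params, f=f)["Lw_i"]


@register_zero_variate("Wdi")
def _predict_Wdi(params, ctx):
    from .observables import dry_weight

    f = _ctx_f(params, ctx)
    Vi = compound_parameters(params, f=f)["L_i"] ** 3
    st = OrganismState(E=f * params.E_m * Vi, V=Vi,
                       E_H=params.E_Hp if params.E_Hp is not None else 0.0)
    return dry_weight(st, params)


@register_zero_variate("rB")
def _predict_rB(params, ctx):
    from .environment import CELSIUS_OFFSET, temperature_correction

    f = _ctx_f(params, ctx)
    rb = compound_parameters(params, f=f)["r_B"]
    if "T_C" in ctx:
        rb *= temperature_correction(params.temp, float(ctx["T_C"]) + CELSIUS_OFFSET)
    return rb


@register_zero_variate("am")
def _predict_am(params, ctx):
    from .lifecycle import lifespan

    return lifespan(params, f=_ctx_f(params, ctx), T_C=ctx.get("T_C"))


@register_zero_variate("Ri")
def _predict_Ri(params, ctx):
    from .observables import reproduction_rate

    f = _ctx_f(params, ctx)
    L = float(ctx.get("L", compound_parameters(params, f=f)["L_i"]))
    per_year = bool(ctx.get("per_year", False))
    R = reproduction_rate(params, f=f, L=L, T_C=ctx.get("T_C"), E_0=ctx.get("E_0"))
    return R * 365.0 if per_year else R


@register_zero_variate("Wwp")
def _predict_Wwp(params, ctx):
    from .environment import Forcing as _F
    from .lifecycle import embryo_solution
    from .observables import wet_weight
    from .simulate import SimOptions, simulate

    f = _ctx_f(params, ctx)
    T_C = ctx.get("T_C", params.temp.T_ref - 273.15)
    birth = embryo_solution(params, e_b=min(1.0, max(f, 0.2)), T_C=T_C)
    traj = simulate(params, _F.constant(T_C, f=f), birth.state, horizon=5000.0,
                    options=SimOptions(spawning=False, stop_at="puberty"))
    ev = {e.name: e for e in traj.events}
    if "puberty" not in ev:
        raise RuntimeError("puberty not reached within the trait-evaluation horizon")
    return wet_weight(ev["puberty"].state, params)


def _growth_sim(params: DEBParams, ds: UniVariateDataset):
    from .simulate import SimOptions, init_from_weight, simulate

    ctx = dict(ds.context)
    forcing = ctx.get("forcing")
    if forcing is None:
        T_C = float(ctx.get("T_C", params.temp.T_ref - 273.15))
        if "chl" in ctx:
            forcing = Forcing.constant(T_C, chl=float(ctx["chl"]))
        else:
            forcing = Forcing.constant(T_C, f=float(ctx.get("f", 1.0)))
    init = ctx.get("init")
    if isinstance(init, OrganismState):
        state = init
    elif isinstance(init, Mapping) and "wet_weight_g" in init:
        state = init_from_weight(params, float(init["wet_weight_g"]), wet=True,
                                 e=float(init.get("e", 0.8)))
    elif isinstance(init, Mapping) and "dry_weight_g" in init:
        state = init_from_weight(params, float(init["dry_weight_g"]), wet=False,
                                 e=float(init.get("e", 0.8)))
    else:
        raise ValueError(f"dataset {ds.name!r}: growth context needs an init rule")
    opts = ctx.get("options") or SimOptions(spawning=bool(ctx.get("spawning", False)))
    horizon = float(np.max(ds.x))
    t_eval = np.unique(np.concatenate([[0.0], np.asarray(ds.x, dtype=float)]))
    return simulate(params, forcing, state, horizon=horizon, t_eval=t_eval, options=opts)


@register_uni_variate("growth")
def _predict_growth(params, ds):
    from .observables import dry_weight, physical_length, wet_weight

    traj = _growth_sim(params, ds)
    t = np.asarray(traj.time)
    vals = []
    for i in range(len(t)):
        st = traj.state_at_index(i)
        if ds.response == "dw_g":
            vals.append(dry_weight(st, params))
        elif ds.response == "ww_g":
            vals.append(wet_weight(st, params))
        elif ds.response == "length_cm":
            vals.append(physical_length(st.V, params, E_H=st.E_H))
        else:
            raise ValueError(f"unknown growth response {ds.response!r}")
    # match observation days to the simulated grid (within 0.5 d)
    vals = np.asarray(vals)
    out = np.empty(ds.x.size)
    for j, xj in enumerate(ds.x):
        i = int(np.argmin(np.abs(t - xj)))
        if abs(t[i] - xj) > 0.5:
            raise RuntimeError(
                f"dataset {ds.name!r}: no simulated point within 0.5 d of day {xj} "
                f"(trajectory may have ended early)"
            )
        out[j] = vals[i]
    return out


@register_uni_variate("age_length")
def _predict_age_length(params, ds):
    from .lifecycle import embryo_solution
    from .observables import physical_length
    from .simulate import SimOptions, simulate

    ctx = dict(ds.context)
    f = _ctx_f(params, ctx)
    T_C = float(ctx.get("T_C", params.temp.T_ref - 273.15))
    birth = embryo_solution(params, e_b=min(1.0, max(f, 0.2)), T_C=T_C)
    horizon = float(np.max(ds.x)) - birth.age
    traj = simulate(params, Forcing.constant(T_C, f=f), birth.state,
                    horizon=max(horizon, 1.0), age_offset=birth.age,
                    options=SimOptions(spawning=False))
    t_age = np.asarray(traj.time) + birth.age
    L = np.array([
        physical_length(traj.state_at_index(i).V, params, E_H=traj.state_at_index(i).E_H)
        for i in range(len(t_age))
    ])
    return np.interp(ds.x, t_age, L)


@register_uni_variate("respiration_vs_T")
def _predict_respiration(params, ds):
    from .core import compute_fluxes
    from .environment import CELSIUS_OFFSET, temperature_correction
    from .observables import respiration_proxy
    from .simulate import init_from_weight

    ctx = dict(ds.context)
    f = _ctx_f(params, ctx)
    init = ctx.get("init", {})
    state = init_from_weight(params, float(init.get("wet_weight_g", 1.0)), wet=True,
                             e=float(init.get("e", min(f, 1.0))))
    out = []
    for T_C in ds.x:
        tc = temperature_correction(params.temp, float(T_C) + CELSIUS_OFFSET)
        fx = compute_fluxes(params, state, f=f, T_corr=tc, s=params.s_M_ref)
        out.append(respiration_proxy(fx, ctx.get("coefficients")))
    return np.asarray(out)


@register_uni_variate("fecundity_vs_length")
def _predict_fecundity(params, ds):
    from .observables import reproduction_rate

    ctx = dict(ds.context)
    f = _ctx_f(params, ctx)
    per_year = bool(ctx.get("per_year", True))
    out = []
    for Lw in ds.x:
        L = float(Lw) * params.del_M
        # a known per-egg cost (measured egg energy) may be supplied
        R = reproduction_rate(params, f=f, L=L, T_C=ctx.get("T_C"), E_0=ctx.get("E_0"))
        out.append(R * 365.0 if per_year else R)
    return np.asarray(out)


def predict_dataset(params: DEBParams, dataset: Dataset) -> np.ndarray:
    """Model predictions matched one-to-one to a dataset's observations.

    Zero-variate data dispatch on the trait name, uni-variate datasets
    on their ``kind``; unknown names raise with the registered list.
    """
    if isinstance(dataset, ZeroVariateDatum):
        if dataset.name not in _ZERO_VARIATE:
            # allow "name:qualifier" naming for repeated traits
            base = dataset.name.split(":", 1)[0]
            if base not in _ZERO_VARIATE:
                raise KeyError(
                    f"unknown zero-variate trait {dataset.name!r}; registered: "
                    f"{sorted(_ZERO_VARIATE)}"
                )
            fn = _ZERO_VARIATE[base]
        else:
            fn = _ZERO_VARIATE[dataset.name]
        return np.array([float(fn(params, dataset.context))])
    if dataset.kind not in _UNI_VARIATE:
        raise KeyError(
            f"unknown uni-variate dataset kind {dataset.kind!r}; registered: "
            f"{sorted(_UNI_VARIATE)}"
        )
    return np.asarray(_UNI_VARIATE[dataset.kind](params, dataset))


def predict_all(params: DEBParams, datasets: Sequence[Dataset]) -> dict:
    return {ds.name: predict_dataset(params, ds) for ds in datasets}


# ---------------------------------------------------------------------------
# parameter transforms

_LOGIT_PARAMS = {"kap", "kap_X", "kap_R"}


def _to_theta(params: DEBParams, free: Sequence[str]) -> np.ndarray:
    th = []
    for name in free:
        val = getattr(params, name)
        if name in _LOGIT_PARAMS:
            th.append(math.log(val / (1.0 - val)))
        else:
            th.append(math.log10(val))
    return np.array(th)


def _from_theta(params: DEBParams, free: Sequence[str], theta: np.ndarray) -> DEBParams:
    changes = {}
    for name, t in zip(free, theta):
        if name in _LOGIT_PARAMS:
            changes[name] = 1.0 / (1.0 + math.exp(-t))
        else:
            changes[name] = 10.0 ** t
    return params.replace(**changes)


# ---------------------------------------------------------------------------
# estimation

@dataclass
class EstimationResult:
    """Outcome of one covariation fit."""

    params: DEBParams
    mre: float
    re_per_dataset: dict
    trace: list
    converged: bool
    free: tuple
    start_params: DEBParams
    n_evaluations: int = 0
    seed: Optional[int] = None

    def parameter_table(self):
        import pandas as pd

        rows = []
        for name in self.free:
            a = getattr(self.start_params, name)
            b = getattr(self.params, name)
            rows.append({"parameter": name, "start": a, "estimate": b,
                         "change_pct": 100.0 * (b - a) / a})
        return pd.DataFrame(rows)


def estimate(
    init_params: DEBParams,
    datasets: Sequence[Dataset],
    free: Sequence[str] = (),
    bounds: Optional[Mapping[str, tuple]] = None,
    max_iterations: int = 2000,
    restarts: int = 3,
    seed: Optional[int] = None,
    symmetric: bool = False,
    fatol: float = 1e-6,
) -> EstimationResult:
    """Nelder-Mead covariation fit of ``free`` parameters to ``datasets``.

    Free parameters are optimised in log10 space (logit for fractions)
    which enforces positivity; optional ``bounds`` are {name: (lo, hi)}
    boxes on the natural scale, enforced by an infinite loss outside.
    Convergence: simplex loss spread below ``fatol`` or the iteration
    budget; up to ``restarts`` restarts from the best vertex. The whole
    procedure is deterministic for a given starting point.
    """
    datasets = list(datasets)
    if not datasets:
        raise ValueError("at least one dataset is required")

    def objective_params(p: DEBParams) -> float:
        try:
            preds = predict_all(p, datasets)
        except (ValueError, RuntimeError, KeyError):
            return math.inf
        return loss_mre(datasets, preds, symmetric=symmetric)

    mre0 = None
    try:
        preds0 = predict_all(init_params, datasets)
        mre0 = loss_mre(datasets, preds0, symmetric=symmetric)
    except Exception as exc:  # identify the offending dataset for the user
        for ds in datasets:
            try:
                predict_dataset(init_params, ds)
            except Exception:
                raise RuntimeError(
                    f"loss not computable at the initial parameters; dataset "
                    f"{ds.name!r} failed"
                ) from exc
        raise
    if not math.isfinite(mre0):
        raise RuntimeError("loss is non-finite at the initial parameters")

    if not free:
        re = {ds.name: loss_mre([ds], {ds.name: preds0[ds.name]}, symmetric=symmetric)
              for ds in datasets}
        return EstimationResult(init_params, mre0, re, [mre0], True, (),
                                init_params, n_evaluations=1, seed=seed)

    free = tuple(free)
    n_eval = 0
    trace: list[float] = [mre0]

    def objective(theta: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        p = _from_theta(init_params, free, theta)
        if bounds:
            for name, (lo, hi) in bounds.items():
                val = getattr(p, name)
                if not lo <= val <= hi:
                    return math.inf
        val = objective_params(p)
        if val < trace[-1]:
            trace.append(val)
        return val

    theta = _to_theta(init_params, free)
    best = (objective(theta), theta)
    converged = False
    for _ in range(max(restarts, 1)):
        res = minimize(
            objective, best[1], method="Nelder-Mead",
            options={"maxiter": max_iterations, "fatol": fatol,
                     "xatol": 1e-8, "adaptive": False},
        )
        improved = res.fun < best[0] - 1e-15
        if res.fun < best[0]:
            best = (res.fun, np.asarray(res.x))
        if res.success:
            converged = True
        if not improved:
            break

    final = _from_theta(init_params, free, best[1])
    preds = predict_all(final, datasets)
    mre = loss_mre(datasets, preds, symmetric=symmetric)
    re = {ds.name: loss_mre([ds], {ds.name: preds[ds.name]}, symmetric=symmetric)
          for ds in datasets}
    return EstimationResult(final, mre, re, trace, converged, free, init_params,
                            n_evaluations=n_eval, seed=seed)


def calibrate_KX(
    params: DEBParams,
    datasets: Sequence[Dataset],
    bounds: tuple = (0.01, 100.0),
) -> float:
    """One-dimensional fit of the half-saturation constant K_X.

    All datasets must carry chlorophyll-mode food context (a ``chl``
    value or a chl-mode forcing); K_X is the single free parameter
    linking the concentration to food availability.
    """
    for ds in datasets:
        ctx = ds.context
        forcing = ctx.get("forcing") if isinstance(ctx, Mapping) else None
        has_chl = "chl" in ctx or (forcing is not None and getattr(forcing, "food_mode", "") == "chl")
        if not has_chl:
            raise ValueError(f"dataset {ds.name!r} has no chlorophyll food context")

    def obj(logk: float) -> float:
        p = params.replace(K_X=10.0 ** logk)
        try:
            return loss_mre(datasets, predict_all(p, datasets))
        except (ValueError, RuntimeError):
            return math.inf

    lo, hi = math.log10(bounds[0]), math.log10(bounds[1])
    res = minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-7})
    k = 10.0 ** float(res.x)
    if obj(lo) == obj(hi) == res.fun:
        import logging

        logging.getLogger(__name__).warning(
            "K_X calibration: loss is flat (no food sensitivity); returning boundary"
        )
    return k


# ---------------------------------------------------------------------------
# file/manifest plumbing

def dataset_from_dict(d: Mapping, forcing: Optional[Forcing] = None) -> Dataset:
    """Build a dataset from a plain mapping (manifest entry)."""
    d = dict(d)
    ctx = dict(d.pop("context", {}) or {})
    if forcing is not None and "forcing" not in ctx:
        ctx["forcing"] = forcing
    if "kind" in d:
        return UniVariateDataset(
            name=d["name"], kind=d["kind"],
            x=np.asarray(d["x"], dtype=float), y=np.asarray(d["y"], dtype=float),
            weights=None if d.get("weights") is None else np.asarray(d["weights"], float),
            context=ctx, response=d.get("response", "dw_g"), ref=d.get("ref", ""),
        )
    return ZeroVariateDatum(
        name=d["name"], value=float(d["value"]), unit=d.get("unit", ""),
        weight=float(d.get("weight", 1.0)), context=ctx, ref=d.get("ref", ""),
    )
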