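"""Life-stage thresholds and discrete events.

Covers the embryo initial-reserve problem (how much reserve an egg must
carry so the hatchling reaches the birth maturity E_Hb at a prescribed
reserve density), event detection along simulated trajectories,
brooding (larviparous incubation reduces maternal food intake by a
factor 0.8 until the brood reaches the release maturity E_Hr), spawning
(a fraction kap_R of the reproduction buffer is emptied) and the
Weibull-Gompertz ageing lifespan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .core import OrganismState
from .environment import CELSIUS_OFFSET, temperature_correction
from .params import DEBParams

__all__ = [
    "EmbryoSolution",
    "initial_reserve",
    "embryo_solution",
    "lifecycle_acceleration",
    "LifeEvent",
    "LifeEvents",
    "detect_events",
    "BroodState",
    "brooding_multiplier",
    "SpawnRecord",
    "apply_spawning",
    "lifespan",
]

#: structural volume assigned to a freshly fertilised egg (cm^3); small
#: enough that results are insensitive to it, large enough for the ODE.
V_EGG = 1e-12

#: scaled reserve density below which the individual dies of starvation
E_DEATH = 1e-4


@dataclass(frozen=True)
class EmbryoSolution:
    """Outcome of one embryo integration (fertilisation -> maturity target)."""

    E_0: float            # initial reserve (J)
    age: float            # age at which the maturity target was reached (d)
    state: OrganismState  # state at that moment
    reached: bool         # False when reserve ran out first

    def scaled_reserve_density(self, params: DEBParams) -> float:
        return self.state.scaled_reserve_density(params)


def _integrate_embryo(
    params: DEBParams, E_0: float, tc: float, target: float, t_max: float = 1000.0
) -> EmbryoSolution:
    """Integrate the non-feeding embryo from (E_0, ~0, 0) until E_H = target."""
    v0 = params.v_base * tc
    pM = params.p_M * tc
    kJ = params.k_J * tc
    kap, E_G = params.kap, params.E_G

    def rhs(t, y):
        E, V, E_H = y
        V = max(V, V_EGG)
        L = V ** (1.0 / 3.0)
        p_S = pM * V
        p_C = E * (E_G * v0 / L + p_S / V) / (kap * E / V + E_G)
        return [-p_C, (kap * p_C - p_S) / E_G, (1.0 - kap) * p_C - kJ * E_H]

    def hit(t, y):
        return y[2] - target

    hit.terminal = True
    hit.direction = 1.0

    def spent(t, y):
        return y[0] - E_DEATH * max(y[1], V_EGG) * params.E_m

    spent.terminal = True
    spent.direction = -1.0

    sol = solve_ivp(
        rhs, (0.0, t_max), [E_0, V_EGG, 0.0], method="LSODA",
        events=[hit, spent], rtol=1e-9, atol=[1e-16, 1e-22, 1e-16],
    )
    if sol.t_events[0].size:
        t_b = float(sol.t_events[0][0])
        E, V, E_H = sol.y_events[0][0]
        return EmbryoSolution(E_0, t_b, OrganismState(E=max(E, 0.0), V=V, E_H=E_H), True)
    E, V, E_H = sol.y[:, -1]
    return EmbryoSolution(E_0, float(sol.t[-1]),
                          OrganismState(E=max(E, 0.0), V=max(V, V_EGG), E_H=max(E_H, 0.0)),
                          False)


@lru_cache(maxsize=256)
def _initial_reserve_cached(params: DEBParams, e_b: float, T_K: float, target: float) -> float:
    tc = temperature_correction(params.temp, T_K)
    lo = target / (1.0 - params.kap)  # cannot even pay the maturation bill
    hi = lo
    for _ in range(60):
        hi *= 2.0
        s = _integrate_embryo(params, hi, tc, target)
        if s.reached and s.scaled_reserve_density(params) >= e_b:
            break
    else:
        raise RuntimeError(
            f"initial_reserve: no bracket found for e_b={e_b} "
            f"(last E_0={hi:g}, reached={s.reached})"
        )
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        s = _integrate_embryo(params, mid, tc, target)
        if s.reached and s.scaled_reserve_density(params) >= e_b:
            hi = mid
        else:
            lo = mid
        if (hi - lo) / hi < 1e-11:
            break
    return hi


def initial_reserve(
    params: DEBParams,
    e_b: float = 1.0,
    T_C: Optional[float] = None,
    target: Optional[float] = None,
) -> float:
    """Initial reserve E_0 (J) such that the embryo is born with reserve
    density ``e_b``.

    Solved by bisection on E_0 with the embryo initial-value problem as
    inner solver; the returned egg, integrated forward without feeding,
    reaches ``E_H = E_Hb`` with scaled reserve density ``e_b``.

    Parameters
    ----------
    e_b : float
        Scaled reserve density at birth, in (0, 1].
    T_C : float, optional
        Incubation temperature (deg C); defaults to the reference
        temperature.
    target : float, optional
        Maturity level ending the integration (defaults to E_Hb).
    """
    if not 0.0 < e_b <= 1.0:
        raise ValueError("e_b must lie in (0, 1]")
    if target is None:
        if params.E_Hb is None:
            raise ValueError("parameter set has no E_Hb; supply an explicit target")
        target = params.E_Hb
    T_K = params.temp.T_ref if T_C is None else T_C + CELSIUS_OFFSET
    return _initial_reserve_cached(params, float(e_b), float(T_K), float(target))


def embryo_solution(
    params: DEBParams,
    E_0: Optional[float] = None,
    e_b: float = 1.0,
    T_C: Optional[float] = None,
    target: Optional[float] = None,
) -> EmbryoSolution:
    """Embryo trajectory endpoint for a given (or solved) initial reserve."""
    if target is None:
        if params.E_Hb is None:
            raise ValueError("parameter set has no E_Hb; supply an explicit target")
        target = params.E_Hb
    if E_0 is None:
        E_0 = initial_reserve(params, e_b=e_b, T_C=T_C, target=target)
    T_K = params.temp.T_ref if T_C is None else T_C + CELSIUS_OFFSET
    tc = temperature_correction(params.temp, T_K)
    return _integrate_embryo(params, E_0, tc, target)


@lru_cache(maxsize=64)
def _lifecycle_acceleration_cached(params: DEBParams, f: float, T_K: float) -> float:
    from .simulate import SimOptions, simulate
    from .environment import Forcing

    birth = embryo_solution(params, e_b=1.0, T_C=T_K - CELSIUS_OFFSET)
    forcing = Forcing.constant(T_K - CELSIUS_OFFSET, f=f)
    traj = simulate(
        params, forcing, birth.state, horizon=2000.0,
        options=SimOptions(spawning=False, stop_at="metamorphosis"),
    )
    ev = {e.name: e for e in traj.events}
    if "settlement" not in ev or "metamorphosis" not in ev:
        raise RuntimeError("lifecycle did not reach metamorphosis; acceleration undefined")
    return ev["metamorphosis"].state.structural_length() / ev["settlement"].state.structural_length()


def lifecycle_acceleration(params: DEBParams, f: float = 1.0, T_C: Optional[float] = None) -> float:
    """Emergent acceleration factor s_M = L(E_Hj) / L(E_Hs).

    Computed from the full lifecycle solution (embryo plus fed larva) at
    constant food ``f`` and temperature ``T_C``.
    """
    if not params.has_larval_stages:
        return params.s_M_ref
    T_K = params.temp.T_ref if T_C is None else T_C + CELSIUS_OFFSET
    return _lifecycle_acceleration_cached(params, float(f), float(T_K))


# ---------------------------------------------------------------------------
# events

@dataclass(frozen=True)
class LifeEvent:
    name: str
    age: float               # d
    state: OrganismState
    length: float            # physical length (cm)
    dry_weight: float        # g


@dataclass(frozen=True)
class LifeEvents:
    """Ordered life-history events detected on a trajectory."""

    events: tuple

    _ORDER = ("birth", "release", "settlement", "metamorphosis", "puberty")

    def __iter__(self):
        return iter(self.events)

    def get(self, name: str) -> Optional[LifeEvent]:
        for e in self.events:
            if e.name == name:
                return e
        return None

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {"event": e.name, "age_d": e.age, "length_cm": e.length,
                 "dryweight_g": e.dry_weight}
                for e in self.events
            ]
        )


def detect_events(trajectory, params: DEBParams) -> LifeEvents:
    """Life events of a simulated trajectory.

    Event times come from the integrator's threshold localisation stored
    on the trajectory; lengths use the pre-metamorphosis shape
    coefficient del_Mb up to E_Hj and del_M beyond. Thresholds never
    reached are simply absent.
    """
    from .observables import dry_weight, physical_length

    events = []
    for ev in trajectory.events:
        if ev.name not in LifeEvents._ORDER:
            continue
        events.append(
            LifeEvent(
                name=ev.name,
                age=ev.time + trajectory.age_offset,
                state=ev.state,
                length=physical_length(ev.state.V, params, E_H=ev.state.E_H),
                dry_weight=dry_weight(ev.state, params),
            )
        )
    events.sort(key=lambda e: LifeEvents._ORDER.index(e.name))
    return LifeEvents(tuple(events))


# ---------------------------------------------------------------------------
# brooding and spawning

@dataclass
class BroodState:
    """Larviparous incubation state of a (flat oyster) female."""

    active: bool = False
    start: Optional[float] = None      # d
    end: Optional[float] = None        # d (set once the release age is known)
    factor: float = 0.8                # feeding multiplier while active

    def __post_init__(self) -> None:
        if not 0.0 < self.factor <= 1.0:
            raise ValueError("brooding feeding multiplier must lie in (0, 1]")


def brooding_multiplier(brood: Optional[BroodState], t: Optional[float] = None) -> float:
    """Feeding multiplier: ``brood.factor`` while incubating, 1 otherwise."""
    if brood is None or not brood.active:
        return 1.0
    if t is not None and brood.end is not None and t >= brood.end:
        return 1.0
    return brood.factor


@dataclass(frozen=True)
class SpawnRecord:
    time: float            # d
    energy: float          # J released from the buffer
    eggs: float            # released energy / egg cost
    E_0: float             # per-egg cost used (J)


def apply_spawning(
    state: OrganismState,
    params: DEBParams,
    t: float = 0.0,
    E_0: Optional[float] = None,
) -> tuple[OrganismState, SpawnRecord]:
    """Empty a fraction kap_R of the reproduction buffer into gametes.

    The per-egg cost defaults to the initial reserve solved at the
    spawner's current reserve density. For brooding species (those with
    a release threshold E_Hr) spawning as female starts incubation.
    """
    if params.E_Hp is None or state.E_H < params.E_Hp:
        raise ValueError("spawning before puberty is not possible")
    if state.E_R < 0:
        raise ValueError("reproduction buffer must be non-negative")
    released = params.kap_R * state.E_R
    if released == 0.0:
        return state, SpawnRecord(time=t, energy=0.0, eggs=0.0, E_0=math.nan)
    if E_0 is None:
        e_b = min(max(state.scaled_reserve_density(params), 0.1), 1.0)
        E_0 = initial_reserve(params, e_b=e_b)
    new = state.replace(
        E_R=state.E_R - released,
        brooding=params.E_Hr is not None,
        brood_start=t if params.E_Hr is not None else None,
    )
    return new, SpawnRecord(time=t, energy=released, eggs=released / E_0, E_0=E_0)


def brood_duration(params: DEBParams, T_C: Optional[float] = None, e_b: float = 1.0) -> float:
    """Days for a brooded embryo to develop from fertilisation to E_Hr.

    The egg carries the initial reserve solved for birth density ``e_b``
    and is integrated on to the release maturity at the ambient
    temperature.
    """
    if params.E_Hr is None:
        raise ValueError("parameter set has no release threshold E_Hr")
    E_0 = initial_reserve(params, e_b=e_b, T_C=T_C)
    sol = embryo_solution(params, E_0=E_0, T_C=T_C, target=params.E_Hr)
    if not sol.reached:
        raise RuntimeError("brooded embryo exhausted reserve before E_Hr")
    return sol.age


# ---------------------------------------------------------------------------
# ageing

def lifespan(
    params: DEBParams,
    f: float = 1.0,
    T_C: Optional[float] = None,
    horizon: float = 60_000.0,
) -> float:
    """Expected age at death (d) under constant food and temperature.

    Integrates the Weibull-Gompertz ageing pair (q, h) along the growth
    trajectory from birth and returns the mean lifespan
    ``integral of S(t) dt`` with survival ``S = exp(-integral h)``.
    """
    if params.h_a is None:
        raise ValueError("parameter set has no ageing block (h_a)")
    if not 0.0 < f <= 1.0:
        raise ValueError("f must lie in (0, 1]")
    from .environment import Forcing
    from .simulate import SimOptions, simulate

    T_C_eff = params.temp.T_ref - CELSIUS_OFFSET if T_C is None else T_C
    birth = embryo_solution(params, e_b=min(1.0, max(f, 0.2)), T_C=T_C_eff)
    forcing = Forcing.constant(T_C_eff, f=f)
    traj = simulate(
        params, forcing, birth.state, horizon=horizon,
        t_eval=np.linspace(0.0, horizon, 2001),
        options=SimOptions(spawning=False),
    )
    S = np.exp(-np.asarray(traj.cum_h))
    t = np.asarray(traj.time)
    mean = float(np.trapezoid(S, t))
    if S[-1] > 1e-3:
        # hazard never built up within the horizon (e.g. h_a -> 0)
        return math.inf
    return mean
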