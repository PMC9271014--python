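"""Time integration of the full asj model under environmental forcing.

The integrator is adaptive (LSODA via :func:`scipy.integrate.solve_ivp`)
with event localisation at maturity thresholds, starvation death and
reproduction-buffer exhaustion. Spawning is evaluated on a daily clock
once the individual is mature: when the buffer density exceeds a
configurable fraction of the reserve capacity and the water is warmer
than the spawning temperature, a fraction kap_R of the buffer is
released; brooding species then incubate until the brood reaches the
release maturity, feeding at a reduced rate meanwhile.

Alongside the state the integrator accumulates assimilated energy and
the maintenance integrals, so that the full energy budget
dE + dE_R + dE_H + E_G dV + (p_S + p_J) dt = p_A dt can be verified on
any stored window, and the cumulative hazard for survival bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .core import OrganismState, acceleration_factor, state_derivatives
from .environment import CELSIUS_OFFSET, Forcing, temperature_correction
from .lifecycle import E_DEATH, SpawnRecord, brood_duration, initial_reserve
from .params import DEBParams, TempParams

__all__ = ["SimOptions", "TrajectoryEvent", "Trajectory", "simulate", "init_from_weight",
           "run_scenario", "ScenarioResult"]

_THRESHOLDS = (
    ("E_Hb", "birth"),
    ("E_Hr", "release"),
    ("E_Hs", "settlement"),
    ("E_Hj", "metamorphosis"),
    ("E_Hp", "puberty"),
)


@dataclass(frozen=True)
class SimOptions:
    """Integrator and event-handling options."""

    rtol: float = 1e-8
    atol: float = 1e-10
    spawning: bool = True
    spawn_temp_C: float = 15.0     # water must be warmer than this to spawn
    spawn_buffer_frac: float = 0.5  # trigger when E_R/V exceeds this * [E_m]
    brood_factor: float = 0.8      # feeding multiplier while brooding
    brood_mode: str = "embryo"     # "embryo" (develop to E_Hr) or "fixed"
    brood_days: float = 10.0       # duration in "fixed" mode
    s_M: Optional[float] = None    # frozen acceleration for post-metamorphic starts
    L_s: Optional[float] = None    # settlement length when starting mid-acceleration
    stop_at: Optional[str] = None  # terminate at this named event
    feeding_temp: Optional[TempParams] = None  # decoupled thermal response


@dataclass(frozen=True)
class TrajectoryEvent:
    name: str
    time: float
    state: OrganismState


class Trajectory:
    """Stored simulation output on a time grid plus localized events."""

    _STATE_COLS = ("E", "V", "E_H", "E_R", "q", "h")

    def __init__(self, params: DEBParams, forcing: Forcing, options: SimOptions,
                 age_offset: float = 0.0):
        self.params = params
        self.forcing = forcing
        self.options = options
        self.age_offset = age_offset
        self.time: list[float] = []
        self._rows: list[np.ndarray] = []
        self.events: list[TrajectoryEvent] = []
        self.spawns: list[SpawnRecord] = []
        self.died = False
        self.death_time: Optional[float] = None

    # rows are the full augmented state [E,V,E_H,E_R,q,h,cumA,cumS,cumJ,cumH]
    def _append(self, t: float, y: np.ndarray) -> None:
        if self.time and t <= self.time[-1] + 1e-12:
            return
        self.time.append(float(t))
        self._rows.append(np.array(y, dtype=float))

    @property
    def states(self) -> list[OrganismState]:
        return [self.state_at_index(i) for i in range(len(self.time))]

    def state_at_index(self, i: int) -> OrganismState:
        E, V, E_H, E_R = self._rows[i][:4]
        q, h = self._rows[i][4:6]
        return OrganismState(E=max(E, 0.0), V=max(V, 0.0), E_H=max(E_H, 0.0),
                             E_R=max(E_R, 0.0), q=q, h=h)

    @property
    def final_state(self) -> OrganismState:
        return self.state_at_index(len(self.time) - 1)

    def column(self, name: str) -> np.ndarray:
        idx = {"E": 0, "V": 1, "E_H": 2, "E_R": 3, "q": 4, "h": 5,
               "cum_pA": 6, "cum_pSJ": 7, "cum_pJ": 8, "cum_h": 9}[name]
        return np.array([r[idx] for r in self._rows])

    @property
    def cum_h(self) -> np.ndarray:
        return self.column("cum_h")

    def energy_balance(self) -> dict:
        """Full-budget bookkeeping over the stored window (J).

        ``residual`` is assimilated input minus (state changes + spawned
        energy + maintenance integrals); ``relative`` scales it by the
        total assimilated input (or total turnover for a starving run).
        """
        first, last = self._rows[0], self._rows[-1]
        dE = last[0] - first[0]
        dV = last[1] - first[1]
        dEH = last[2] - first[2]
        dER = last[3] - first[3]
        spawned = sum(s.energy for s in self.spawns)
        assim = last[6] - first[6]
        maint = last[7] - first[7]
        residual = assim - (dE + dER + dEH + self.params.E_G * dV + maint + spawned)
        scale = max(assim, abs(dE) + abs(dER) + dEH + maint + abs(dV) * self.params.E_G, 1e-30)
        return {"assimilated": assim, "residual": residual,
                "relative": residual / scale, "spawned": spawned}

    def to_dataframe(self):
        """Observable table: day, states, length, weights, reserve density."""
        import pandas as pd

        from .observables import dry_weight, physical_length, wet_weight

        rows = []
        for t, i in zip(self.time, range(len(self.time))):
            st = self.state_at_index(i)
            dw = dry_weight(st, self.params)
            rows.append(
                {
                    "day": t,
                    "E_J": st.E, "V_cm3": st.V, "E_H_J": st.E_H, "E_R_J": st.E_R,
                    "length_cm": physical_length(st.V, self.params, E_H=st.E_H),
                    "dw_g": dw,
                    "ww_g": dw / self.params.aux.dw_ww_ratio,
                    "e": st.scaled_reserve_density(self.params),
                }
            )
        return pd.DataFrame(rows)

    def plot(self, ax=None):
        """Dry-weight partition (structure / reserve / buffer) through time."""
        import matplotlib.pyplot as plt

        from .observables import weight_components

        if ax is None:
            _, ax = plt.subplots()
        t = np.asarray(self.time)
        comps = [weight_components(self.state_at_index(i), self.params)
                 for i in range(len(t))]
        struct = np.array([c["structure"] for c in comps])
        res = np.array([c["reserve"] for c in comps])
        buf = np.array([c["buffer"] for c in comps])
        ax.stackplot(t, struct, res, buf,
                     labels=["structure", "reserve", "buffer"],
                     colors=["black", "grey", "lightgrey"])
        ax.set_xlabel("time (d)")
        ax.set_ylabel("dry weight (g)")
        ax.legend(loc="upper left")
        return ax


def _frozen_acceleration(params: DEBParams, init: OrganismState, options: SimOptions) -> float:
    if options.s_M is not None:
        return options.s_M
    return params.s_M_ref


def simulate(
    params: DEBParams,
    forcing: Forcing,
    init: OrganismState,
    horizon: float,
    t0: float = 0.0,
    t_eval: Optional[Sequence[float]] = None,
    options: Optional[SimOptions] = None,
    age_offset: float = 0.0,
) -> Trajectory:
    """Integrate the model from ``init`` over ``[t0, t0 + horizon]``.

    ``t_eval`` sets the storage grid (default: daily); event and spawn
    times are always stored in addition. Chlorophyll-mode forcing is
    converted to a functional response with the species K_X.
    """
    options = options or SimOptions()
    if params.E_Hp is None and options.spawning:
        options = replace(options, spawning=False)
    if forcing.food_mode == "chl" and params.K_X is None:
        raise ValueError("chlorophyll forcing requires params.K_X")
    if (
        params.E_Hs is not None
        and params.E_Hj is not None
        and params.E_Hs <= init.E_H < params.E_Hj
        and options.L_s is None
    ):
        raise ValueError(
            "initial state lies inside the acceleration window; supply SimOptions.L_s"
        )

    t_end = t0 + horizon
    if t_eval is None:
        grid = np.arange(t0, t_end + 1e-9, 1.0)
    else:
        grid = np.asarray(t_eval, dtype=float)
    grid = grid[(grid >= t0) & (grid <= t_end + 1e-9)]

    traj = Trajectory(params, forcing, options, age_offset=age_offset)

    # mutable acceleration context
    ctx = {
        "L_s": options.L_s,
        "s_M": _frozen_acceleration(params, init, options),
    }
    if params.E_Hj is not None and init.E_H < params.E_Hj:
        ctx["s_M"] = None  # will be set when metamorphosis is crossed

    brood = {
        "active": init.brooding,
        "end": None,
        "factor": options.brood_factor,
    }
    if init.brooding and init.brood_start is not None:
        dur = (
            brood_duration(params, T_C=forcing.temperature_K(t0) - CELSIUS_OFFSET)
            if options.brood_mode == "embryo"
            else options.brood_days
        )
        brood["end"] = init.brood_start + dur

    feeding_temp = options.feeding_temp

    def current_s(E_H: float, V: float) -> float:
        # tolerant variant of core.acceleration_factor: solver trial steps may
        # overshoot a threshold slightly before the event is localized
        if params.E_Hs is None or params.E_Hj is None:
            return ctx["s_M"] if ctx["s_M"] is not None else params.s_M_ref
        if E_H < params.E_Hs:
            return 1.0
        if E_H < params.E_Hj or ctx["s_M"] is None:
            if ctx["L_s"] is None:
                return 1.0  # settlement crossing still being localized
            return max(1.0, V ** (1.0 / 3.0) / ctx["L_s"])
        return ctx["s_M"]

    def rhs(t, y):
        E, V, E_H, E_R = y[0], max(y[1], 1e-30), max(y[2], 0.0), max(y[3], 0.0)
        state = OrganismState(E=max(E, 0.0), V=V, E_H=E_H, E_R=E_R, q=y[4], h=y[5])
        T_K, f = forcing.at(t, K_X=params.K_X)
        if brood["active"] and (brood["end"] is None or t < brood["end"]):
            f = f * brood["factor"]
        tc = temperature_correction(params.temp, T_K)
        tc_feed = (
            temperature_correction(feeding_temp, T_K) if feeding_temp is not None else None
        )
        d = state_derivatives(
            params, state, f=f, T_corr=tc,
            s=current_s(E_H, V), feeding_T_corr=tc_feed,
        )
        fx = d.fluxes
        return [d.dE, d.dV, d.dE_H, d.dE_R, d.dq, d.dh,
                fx.p_A, fx.p_S + fx.p_J, fx.p_J, state.h]

    y = np.array([init.E, init.V, init.E_H, init.E_R, init.q, init.h,
                  0.0, 0.0, 0.0, 0.0])
    t = t0
    traj._append(t, y)

    # component-wise absolute tolerances: structure and maturity live on much
    # smaller scales than reserve during the larval phase; ageing states are tiny
    a = options.atol
    atol_vec = np.array([a, a * 1e-6, a * 1e-2, a, 1e-22, 1e-16, a * 100, a * 100, a * 100, 1e-12])

    def make_threshold_event(value: float):
        def ev(tt, yy):
            return yy[2] - value
        ev.terminal = True
        ev.direction = 1.0
        return ev

    def death_event(tt, yy):
        return yy[0] - E_DEATH * params.E_m * max(yy[1], 1e-30)

    death_event.terminal = True
    death_event.direction = -1.0

    def buffer_event(tt, yy):
        return yy[3]

    buffer_event.terminal = True
    buffer_event.direction = -1.0

    stop = False
    while t < t_end - 1e-9 and not stop:
        # next maturity threshold above the current level
        next_thr = None
        for attr, name in _THRESHOLDS:
            val = getattr(params, attr)
            if val is not None and y[2] < val * (1.0 - 1e-12):
                next_thr = (name, val)
                break

        # chunk end: daily spawning clock (adults only), brood end
        seg_end = t_end
        adult = params.E_Hp is not None and y[2] >= params.E_Hp * (1.0 - 1e-12)
        if options.spawning and adult:
            seg_end = min(seg_end, math.floor(t + 1e-9) + 1.0)
        if brood["active"] and brood["end"] is not None and brood["end"] > t:
            seg_end = min(seg_end, brood["end"])

        events = [death_event]
        if next_thr is not None:
            events.insert(0, make_threshold_event(next_thr[1]))
        if y[3] > 0:
            events.append(buffer_event)

        seg_eval = np.append(grid[(grid > t + 1e-12) & (grid < seg_end - 1e-12)], seg_end)
        sol = solve_ivp(
            rhs, (t, seg_end), y, method="LSODA", t_eval=seg_eval,
            events=events, rtol=options.rtol, atol=atol_vec,
        )
        if not sol.success:
            raise RuntimeError(
                f"integration failed at t={sol.t[-1] if sol.t.size else t}: {sol.message}"
            )
        sol_y = np.asarray(sol.y)
        if sol_y.size:
            for tt, yy in zip(sol.t, sol_y.T):
                traj._append(tt, yy)

        fired = [i for i, te in enumerate(sol.t_events) if te.size]
        if fired:
            i = fired[0]
            t = float(sol.t_events[i][0])
            y = np.array(sol.y_events[i][0], dtype=float)
            traj._append(t, y)
            ev_fn = events[i]
            if next_thr is not None and i == 0:
                name = next_thr[0]
                st = traj.final_state
                traj.events.append(TrajectoryEvent(name, t, st))
                if name == "settlement":
                    ctx["L_s"] = st.structural_length()
                elif name == "metamorphosis":
                    if ctx["L_s"] is not None:
                        ctx["s_M"] = st.structural_length() / ctx["L_s"]
                    else:
                        ctx["s_M"] = _frozen_acceleration(params, st, options)
                if options.stop_at == name:
                    stop = True
                y[2] = getattr(params, {n: a for a, n in _THRESHOLDS}[name]) * (1.0 + 1e-12)
            elif ev_fn is death_event:
                traj.died = True
                traj.death_time = t
                traj.events.append(TrajectoryEvent("death", t, traj.final_state))
                stop = True
            else:  # buffer exhausted during starvation payment
                y[3] = 0.0
            continue

        t = seg_end
        y = np.array(sol_y[:, -1], dtype=float)

        if brood["active"] and brood["end"] is not None and seg_end >= brood["end"] - 1e-9:
            brood["active"] = False
            traj.events.append(TrajectoryEvent("brood_release", seg_end, traj.final_state))

        # daily spawning check
        adult = params.E_Hp is not None and y[2] >= params.E_Hp * (1.0 - 1e-12)
        if options.spawning and adult and not brood["active"] and t < t_end - 1e-9:
            T_K = forcing.temperature_K(t)
            if (
                T_K - CELSIUS_OFFSET > options.spawn_temp_C
                and y[3] / max(y[1], 1e-30) > options.spawn_buffer_frac * params.E_m
            ):
                st = traj.final_state
                e_b = round(min(max(st.scaled_reserve_density(params), 0.1), 1.0), 2)
                E_0 = initial_reserve(params, e_b=e_b) if params.E_Hb is not None else None
                released = params.kap_R * y[3]
                y[3] -= released
                rec = SpawnRecord(time=t, energy=released,
                                  eggs=released / E_0 if E_0 else math.nan,
                                  E_0=E_0 if E_0 else math.nan)
                traj.spawns.append(rec)
                traj.events.append(TrajectoryEvent("spawning", t, traj.final_state))
                if params.E_Hr is not None:
                    brood["active"] = True
                    dur = (
                        brood_duration(params, T_C=T_K - CELSIUS_OFFSET)
                        if options.brood_mode == "embryo"
                        else options.brood_days
                    )
                    brood["end"] = t + dur
                traj._append(t + 1e-9, y)

    return traj


def init_from_weight(
    params: DEBParams,
    weight: float,
    wet: bool = True,
    e: float = 0.8,
    E_R: float = 0.0,
    E_H: Optional[float] = None,
) -> OrganismState:
    """Reconstruct a state from a field weight measurement.

    Follows the validation convention: fit animals (e = 0.8), empty
    reproduction buffer, fully mature. Structure is solved from
    W_d = d_V V + (w_E/mu_E)(e [E_m] V + E_R); the round trip through
    :func:`oysterdeb.observables.dry_weight` is exact.
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    if not 0.0 <= e <= 1.0:
        raise ValueError("e must lie in [0, 1]")
    if E_H is None:
        E_H = params.E_Hp if params.E_Hp is not None else 0.0
    c = params.aux
    dry = weight * c.dw_ww_ratio if wet else weight
    dry_struct_reserve = dry - c.w_E * E_R / c.mu_E
    denom = c.d_V + c.w_E * e * params.E_m / c.mu_E
    V = dry_struct_reserve / denom
    if V <= 0:
        raise ValueError(
            f"weight {weight} g is below the minimum feasible for E_R={E_R} J"
        )
    return OrganismState(E=e * params.E_m * V, V=V, E_H=E_H, E_R=E_R)


@dataclass
class ScenarioResult:
    trajectory: Trajectory
    observables: "object"          # pandas DataFrame
    errors: Optional[dict] = None  # per-dataset relative errors + MRE


def run_scenario(config: dict) -> ScenarioResult:
    """Run a named scenario: species + forcing + init rule + horizon.

    Config keys: ``species`` (packaged name) or ``params`` (path),
    ``forcing`` (path or dict with Forcing arrays), ``init`` (dict with
    ``wet_weight_g`` or ``dry_weight_g``, optional ``e``), ``days``,
    optional ``options`` (SimOptions fields), optional ``observations``
    (list of dataset dicts understood by the estimation module) and
    ``out_dir``.
    """
    from . import io as _io

    if "species" in config:
        params = _io.load_species(config["species"])
    elif "params" in config:
        params = _io.read_params(config["params"])
    else:
        raise ValueError("scenario config needs 'species' or 'params'")

    fc = config["forcing"]
    if isinstance(fc, Forcing):
        forcing = fc
    elif isinstance(fc, dict):
        forcing = Forcing(**fc)
    else:
        forcing = _io.read_forcing(fc)

    init_cfg = dict(config.get("init", {}))
    if "wet_weight_g" in init_cfg:
        init = init_from_weight(params, init_cfg["wet_weight_g"], wet=True,
                                e=init_cfg.get("e", 0.8), E_R=init_cfg.get("E_R", 0.0))
    elif "dry_weight_g" in init_cfg:
        init = init_from_weight(params, init_cfg["dry_weight_g"], wet=False,
                                e=init_cfg.get("e", 0.8), E_R=init_cfg.get("E_R", 0.0))
    else:
        raise ValueError("scenario init needs wet_weight_g or dry_weight_g")

    options = SimOptions(**config.get("options", {}))
    traj = simulate(params, forcing, init, horizon=float(config["days"]), options=options)
    table = traj.to_dataframe()

    errors = None
    if config.get("observations"):
        from .estimation import dataset_from_dict, loss_mre, predict_dataset

        datasets = [dataset_from_dict(d, forcing=forcing) for d in config["observations"]]
        per = {}
        for ds in datasets:
            pred = predict_dataset(params, ds)
            per[ds.name] = loss_mre([ds], {ds.name: pred})
        all_pred = {ds.name: predict_dataset(params, ds) for ds in datasets}
        errors = {"per_dataset": per, "MRE": loss_mre(datasets, all_pred)}

    if config.get("out_dir"):
        from pathlib import Path

        out = Path(config["out_dir"])
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "observables.csv", index=False)
        from .lifecycle import detect_events

        detect_events(traj, params).to_dataframe().to_csv(out / "events.csv", index=False)
        _io.write_run_manifest(out, config)

    return ScenarioResult(trajectory=traj, observables=table, errors=errors)
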