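"""Energy fluxes and state derivatives of the asj DEB model.

State variables: reserve energy E (J), structural volume V (cm^3),
maturity E_H (J) and the reproduction buffer E_R (J), plus the Weibull-
Gompertz ageing pair (q, h). A fixed fraction kappa of the mobilised
power p_C goes to the soma (somatic maintenance first, growth with the
remainder); the rest covers maturity maintenance and maturation (before
puberty) or the reproduction buffer (after).

Metabolic acceleration: between settlement (E_H = E_Hs) and the end of
metamorphosis (E_H = E_Hj) the surface-specific assimilation {p_Am} and
the energy conductance v are multiplied by s = L / L_s, where L_s is the
structural length at settlement on the running trajectory; the factor is
1 before settlement and frozen at s_M = L_j / L_s afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from .params import DEBParams

__all__ = [
    "OrganismState",
    "Fluxes",
    "StateDerivatives",
    "acceleration_factor",
    "compute_fluxes",
    "state_derivatives",
    "compound_parameters",
]


@dataclass(frozen=True)
class OrganismState:
    """Instantaneous state of one individual."""

    E: float                 # reserve energy (J)
    V: float                 # structural volume (cm^3)
    E_H: float               # maturity (J)
    E_R: float = 0.0         # reproduction buffer (J)
    q: float = 0.0           # ageing acceleration (1/d^2)
    h: float = 0.0           # hazard rate (1/d)
    brooding: bool = False   # larvae incubating in the mantle cavity
    brood_start: Optional[float] = None  # time brooding began (d)

    def __post_init__(self) -> None:
        if self.E < 0 or self.V < 0 or self.E_R < 0 or self.E_H < 0:
            raise ValueError(
                f"state components must be non-negative: E={self.E}, V={self.V}, "
                f"E_H={self.E_H}, E_R={self.E_R}"
            )

    def scaled_reserve_density(self, params: DEBParams) -> float:
        """e = [E]/[E_m]; equals f at reserve equilibrium under constant food."""
        if self.V == 0:
            return 0.0
        return self.E / (self.V * params.E_m)

    def structural_length(self) -> float:
        """L = V^(1/3) (cm)."""
        return self.V ** (1.0 / 3.0)

    def replace(self, **changes) -> "OrganismState":
        return replace(self, **changes)


@dataclass(frozen=True)
class Fluxes:
    """Instantaneous energy fluxes (J/d); all follow the kappa-rule exactly."""

    p_X: float   # ingestion
    p_A: float   # assimilation
    p_C: float   # mobilisation
    p_S: float   # somatic maintenance
    p_J: float   # maturity maintenance
    p_G: float   # growth (negative under starvation before the rule applies)
    p_R: float   # maturation / reproduction allocation

    @property
    def starving(self) -> bool:
        """True when mobilised somatic power cannot cover maintenance."""
        return self.p_G < 0.0


@dataclass(frozen=True)
class StateDerivatives:
    """Time derivatives of the organism state plus the fluxes behind them."""

    dE: float
    dV: float
    dE_H: float
    dE_R: float
    dq: float
    dh: float
    fluxes: Fluxes
    starving: bool = False


def acceleration_factor(
    params: DEBParams,
    E_H: float,
    V: float,
    L_s: Optional[float] = None,
    s_M: Optional[float] = None,
) -> float:
    """Metabolic acceleration s at maturity ``E_H`` and volume ``V``.

    ``L_s`` is the structural length at settlement of the running
    trajectory (required inside the acceleration window); ``s_M``
    overrides the frozen post-metamorphic factor (defaults to the
    species' reference value).
    """
    s_M_eff = params.s_M_ref if s_M is None else s_M
    if params.E_Hs is None or params.E_Hj is None:
        return s_M_eff
    if E_H < params.E_Hs:
        return 1.0
    if E_H >= params.E_Hj:
        return s_M_eff
    if L_s is None:
        raise ValueError(
            "structural length at settlement (L_s) is required to evaluate the "
            "acceleration factor between E_Hs and E_Hj"
        )
    return max(1.0, V ** (1.0 / 3.0) / L_s)


def compute_fluxes(
    params: DEBParams,
    state: OrganismState,
    f: float,
    T_corr: float,
    s: Optional[float] = None,
    L_s: Optional[float] = None,
    feeding_T_corr: Optional[float] = None,
) -> Fluxes:
    """Evaluate all energy fluxes at one state.

    Parameters
    ----------
    f : float
        Scaled functional response in [0, 1]; any brooding reduction must
        already be applied by the caller.
    T_corr : float
        Arrhenius correction factor (> 0) applied to every rate.
    s : float, optional
        Acceleration factor; inferred from maturity when omitted.
    feeding_T_corr : float, optional
        Separate correction for the feeding fluxes (decoupled thermal
        response); defaults to ``T_corr``.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"scaled functional response must lie in [0,1], got {f}")
    if T_corr <= 0:
        raise ValueError("temperature correction factor must be positive")
    if state.V <= 0:
        raise ValueError("structural volume must be positive to evaluate fluxes")
    tc_feed = T_corr if feeding_T_corr is None else feeding_T_corr
    if s is None:
        s = acceleration_factor(params, state.E_H, state.V, L_s=L_s)

    V = state.V
    V23 = V ** (2.0 / 3.0)
    L = V ** (1.0 / 3.0)

    feeding_on = params.E_Hb is None or state.E_H >= params.E_Hb
    if feeding_on and f > 0:
        p_A = s * params.p_Am_base * f * V23 * tc_feed
        p_X = p_A / params.kap_X
    else:
        p_A = 0.0
        p_X = 0.0

    p_S = (params.p_M * V + params.p_T * V23) * T_corr
    v_eff = s * params.v_base * T_corr
    # standard reserve dynamics: p_C = E*(E_G*v_eff/L + p_S/V)/(kap*E/V + E_G)
    p_C = state.E * (params.E_G * v_eff / L + p_S / V) / (params.kap * state.E / V + params.E_G)
    p_J = params.k_J * state.E_H * T_corr
    p_G = params.kap * p_C - p_S
    p_R = (1.0 - params.kap) * p_C - p_J
    return Fluxes(p_X=p_X, p_A=p_A, p_C=p_C, p_S=p_S, p_J=p_J, p_G=p_G, p_R=p_R)


def state_derivatives(
    params: DEBParams,
    state: OrganismState,
    f: float,
    T_corr: float,
    s: Optional[float] = None,
    L_s: Optional[float] = None,
    feeding_T_corr: Optional[float] = None,
) -> StateDerivatives:
    """Rates of change of (E, V, E_H, E_R, q, h) at one state.

    Maturity is frozen at E_Hp; the allocation p_R then feeds the
    reproduction buffer. Starvation (kappa*p_C < p_S) is paid first from
    the reproduction buffer, then by shrinking structure at cost E_G per
    cm^3; maturity never decreases.
    """
    fx = compute_fluxes(params, state, f, T_corr, s=s, L_s=L_s, feeding_T_corr=feeding_T_corr)
    dE = fx.p_A - fx.p_C

    adult = params.E_Hp is not None and state.E_H >= params.E_Hp
    starving = fx.starving
    if not starving:
        dV = fx.p_G / params.E_G
        if adult:
            dE_H, dE_R = 0.0, fx.p_R
        else:
            dE_H, dE_R = max(fx.p_R, 0.0), 0.0
    else:
        shortfall = -fx.p_G  # J/d still owed to somatic maintenance
        if state.E_R > 0:
            dV = 0.0
            dE_R = (fx.p_R if adult else 0.0) - shortfall
        else:
            dV = -shortfall / params.E_G
            dE_R = max(fx.p_R, 0.0) if adult else 0.0
        dE_H = 0.0

    # Weibull-Gompertz ageing
    if params.h_a is not None:
        e = state.scaled_reserve_density(params)
        L = state.structural_length()
        if s is None:
            s_eff = acceleration_factor(params, state.E_H, state.V, L_s=L_s)
        else:
            s_eff = s
        v_eff = s_eff * params.v_base * T_corr
        r = dV / state.V if state.V > 0 else 0.0
        L_m_acc = params.kap * params.p_Am / params.p_M  # fully accelerated max length
        s_g = params.s_g or 0.0
        dq = (state.q * (state.V / L_m_acc ** 3) * s_g + params.h_a * T_corr) * e * (
            v_eff / L - r
        ) - r * state.q
        dh = state.q - r * state.h
    else:
        dq = dh = 0.0

    return StateDerivatives(dE=dE, dV=dV, dE_H=dE_H, dE_R=dE_R, dq=dq, dh=dh,
                            fluxes=fx, starving=starving)


def compound_parameters(params: DEBParams, f: float = 1.0, s_M: str | float = "reference") -> dict:
    """Derived traits implied by a primary parameter set.

    Parameters
    ----------
    f : float
        Scaled food level for the food-dependent entries (ultimate sizes,
        von Bertalanffy rate).
    s_M : "reference", "lifecycle" or float
        Source of the acceleration factor: the species' reference value,
        the emergent ratio L(E_Hj)/L(E_Hs) of the full lifecycle solution
        at this ``f``, or an explicit number.

    Returns a dict with maximum reserve capacity ``E_m`` (J/cm^3),
    maintenance ratio ``k_M`` (1/d), energy investment ratio ``g``,
    pre- and post-acceleration maximum structural lengths ``L_m_base``
    and ``L_m`` (cm), the derived zoom factor ``z`` (= L_m_base / 1 cm),
    ultimate structural and physical lengths ``L_i``/``Lw_i`` (cm), the
    von Bertalanffy rate ``r_B`` (1/d, at the reference temperature),
    reserve residence time ``t_E_1cm`` (d at L = 1 cm) and ``s_M``.
    """
    E_m = params.E_m
    k_M = params.p_M / params.E_G
    g = params.E_G / (params.kap * E_m)
    if s_M == "lifecycle":
        if not params.has_larval_stages:
            s_M_val = params.s_M_ref
        else:
            from .lifecycle import lifecycle_acceleration

            s_M_val = lifecycle_acceleration(params, f=f)
    elif s_M == "reference":
        s_M_val = params.s_M_ref
    else:
        s_M_val = float(s_M)
    L_m_base = params.kap * params.p_Am_base / params.p_M
    L_m = s_M_val * L_m_base
    L_i = f * L_m
    r_B = (k_M / 3.0) / (1.0 + f / g)
    return {
        "E_m": E_m,
        "k_M": k_M,
        "g": g,
        "L_m_base": L_m_base,
        "L_m": L_m,
        "z": L_m_base,
        "s_M": s_M_val,
        "L_i": L_i,
        "Lw_i": L_i / params.del_M,
        "r_B": r_B,
        "t_E_1cm": 1.0 / params.v,
    }
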