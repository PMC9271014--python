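"""Mapping model state to measurable quantities.

Physical (shell) length uses the stage-dependent shape coefficient
L_w = V^(1/3) / delta; dry tissue weight is structure mass plus the mass
equivalent of reserve and reproduction buffer,
W_d = d_V V + w_E (E + E_R) / mu_E, and wet weight divides by the
species' dry-to-wet tissue ratio. Respiration is reported as a relative
proxy (a weighted sum of dissipating powers); the absolute calibration
is deliberately out of scope.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional

from .core import Fluxes, OrganismState, compute_fluxes
from .environment import CELSIUS_OFFSET, temperature_correction
from .params import DEBParams

__all__ = [
    "physical_length",
    "structural_volume_from_length",
    "dry_weight",
    "wet_weight",
    "weight_components",
    "growth_rate",
    "reproduction_rate",
    "respiration_proxy",
    "clearance_rate",
]

logger = logging.getLogger(__name__)


def physical_length(V: float, params: DEBParams, E_H: Optional[float] = None) -> float:
    """Physical length L_w = V^(1/3)/delta (cm).

    Uses the pre-metamorphosis shape coefficient del_Mb while
    E_H < E_Hj, del_M after (step change at metamorphosis). With no
    maturity given the post-metamorphic shape is assumed.
    """
    if V < 0:
        raise ValueError("structural volume must be non-negative")
    delta = params.del_M if E_H is None else params.shape_coefficient(E_H)
    return V ** (1.0 / 3.0) / delta


def structural_volume_from_length(L_w: float, params: DEBParams,
                                  E_H: Optional[float] = None) -> float:
    """Inverse of :func:`physical_length`."""
    delta = params.del_M if E_H is None else params.shape_coefficient(E_H)
    return (L_w * delta) ** 3


def dry_weight(state: OrganismState, params: DEBParams) -> float:
    """Dry tissue weight (g): structure + reserve + reproduction buffer."""
    c = params.aux
    return c.d_V * state.V + c.w_E * (state.E + state.E_R) / c.mu_E


def wet_weight(state: OrganismState, params: DEBParams) -> float:
    """Total wet tissue weight (g) via the species dry/wet ratio."""
    return dry_weight(state, params) / params.aux.dw_ww_ratio


def weight_components(state: OrganismState, params: DEBParams) -> dict:
    """Dry-weight partition into structure, reserve and buffer (sums exactly)."""
    c = params.aux
    return {
        "structure": c.d_V * state.V,
        "reserve": c.w_E * state.E / c.mu_E,
        "buffer": c.w_E * state.E_R / c.mu_E,
    }


def growth_rate(dw_start: float, dw_end: float, days: float) -> float:
    """Average growth rate (g DW / d) = (DW_end - DW_start) / time.

    Negative values are allowed (shrinkage under starvation).
    """
    if days <= 0:
        raise ValueError("duration must be positive")
    return (dw_end - dw_start) / days


def reproduction_rate(
    params: DEBParams,
    f: float,
    L: float,
    T_C: Optional[float] = None,
    E_0: Optional[float] = None,
    s_M: Optional[float] = None,
) -> float:
    """Continuous egg production rate (eggs/d) of an adult at structural
    length ``L`` and reserve equilibrium (e = f).

    R = kap_R * p_R / E_0, with p_R evaluated at the adult state and
    E_0 the egg cost at reserve density ``f``. Returns 0 (with a
    warning) when the surplus allocation p_R is not positive.
    """
    if params.E_Hp is None:
        raise ValueError("parameter set has no puberty threshold E_Hp")
    if not 0.0 < f <= 1.0:
        raise ValueError("f must lie in (0, 1]")
    T_K = params.temp.T_ref if T_C is None else T_C + CELSIUS_OFFSET
    tc = temperature_correction(params.temp, T_K)
    V = L ** 3
    state = OrganismState(E=f * params.E_m * V, V=V, E_H=params.E_Hp)
    fx = compute_fluxes(params, state, f=f, T_corr=tc, s=s_M or params.s_M_ref)
    if fx.p_R <= 0:
        logger.warning(
            "no reproductive surplus at f=%g, L=%g cm (p_R=%g J/d); rate is 0",
            f, L, fx.p_R,
        )
        return 0.0
    if E_0 is None:
        from .lifecycle import initial_reserve

        E_0 = initial_reserve(params, e_b=min(max(f, 0.1), 1.0))
    return params.kap_R * fx.p_R / E_0


_DEFAULT_RESP_COEFS = {"p_S": 1.0, "p_J": 1.0, "p_R": 1.0, "p_A": 0.0, "p_G": 0.0}


def respiration_proxy(fluxes: Fluxes, coefficients: Optional[Mapping[str, float]] = None) -> float:
    """Relative oxygen-consumption proxy: weighted sum of powers.

    Defaults make the proxy proportional to total dissipation
    (maintenance + maturity maintenance + maturation/reproduction
    overhead); assimilation and growth overheads can be switched on via
    ``coefficients``. The output has arbitrary units by design.
    """
    coefs = dict(_DEFAULT_RESP_COEFS)
    if coefficients:
        unknown = sorted(set(coefficients) - set(coefs))
        if unknown:
            raise ValueError(f"unknown respiration coefficients: {unknown}")
        coefs.update(coefficients)
    if any(c < 0 for c in coefs.values()):
        raise ValueError("respiration coefficients must be non-negative")
    return (
        coefs["p_S"] * fluxes.p_S
        + coefs["p_J"] * fluxes.p_J
        + coefs["p_R"] * max(fluxes.p_R, 0.0)
        + coefs["p_A"] * fluxes.p_A
        + coefs["p_G"] * max(fluxes.p_G, 0.0)
    )


def clearance_rate(
    state: OrganismState,
    params: DEBParams,
    T_C: Optional[float] = None,
    s_M: Optional[float] = None,
) -> float:
    """Mass-specific clearance rate (L/h per g dry weight).

    CR = F_m * s_M * V^(2/3) * TC / (24 * W_d); reported for comparison
    with measured clearance but not calibrated (the per-gram
    normalisation conditions of published values vary).
    """
    if params.F_m is None:
        raise ValueError("parameter set has no searching rate F_m")
    T_K = params.temp.T_ref if T_C is None else T_C + CELSIUS_OFFSET
    tc = temperature_correction(params.temp, T_K)
    s = params.s_M_ref if s_M is None else s_M
    wd = dry_weight(state, params)
    if wd <= 0:
        raise ValueError("dry weight must be positive")
    # F_m is tabulated for the accelerated organism, like p_Am
    return params.F_m * (s / params.s_M_ref) * state.V ** (2.0 / 3.0) * tc / (24.0 * wd)
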