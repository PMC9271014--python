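"""Species parameter sets for the oyster DEB models.

A :class:`DEBParams` instance holds the full primary parameter set of an
individual-level Dynamic Energy Budget model of the 'asj' family
(metabolic acceleration between settlement and the end of metamorphosis),
together with the 5-parameter Arrhenius temperature block and auxiliary
composition constants used to convert energy and structure into weights.

Units follow the DEB convention throughout: time in days, energy in J,
length in cm, volume in cm^3, temperature in Kelvin internally.

The printed maximum surface-specific assimilation rate ``p_Am`` and energy
conductance ``v`` refer to the fully accelerated (juvenile/adult) organism;
the pre-acceleration (embryo/early larva) values are obtained by dividing
by the species' reference acceleration factor ``s_M_ref`` (5.9 for the flat
oyster, 4.8 for the Pacific oyster). Both scalings leave the maximum
reserve capacity [E_m] = p_Am / v unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Optional


__all__ = [
    "TempParams",
    "CompositionParams",
    "DEBParams",
    "PARAM_KEYS",
    "AUX_KEYS",
]


# Table-style key vocabulary for flat parameter files (one value per key).
PARAM_KEYS = (
    "T_ref", "T_A", "T_L", "T_AL", "T_H", "T_AH",
    "z", "F_m", "p_Am", "kap_X", "kap_P", "v", "kap", "kap_R",
    "p_M", "p_T", "k_J", "E_G",
    "E_Hb", "E_Hr", "E_Hs", "E_Hj", "E_Hp",
    "h_a", "s_g", "del_Mb", "del_M", "K_X",
)

AUX_KEYS = ("d_V", "d_E", "mu_E", "w_E", "w_V", "dw_ww_ratio", "s_M_ref")


@dataclass(frozen=True)
class TempParams:
    """Five-parameter Arrhenius thermal-performance block.

    Attributes
    ----------
    T_ref : float
        Reference temperature (K); the correction factor equals 1 there.
    T_A : float
        Arrhenius temperature (K) inside the tolerance range.
    T_L, T_H : float
        Lower / upper boundary of the tolerance range (K).
    T_AL, T_AH : float
        Arrhenius temperatures governing the rate collapse below T_L and
        above T_H (K).
    """

    T_ref: float
    T_A: float
    T_L: float
    T_AL: float
    T_H: float
    T_AH: float

    def __post_init__(self) -> None:
        for name in ("T_ref", "T_A", "T_L", "T_AL", "T_H", "T_AH"):
            if getattr(self, name) <= 0:
                raise ValueError(f"TempParams.{name} must be positive")
        if not (self.T_L < self.T_ref < self.T_H):
            raise ValueError(
                f"require T_L < T_ref < T_H, got {self.T_L}, {self.T_ref}, {self.T_H}"
            )


@dataclass(frozen=True)
class CompositionParams:
    """Biochemical composition constants linking energy/volume to mass.

    Defaults are the conventional generalised-animal values used behind
    weight predictions (d_V = d_E = 0.09 g/cm^3, mu_E = 550 kJ/mol,
    w_E = w_V = 23.9 g/mol); the dry-to-wet tissue ratio is species
    specific (0.015 flat oyster, 0.018 Pacific oyster).
    """

    d_V: float = 0.09          # g dry structure per cm^3
    d_E: float = 0.09          # g dry reserve per cm^3
    mu_E: float = 550_000.0    # J per mol reserve
    w_E: float = 23.9          # g per mol reserve
    w_V: float = 23.9          # g per mol structure
    dw_ww_ratio: float = 0.015  # dry tissue / total wet tissue

    def __post_init__(self) -> None:
        for name in ("d_V", "d_E", "mu_E", "w_E", "w_V", "dw_ww_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"CompositionParams.{name} must be positive")
        if not 0 < self.dw_ww_ratio < 1:
            raise ValueError("dw_ww_ratio must be in (0, 1)")


def _req_pos(value: float, name: str) -> None:
    if value is None or value <= 0:
        raise ValueError(f"DEBParams.{name} must be strictly positive")


@dataclass(frozen=True)
class DEBParams:
    """Full species parameter set (core + temperature + auxiliary).

    The maturity thresholds ``E_Hb`` (birth), ``E_Hr`` (larval release,
    flat oyster only), ``E_Hs`` (settlement), ``E_Hj`` (end of
    metamorphosis) and ``E_Hp`` (puberty) delimit the life stages of the
    asj model. Parameter sets without thresholds (the 'std'-style Pacific
    oyster set) support post-metamorphic simulation only.
    """

    p_Am: float               # max spec assimilation, accelerated (J/d/cm^2)
    v: float                  # energy conductance, accelerated (cm/d)
    kap: float                # allocation fraction to soma
    p_M: float                # volume-specific somatic maintenance (J/d/cm^3)
    E_G: float                # specific cost for structure (J/cm^3)
    k_J: float                # maturity maintenance rate coefficient (1/d)
    kap_R: float              # reproduction efficiency / spawned fraction
    kap_X: float = 0.8        # digestion efficiency food -> reserve
    kap_P: float = 0.1        # faecation efficiency food -> faeces
    p_T: float = 0.0          # surface-specific somatic maintenance (J/d/cm^2)
    F_m: Optional[float] = None   # max spec searching rate (L/d/cm^2)
    z: Optional[float] = None     # printed zoom factor (informational)
    E_Hb: Optional[float] = None  # maturity at birth (J)
    E_Hr: Optional[float] = None  # maturity at larval release (J)
    E_Hs: Optional[float] = None  # maturity at settlement (J)
    E_Hj: Optional[float] = None  # maturity at end of metamorphosis (J)
    E_Hp: Optional[float] = None  # maturity at puberty (J)
    h_a: Optional[float] = None   # Weibull ageing acceleration (1/d^2)
    s_g: Optional[float] = None   # Gompertz stress coefficient
    del_Mb: Optional[float] = None  # shape coefficient before metamorphosis
    del_M: float = 0.4            # shape coefficient after metamorphosis
    K_X: Optional[float] = None   # half-saturation constant (ug chl a / L)
    s_M_ref: float = 1.0          # reference acceleration factor
    temp: TempParams = field(
        default_factory=lambda: TempParams(293.1, 5000.0, 286.0, 23000.0, 303.0, 55610.0)
    )
    aux: CompositionParams = field(default_factory=CompositionParams)
    name: str = ""

    def __post_init__(self) -> None:
        for nm in ("p_Am", "v", "p_M", "E_G", "k_J", "s_M_ref"):
            _req_pos(getattr(self, nm), nm)
        if not 0 < self.kap < 1:
            raise ValueError("kap must be in (0, 1)")
        if not 0 < self.kap_X <= 1:
            raise ValueError("kap_X must be in (0, 1]")
        if not 0 <= self.kap_R <= 1:
            raise ValueError("kap_R must be in [0, 1]")
        if self.p_T < 0:
            raise ValueError("p_T must be non-negative")
        if not 0 < self.del_M < 1:
            raise ValueError("del_M must be in (0, 1)")
        if self.del_Mb is not None and not 0 < self.del_Mb < 1:
            raise ValueError("del_Mb must be in (0, 1)")
        thresholds = [
            (nm, getattr(self, nm))
            for nm in ("E_Hb", "E_Hr", "E_Hs", "E_Hj", "E_Hp")
            if getattr(self, nm) is not None
        ]
        for nm, val in thresholds:
            _req_pos(val, nm)
        vals = [v for _, v in thresholds]
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError(
                "maturity thresholds must be ordered E_Hb <= E_Hr <= E_Hs <= E_Hj <= E_Hp, got "
                + ", ".join(f"{nm}={val:g}" for nm, val in thresholds)
            )
        if self.K_X is not None:
            _req_pos(self.K_X, "K_X")

    # -- acceleration-aware views -------------------------------------

    @property
    def p_Am_base(self) -> float:
        """Pre-acceleration assimilation rate {p_Am}/s_M_ref (J/d/cm^2)."""
        return self.p_Am / self.s_M_ref

    @property
    def v_base(self) -> float:
        """Pre-acceleration energy conductance v/s_M_ref (cm/d)."""
        return self.v / self.s_M_ref

    @property
    def E_m(self) -> float:
        """Maximum reserve capacity [E_m] = {p_Am}/v (J/cm^3); acceleration-invariant."""
        return self.p_Am / self.v

    @property
    def has_larval_stages(self) -> bool:
        """True when the maturity thresholds needed for the full lifecycle are present."""
        return all(
            getattr(self, nm) is not None for nm in ("E_Hb", "E_Hs", "E_Hj", "E_Hp")
        )

    def shape_coefficient(self, E_H: float) -> float:
        """Shape coefficient at maturity level ``E_H``.

        del_Mb applies before the end of metamorphosis, del_M after (step
        change at E_Hj; the isomorphy assumption visibly breaks there).
        """
        if self.E_Hj is not None and E_H < self.E_Hj and self.del_Mb is not None:
            return self.del_Mb
        return self.del_M

    def replace(self, **changes) -> "DEBParams":
        """Return a copy with ``changes`` applied (validated)."""
        return replace(self, **changes)

    # -- flat-file mapping --------------------------------------------

    def to_dict(self) -> dict:
        """Flat key->value mapping using the tabulated symbol names plus an aux block."""
        d = {
            "T_ref": self.temp.T_ref, "T_A": self.temp.T_A,
            "T_L": self.temp.T_L, "T_AL": self.temp.T_AL,
            "T_H": self.temp.T_H, "T_AH": self.temp.T_AH,
            "z": self.z, "F_m": self.F_m, "p_Am": self.p_Am,
            "kap_X": self.kap_X, "kap_P": self.kap_P, "v": self.v,
            "kap": self.kap, "kap_R": self.kap_R, "p_M": self.p_M,
            "p_T": self.p_T, "k_J": self.k_J, "E_G": self.E_G,
            "E_Hb": self.E_Hb, "E_Hr": self.E_Hr, "E_Hs": self.E_Hs,
            "E_Hj": self.E_Hj, "E_Hp": self.E_Hp,
            "h_a": self.h_a, "s_g": self.s_g,
            "del_Mb": self.del_Mb, "del_M": self.del_M, "K_X": self.K_X,
        }
        d = {k: float(v) for k, v in d.items() if v is not None}
        aux = {k: float(v) for k, v in asdict(self.aux).items()}
        aux["s_M_ref"] = float(self.s_M_ref)
        d["aux"] = aux
        if self.name:
            d["name"] = self.name
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DEBParams":
        """Build a validated parameter set from a flat mapping.

        Unknown keys are rejected with the full list of offenders so that
        typos in parameter files fail loudly.
        """
        d = dict(d)
        name = d.pop("name", "")
        aux_d = dict(d.pop("aux", {}) or {})
        unknown = sorted(set(d) - set(PARAM_KEYS))
        if unknown:
            raise KeyError(f"unknown parameter keys: {unknown}; allowed: {list(PARAM_KEYS)}")
        unknown_aux = sorted(set(aux_d) - set(AUX_KEYS))
        if unknown_aux:
            raise KeyError(f"unknown aux keys: {unknown_aux}; allowed: {list(AUX_KEYS)}")
        missing = [k for k in ("p_Am", "v", "kap", "p_M", "E_G", "k_J", "kap_R") if k not in d]
        if missing:
            raise KeyError(f"missing required parameter keys: {missing}")
        t_missing = [k for k in ("T_ref", "T_A", "T_L", "T_AL", "T_H", "T_AH") if k not in d]
        if t_missing:
            raise KeyError(f"missing temperature keys: {t_missing}")
        temp = TempParams(
            T_ref=float(d.pop("T_ref")), T_A=float(d.pop("T_A")),
            T_L=float(d.pop("T_L")), T_AL=float(d.pop("T_AL")),
            T_H=float(d.pop("T_H")), T_AH=float(d.pop("T_AH")),
        )
        s_M_ref = float(aux_d.pop("s_M_ref", 1.0))
        aux = CompositionParams(**{k: float(v) for k, v in aux_d.items()})
        kwargs = {k: (float(v) if v is not None else None) for k, v in d.items()}
        return cls(temp=temp, aux=aux, s_M_ref=s_M_ref, name=name, **kwargs)
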