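"""Environmental forcing: temperature correction and food availability.

All physiological rates are corrected by the 5-parameter Arrhenius factor

    TC(T) = exp(T_A/T_ref - T_A/T) * s(T_ref) / s(T),
    s(T)  = 1 + exp(T_AL/T - T_AL/T_L) + exp(T_AH/T_H - T_AH/T),

which equals 1 at the reference temperature, is maximal inside the
tolerance range [T_L, T_H] and collapses smoothly outside it. Food uptake
is scaled by the Holling type-II functional response
f = X / (X + K_X) on the chlorophyll-a concentration X.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .params import TempParams

__all__ = [
    "CELSIUS_OFFSET",
    "temperature_correction",
    "functional_response",
    "Forcing",
    "ThermalResponse",
]

logger = logging.getLogger(__name__)

CELSIUS_OFFSET = 273.15


def _boundary_term(tp: TempParams, T):
    return (
        1.0
        + np.exp(tp.T_AL / T - tp.T_AL / tp.T_L)
        + np.exp(tp.T_AH / tp.T_H - tp.T_AH / T)
    )


def temperature_correction(tp: TempParams, T):
    """Arrhenius correction factor at absolute temperature ``T`` (K).

    Vectorised over ``T``. TC(T_ref) = 1 exactly; TC > 0 everywhere
    (extreme temperatures drive it towards 0, never an error).
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("absolute temperature must be positive")
    tc = (
        np.exp(tp.T_A / tp.T_ref - tp.T_A / T)
        * _boundary_term(tp, tp.T_ref)
        / _boundary_term(tp, T)
    )
    return float(tc) if tc.ndim == 0 else tc


def functional_response(X, K_X: float):
    """Holling type-II scaled functional response f = X / (X + K_X).

    Parameters
    ----------
    X : float or array
        Food density (ug chl a per L). Must be non-negative.
    K_X : float
        Half-saturation constant (ug chl a per L), strictly positive.
    """
    X = np.asarray(X, dtype=float)
    if K_X <= 0:
        raise ValueError("K_X must be strictly positive")
    if np.any(X < 0):
        raise ValueError("food density must be non-negative")
    f = X / (X + K_X)
    return float(f) if f.ndim == 0 else f


@dataclass(frozen=True)
class ThermalResponse:
    """Coupled or decoupled thermal correction of the flux groups.

    By default one temperature block multiplies every rate (ingestion,
    maintenance, maturation, ageing). Optionally a separate block can be
    supplied for the feeding fluxes — the published improvement path of
    decoupling the Arrhenius relationship of ingestion from respiration —
    while all other rates keep the default block.
    """

    default: TempParams
    feeding: Optional[TempParams] = None

    def factor(self, T_K: float) -> float:
        return temperature_correction(self.default, T_K)

    def feeding_factor(self, T_K: float) -> float:
        tp = self.feeding if self.feeding is not None else self.default
        return temperature_correction(tp, T_K)


class Forcing:
    """Time-indexed temperature and food environment.

    Parameters
    ----------
    time : array
        Strictly increasing time grid (d).
    temperature_C : array
        Water temperature (deg C) on the grid.
    chl : array, optional
        Chlorophyll-a concentration (ug/L); mutually exclusive with ``f``.
    f : array, optional
        Directly supplied scaled functional response in [0, 1].

    Values between grid points are linearly interpolated; evaluation
    beyond the span clamps to the end values (logged once).
    """

    def __init__(
        self,
        time: Sequence[float],
        temperature_C: Sequence[float],
        chl: Optional[Sequence[float]] = None,
        f: Optional[Sequence[float]] = None,
    ):
        self.time = np.atleast_1d(np.asarray(time, dtype=float))
        if self.time.size == 0:
            raise ValueError("forcing must contain at least one record")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("forcing time grid must be strictly increasing")
        self.temperature_C = np.broadcast_to(
            np.asarray(temperature_C, dtype=float), self.time.shape
        ).astype(float)
        if (chl is None) == (f is None):
            raise ValueError("supply exactly one of chl or f")
        if chl is not None:
            self.chl = np.broadcast_to(np.asarray(chl, dtype=float), self.time.shape).astype(float)
            if np.any(self.chl < 0):
                raise ValueError("chlorophyll must be non-negative")
            self.f = None
        else:
            self.f = np.broadcast_to(np.asarray(f, dtype=float), self.time.shape).astype(float)
            if np.any((self.f < 0) | (self.f > 1)):
                raise ValueError("scaled functional response must lie in [0, 1]")
            self.chl = None
        self._warned_clamp = False

    # -- constructors --------------------------------------------------

    @classmethod
    def constant(
        cls,
        temperature_C: float,
        chl: Optional[float] = None,
        f: Optional[float] = None,
        span: float = 1e6,
    ) -> "Forcing":
        """Constant environment over ``[0, span]`` days."""
        t = np.array([0.0, float(span)])
        return cls(
            t,
            [temperature_C, temperature_C],
            chl=None if chl is None else [chl, chl],
            f=None if f is None else [f, f],
        )

    @classmethod
    def from_dataframe(cls, df, food_mode: str = "auto") -> "Forcing":
        """Build from a table with columns day, temperature_C and chl_ugL or f."""
        cols = set(df.columns)
        if "day" not in cols or "temperature_C" not in cols:
            raise ValueError("forcing table needs 'day' and 'temperature_C' columns")
        if food_mode == "auto":
            food_mode = "chl" if "chl_ugL" in cols else "f"
        if food_mode == "chl":
            return cls(df["day"], df["temperature_C"], chl=df["chl_ugL"])
        return cls(df["day"], df["temperature_C"], f=df["f"])

    # -- evaluation ----------------------------------------------------

    @property
    def food_mode(self) -> str:
        return "chl" if self.chl is not None else "f"

    @property
    def span(self) -> tuple[float, float]:
        return float(self.time[0]), float(self.time[-1])

    def _interp(self, series: np.ndarray, t: float) -> float:
        if (t < self.time[0] or t > self.time[-1]) and not self._warned_clamp:
            logger.warning(
                "forcing evaluated outside span [%g, %g] at t=%g; clamping to end values",
                self.time[0], self.time[-1], t,
            )
            self._warned_clamp = True
        return float(np.interp(t, self.time, series))

    def temperature_K(self, t: float) -> float:
        """Temperature (K) at time ``t``."""
        return self._interp(self.temperature_C, t) + CELSIUS_OFFSET

    def food(self, t: float) -> float:
        """Raw food value at ``t``: chlorophyll (ug/L) in chl mode, f otherwise."""
        series = self.chl if self.chl is not None else self.f
        return self._interp(series, t)

    def at(self, t: float, K_X: Optional[float] = None) -> tuple[float, float]:
        """(temperature K, scaled functional response f) at time ``t``.

        In chl mode ``K_X`` is required to convert the concentration to f.
        """
        T_K = self.temperature_K(t)
        if self.chl is not None:
            if K_X is None:
                raise ValueError("K_X required to convert chlorophyll to functional response")
            return T_K, functional_response(self.food(t), K_X)
        return T_K, self.food(t)

    def to_dataframe(self):
        import pandas as pd

        data = {"day": self.time, "temperature_C": self.temperature_C}
        if self.chl is not None:
            data["chl_ugL"] = self.chl
        else:
            data["f"] = self.f
        return pd.DataFrame(data)

    def __repr__(self) -> str:  # pragma: no cover
        lo, hi = self.span
        return f"Forcing({self.food_mode}, t=[{lo:g}, {hi:g}] d, n={self.time.size})"
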