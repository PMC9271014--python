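"""oysterdeb: Dynamic Energy Budget modelling of flat and Pacific oysters.

Individual-level bioenergetics (asj DEB model with metabolic
acceleration) driven by temperature and chlorophyll forcing, life-event
handling from fertilisation to death, and parameter estimation by
Nelder-Mead minimisation of the mean-relative-error loss.
"""

from .core import (
    Fluxes,
    OrganismState,
    StateDerivatives,
    compound_parameters,
    compute_fluxes,
    state_derivatives,
)
from .environment import Forcing, ThermalResponse, functional_response, temperature_correction
from .io import load_species, read_forcing, read_params, write_forcing, write_params
from .lifecycle import (
    BroodState,
    LifeEvents,
    apply_spawning,
    brooding_multiplier,
    detect_events,
    initial_reserve,
    lifecycle_acceleration,
    lifespan,
)
from .params import CompositionParams, DEBParams, TempParams
from .simulate import SimOptions, Trajectory, init_from_weight, run_scenario, simulate

__version__ = "0.1.0"

__all__ = [
    "CompositionParams", "DEBParams", "TempParams",
    "Fluxes", "OrganismState", "StateDerivatives",
    "compound_parameters", "compute_fluxes", "state_derivatives",
    "Forcing", "ThermalResponse", "functional_response", "temperature_correction",
    "load_species", "read_forcing", "read_params", "write_forcing", "write_params",
    "BroodState", "LifeEvents", "apply_spawning", "brooding_multiplier",
    "detect_events", "initial_reserve", "lifecycle_acceleration", "lifespan",
    "SimOptions", "Trajectory", "init_from_weight", "run_scenario", "simulate",
    "DEBModel", "DEBResults",
    "__version__",
]


def __getattr__(name):
    # deferred: model.py imports estimation which imports simulate
    if name in ("DEBModel", "DEBResults"):
        from . import model

        return getattr(model, name)
    raise AttributeError(f"module {__name__!r} has no attribute {name!r}")
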