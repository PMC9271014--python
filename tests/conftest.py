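import numpy as np
import pytest

from oysterdeb import load_species
from oysterdeb.core import OrganismState


@pytest.fixture(scope="session")
def flat():
    """Flat oyster (O. edulis) parameter set."""
    return load_species("o_edulis")


@pytest.fixture(scope="session")
def gigas():
    """Pacific oyster (C. gigas) AmP-style asj parameter set."""
    return load_species("c_gigas_amp")


@pytest.fixture(scope="session")
def gigas_std():
    """Pacific oyster standard-model set (post-metamorphic only)."""
    return load_species("c_gigas_std")


@pytest.fixture(scope="session")
def flat_juvenile(flat):
    """Post-metamorphic flat-oyster juvenile at e = 0.8."""
    V = 0.01
    return OrganismState(E=0.8 * flat.E_m * V, V=V, E_H=flat.E_Hj * 1.5)


@pytest.fixture(scope="session")
def flat_adult(flat):
    """Fully mature flat oyster at e = 0.9 with some buffer."""
    V = 8.0
    return OrganismState(E=0.9 * flat.E_m * V, V=V, E_H=flat.E_Hp, E_R=500.0)


@pytest.fixture(scope="session")
def flat_birth(flat):
    from oysterdeb.lifecycle import embryo_solution

    return embryo_solution(flat, e_b=1.0)


def euler_integrate(params, state, f, T_corr, days, dt):
    """Independent fixed-step Euler oracle for the post-metamorphic ODEs."""
    from oysterdeb.core import state_derivatives

    st = state
    n = int(round(days / dt))
    for _ in range(n):
        d = state_derivatives(params, st, f=f, T_corr=T_corr, s=params.s_M_ref)
        st = st.replace(
            E=st.E + dt * d.dE,
            V=st.V + dt * d.dV,
            E_H=min(st.E_H + dt * d.dE_H, params.E_Hp if params.E_Hp else np.inf),
            E_R=max(st.E_R + dt * d.dE_R, 0.0),
            q=st.q + dt * d.dq,
            h=st.h + dt * d.dh,
        )
    return st
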