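import numpy as np
import pytest

from polyleip import EnergyParams, SolutionConditions, build_chain


@pytest.fixture
def minimal_chain():
    """Three sites joined by two rotatable bonds (spacing 3)."""
    return build_chain(3, 3, 0.2, 120.0)


@pytest.fixture
def rigid_chain10():
    return build_chain(10, spacing=1, bond_length=0.2)


@pytest.fixture
def figure_params():
    """The flexible study parameters: pK=9, eps_t=1, u_g=0, sigma=10."""
    return EnergyParams(pK=9.0, sigma=10.0, u_t=10.0**-1.0, u_g=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240811)


def random_params(rng, forbid_zero=False):
    """Random non-degenerate energy parameters for oracle sweeps."""
    low = 0.05 if forbid_zero else 0.0
    return EnergyParams(
        pK=float(rng.uniform(4.0, 10.0)),
        sigma=float(rng.uniform(low, 3.0)),
        psi=float(rng.uniform(0.2, 2.0)),
        omega=float(rng.uniform(0.2, 2.0)),
        u_t=float(rng.uniform(low, 2.0)),
        u_g=float(rng.uniform(low, 2.0)),
    )


def sr_conditions(pH, I=0.1):
    return SolutionConditions(pH=pH, ionic_strength=I, lr_enabled=False)
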