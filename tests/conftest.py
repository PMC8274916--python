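import numpy as np
import pytest

import poromcts as pm
from poromcts.parameters import ModelParameters


@pytest.fixture(scope="session")
def ct26():
    return pm.preset("CT26-optimized")


@pytest.fixture(scope="session")
def generic():
    return pm.preset("generic")


@pytest.fixture(scope="session")
def coarse_disc():
    """Cheap discretization for solver behavior tests."""
    return pm.Discretization(dh=20e-6, dt=2400.0, t_end=2 * 86400.0)


@pytest.fixture(scope="session")
def free_run_coarse(generic, coarse_disc):
    """One shared 2-day free-growth run on a coarse mesh."""
    return pm.run_simulation(pm.free_growth_domain(), coarse_disc, generic)


@pytest.fixture(scope="session")
def capsule_run_coarse(ct26):
    """One shared encapsulated run on a coarse mesh, past confluence."""
    disc = pm.Discretization(dh=10e-6, dt=2400.0, t_end=8 * 86400.0)
    return pm.run_simulation(
        pm.capsule_domain(), disc, ct26,
        t_end_after_confluence=36 * 3600.0,
    )
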