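import numpy as np
import pytest
from hypothesis import settings

from proteonet import cubic_lattice, preset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def table1():
    """Baseline primary-tauopathy kinetic parameters."""
    return preset("primary_table1")


@pytest.fixture(scope="session")
def secondary():
    """Secondary-tauopathy parameters (b2=0.75, b3=3)."""
    return preset("secondary_table1")


@pytest.fixture(scope="session")
def fig22():
    """Unit-rate primary phase-portrait parameters with 0.01 diffusivities."""
    return preset("fig22_primary")


@pytest.fixture(scope="session")
def fig23():
    """Unit-rate secondary phase-portrait parameters with 0.01 diffusivities."""
    return preset("fig23_secondary")


@pytest.fixture(scope="session")
def small_lattice():
    return cubic_lattice(5, 3, 2)


@pytest.fixture()
def rng():
    return np.random.default_rng(20231013)
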