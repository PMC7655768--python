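import numpy as np
import pytest

from sindypi import systems
from sindypi.library import enumerate_terms, evaluate_terms


@pytest.fixture(scope="session")
def mm_data():
    """Noise-free enzyme-kinetics trajectory with analytic derivatives."""
    t = np.arange(0.0, 10.0 + 1e-12, 0.001)
    return systems.simulate_michaelis_menten(t=t)


@pytest.fixture(scope="session")
def mm_library(mm_data):
    spec = systems.mm_library_spec()
    return evaluate_terms(enumerate_terms(spec), mm_data)


@pytest.fixture(scope="session")
def kdv_field():
    """Modified KdV simulation with the gain term active."""
    return systems.simulate_modified_kdv(systems.KdVParams(g0=1.0, gamma=0.1))
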