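import numpy as np
import pytest

from gencircuit import fixtures
from gencircuit import model as M


@pytest.fixture(scope="session")
def toy():
    """Canonical zero-noise 2-gene / 4-nucleus problem (truth, data, objective)."""
    return fixtures.toy_problem(seed=1)


@pytest.fixture(scope="session")
def toy_truth(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_data(toy):
    return toy[1]


@pytest.fixture(scope="session")
def toy_objective(toy):
    return toy[2]


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def decay_only_params():
    """2-gene circuit with production and diffusion switched off."""
    return M.GeneCircuitParams(
        W=np.zeros((2, 2)), m=np.zeros(2), h=np.zeros(2),
        R=np.array([1e-12, 1e-12]), D_base=np.zeros(2),
        decay=np.log(2.0) / np.array([10.0, 15.0]))
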