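import numpy as np
import pytest

from statescape.mem import MEMParameters
from statescape.simulate import make_ising_model


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_params():
    """A fixed, moderately coupled 3-node model."""
    h = np.array([0.2, -0.1, 0.05])
    J = np.array([[0.0, 0.3, -0.2], [0.3, 0.0, 0.1], [-0.2, 0.1, 0.0]])
    return MEMParameters(h=h, J=J)


@pytest.fixture
def seven_node_model():
    """Random 7-node ground-truth model at the scale used throughout."""
    return make_ising_model(7, 0.3, 0.3, seed=7)


def ferromagnet(n: int, j: float = 0.5) -> MEMParameters:
    J = np.full((n, n), j)
    np.fill_diagonal(J, 0.0)
    return MEMParameters(h=np.zeros(n), J=J)
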