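import numpy as np
import pytest

from neutrobs import NBSParams
from neutrobs._quad import quad_positive


@pytest.fixture(scope="session")
def param_grid():
    """A 3x3 (alpha, beta) grid crossed with indeterminacy levels."""
    alphas = (0.5, 1.0, 1.5)
    betas = (0.5, 1.0, 3.0)
    return [(a, b) for a in alphas for b in betas]


@pytest.fixture(scope="session")
def indeterminacies():
    return (0.0, 0.2, 0.5, 0.8)


@pytest.fixture
def quad():
    """Adaptive-quadrature oracle over the positive half line."""
    return quad_positive


def make_params(alpha, beta, i=0.0):
    return NBSParams(alpha, beta, i)
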