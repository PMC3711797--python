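import numpy as np
import pytest

from ifnosc import ParameterSet, StateVector, simulate


@pytest.fixture(scope="session")
def p():
    return ParameterSet()


@pytest.fixture(scope="session")
def y0():
    return StateVector.default_initial()


@pytest.fixture(scope="session")
def basal_traj(p, y0):
    """One shared basal integration over the 8-hour window."""
    return simulate(p=p, y0=y0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def random_states(rng, n, scale=None):
    """Random non-negative states spanning the physiological decades."""
    if scale is None:
        scale = np.array([1e3, 1e5, 1e4, 1e4, 1e2, 1e5, 1e2, 1e5, 1e1])
    return rng.uniform(0.0, 1.0, size=(n, 9)) * scale
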