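import numpy as np
import pytest

from admarkov import ModelOptions, ParameterSet, StateVector


@pytest.fixture(scope="session")
def params():
    return ParameterSet()


@pytest.fixture(scope="session")
def initial():
    return StateVector()


@pytest.fixture(scope="session")
def opts():
    return ModelOptions()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_states(n, seed=0, scale=None):
    """Random non-negative states spanning the model's concentration scales."""
    gen = np.random.default_rng(seed)
    if scale is None:
        scale = StateVector().as_array()
    return gen.random((n, 9)) * 3.0 * scale
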