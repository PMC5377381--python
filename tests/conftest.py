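import numpy as np
import pytest

import bacfire as bf


@pytest.fixture(scope="session")
def params():
    """Default registry, extended section included."""
    return bf.default_parameters()


@pytest.fixture(scope="session")
def params_5d(params):
    """Default registry restricted to the 5D model."""
    return bf.default_parameters(extended=False)


@pytest.fixture(scope="session")
def rest_5d(params):
    return bf.find_resting_state("5d", params)


@pytest.fixture(scope="session")
def rest_extended(params):
    return bf.find_resting_state("extended", params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
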