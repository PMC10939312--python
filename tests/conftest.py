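import numpy as np
import pytest

from expsup.forward_model import FeatureSpace, build_bank


@pytest.fixture(scope="session")
def circular_space():
    return FeatureSpace("circular")


@pytest.fixture(scope="session")
def linear_space():
    return FeatureSpace("linear")


@pytest.fixture(scope="session")
def circular_bank(circular_space):
    return build_bank(circular_space, sigma=0.5)


@pytest.fixture(scope="session")
def linear_bank(linear_space):
    return build_bank(linear_space, sigma=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
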