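import numpy as np
import pytest

from bclswitch import (
    CompiledModel,
    build_default_network,
    default_rate_params,
    run_monte_carlo,
)


@pytest.fixture(scope="session")
def net():
    return build_default_network()


@pytest.fixture(scope="session")
def params():
    return default_rate_params()


@pytest.fixture(scope="session")
def model(net, params):
    return CompiledModel(net, params)


@pytest.fixture(scope="session")
def small_mc(net, params, model):
    """A small shared Monte-Carlo run for unit-level pattern tests."""
    return run_monte_carlo(net, params, 300, seed=20, model=model)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
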