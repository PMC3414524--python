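import numpy as np
import pytest

from mapkfit import (
    RasInput,
    build_canonical_network,
    build_initial_condition,
    make_rate_vector,
)


@pytest.fixture(scope="session")
def network():
    return build_canonical_network()


@pytest.fixture(scope="session")
def system1():
    return build_initial_condition("system1")


@pytest.fixture(scope="session")
def system2():
    return build_initial_condition("system2")


@pytest.fixture
def ras1():
    return RasInput(peak_amplitude=1.0)


@pytest.fixture
def ras2():
    return RasInput(peak_amplitude=0.4)


@pytest.fixture
def moderate_rates(network):
    """A fixed, well-behaved rate vector for simulation tests."""
    rng = np.random.default_rng(11)
    return make_rate_vector(network, np.exp(rng.uniform(np.log(1.0), np.log(50.0), network.n_rates)))


def random_states(network, rng, n):
    """Random non-negative states of realistic magnitude."""
    return rng.uniform(0.0, 1.5, size=(n, network.n_species))
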