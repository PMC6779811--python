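import numpy as np
import pytest

from ictonet.netgen import GeneratorConfig, Network, generate_network
from ictonet.thetadyn import ThetaParams


@pytest.fixture(scope="session")
def net8():
    """Small directed scale-free network used across simulation tests."""
    return generate_network(
        GeneratorConfig("scale_free_static", 8, 2.0, 3.0, True, seed=21))


@pytest.fixture(scope="session")
def net12():
    return generate_network(
        GeneratorConfig("scale_free_static", 12, 2.0, 3.0, True, seed=11))


@pytest.fixture(scope="session")
def star_net():
    """Directed star: the hub drives every leaf and every leaf feeds the hub."""
    n = 8
    w = np.zeros((n, n))
    w[0, 1:] = 1.0
    w[1:, 0] = 0.3
    return Network(weights=w, directed=True)


@pytest.fixture
def fast_params():
    """Reduced-fidelity integration settings for unit tests."""
    return ThetaParams(k=30.0, n_steps=10_000, n_realizations=1, seed=17)
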