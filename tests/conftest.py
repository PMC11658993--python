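import numpy as np
import pytest

from oscontrol.model import NetworkConfig, NodeParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_node_random(rng):
    """Small asymmetric delayed network for gradient and adjoint checks."""
    C = np.array([[0.0, 1.0], [1.0, 0.0]])
    D = np.array([[0.0, 2.3], [1.1, 0.0]])
    return NetworkConfig(N=2, params=NodeParams(), C=C, D=D, c_gl=1.2,
                         E_ext=[0.7, 0.9], I_ext=[0.3, 0.2])


@pytest.fixture
def single_node_cfg():
    z = np.zeros((1, 1))
    return NetworkConfig(N=1, params=NodeParams(), C=z, D=z, c_gl=0.0,
                         E_ext=1.0, I_ext=1.0)
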