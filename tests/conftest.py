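import numpy as np
import pytest

from columnet.network import NetworkSpec, build_network


@pytest.fixture(scope="session")
def net22():
    """Small two-by-two-hypercolumn network shared across tests."""
    return build_network(NetworkSpec(grid=(2, 2), seed=1))


@pytest.fixture(scope="session")
def net66():
    """Full-size default network (built once; structure-only tests)."""
    return build_network(NetworkSpec(grid=(6, 6), seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
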