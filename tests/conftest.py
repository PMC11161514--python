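import numpy as np
import pytest

from physnet import GrowthConfig, grow_network


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def saturated_small():
    """Saturated d=2, L=32 walk-grown network (shared across tests)."""
    cfg = GrowthConfig(d=2, L=32, process="lerw", seed=7)
    return grow_network(cfg)


@pytest.fixture(scope="session")
def saturated_medium():
    """Saturated d=2, L=300 walk-grown network (shared across tests)."""
    cfg = GrowthConfig(d=2, L=300, process="lerw", seed=11)
    return grow_network(cfg)


@pytest.fixture(scope="session")
def saturated_tiny_layout():
    """Saturated d=2, L=10 layout: small enough for dense eigensolvers."""
    cfg = GrowthConfig(d=2, L=10, process="lerw", seed=3)
    return grow_network(cfg)
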