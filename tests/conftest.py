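import numpy as np
import pytest

from pairdif.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """A small 2-group dataset with one DIF item, reused across tests."""
    cfg = SimulationConfig(S=2, group_sizes=[150, 150], J=5, n_dif_items=1,
                           impact_means=[0.0, 0.3], seed=42)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def medium_sim():
    """A 3-group dataset with two DIF items for solver-level tests."""
    cfg = SimulationConfig(S=3, group_sizes=[300, 300, 300], J=8,
                           n_dif_items=2, impact_means=[0.0, -0.3, 0.3],
                           seed=9)
    return simulate_dataset(cfg)
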