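import numpy as np
import pytest

from polychron import ConnectionTable, NetworkConfig, build_network


@pytest.fixture(scope="session")
def toy_config() -> NetworkConfig:
    return NetworkConfig(n_neurons=20, n_excitatory=16, fan_out=5, seed=123)


@pytest.fixture(scope="session")
def toy_table(toy_config) -> ConnectionTable:
    return build_network(toy_config)


@pytest.fixture(scope="session")
def default_table() -> ConnectionTable:
    return build_network(NetworkConfig(seed=42))


def random_small_table(rng: np.random.Generator, n: int = 10, m: int = 30) -> ConnectionTable:
    """Random small all-excitatory table for oracle comparisons."""
    pre = rng.integers(0, n, m)
    post = (pre + 1 + rng.integers(0, n - 1, m)) % n  # no self-connections
    delay = rng.integers(1, 21, m)
    weight = rng.uniform(0.0, 10.0, m)
    return ConnectionTable.from_arrays(pre, post, delay, weight, np.ones(m, bool))
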