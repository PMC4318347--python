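"""Network topology: connection tables and seeded random construction.

The standard network is 1000 Izhikevich cells (800 RS excitatory, 200 FS
inhibitory).  Every cell sends exactly ``fan_out`` connections to randomly
chosen post-synaptic targets; inhibitory cells project to excitatory cells
only.  Excitatory connections get integer conduction delays drawn uniformly
from 1..20 ms and are plastic; inhibitory connections have a fixed 1 ms delay
and fixed weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["NetworkConfig", "ConnectionTable", "SpikeRaster", "build_network"]


@dataclass(frozen=True)
class NetworkConfig:
    n_neurons: int = 1000
    n_excitatory: int = 800
    fan_out: int = 100
    delay_min: int = 1
    delay_max: int = 20
    init_weight_exc: float = 3.0
    init_weight_inh: float = -2.0
    w_max: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_excitatory < self.n_neurons:
            raise ValueError("need 0 < n_excitatory < n_neurons")
        if not 0 < self.fan_out < self.n_neurons:
            raise ValueError("need 0 < fan_out < n_neurons")
        if self.fan_out > self.n_excitatory:
            raise ValueError(
                "inhibitory fan-out exceeds the excitatory population: "
                f"fan_out={self.fan_out} > n_excitatory={self.n_excitatory}"
            )
        if not 1 <= self.delay_min <= self.delay_max:
            raise ValueError("need 1 <= delay_min <= delay_max")

    @property
    def n_inhibitory(self) -> int:
        return self.n_neurons - self.n_excitatory

    def with_seed(self, seed: int) -> "NetworkConfig":
        return replace(self, seed=seed)


@dataclass
class ConnectionTable:
    """Flat synapse arrays: pre, post, integer delay (ms), weight (mV),
    per-synapse derivative (the synaptic-drive proxy, mV per update
    interval), and a plasticity flag."""

    pre: np.ndarray
    post: np.ndarray
    delay: np.ndarray
    weight: np.ndarray
    derivative: np.ndarray
    plastic: np.ndarray

    @classmethod
    def from_arrays(cls, pre, post, delay, weight, plastic) -> "ConnectionTable":
        pre = np.asarray(pre, dtype=np.int32)
        n = pre.size
        return cls(
            pre=pre,
            post=np.asarray(post, dtype=np.int32),
            delay=np.asarray(delay, dtype=np.int32),
            weight=np.asarray(weight, dtype=np.float64),
            derivative=np.zeros(n, dtype=np.float64),
            plastic=np.asarray(plastic, dtype=bool),
        )

    def __len__(self) -> int:
        return int(self.pre.size)

    def copy(self) -> "ConnectionTable":
        return ConnectionTable(
            self.pre.copy(),
            self.post.copy(),
            self.delay.copy(),
            self.weight.copy(),
            self.derivative.copy(),
            self.plastic.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pre": self.pre,
                "post": self.post,
                "delay": self.delay,
                "weight": self.weight,
                "derivative": self.derivative,
                "plastic": self.plastic,
            }
        )


@dataclass
class SpikeRaster:
    """Time-ordered firing events plus population metadata.

    ``times`` are in ms; events are stored in non-decreasing time order.
    """

    times: np.ndarray
    neurons: np.ndarray
    n_excitatory: int
    n_inhibitory: int
    duration_ms: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.int64)
        self.neurons = np.asarray(self.neurons, dtype=np.int32)
        if self.times.size:
            if self.times.min() < 0:
                raise ValueError("spike times must be non-negative")
            if np.any(np.diff(self.times) < 0):
                raise ValueError("spike times must be non-decreasing")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def n_neurons(self) -> int:
        return self.n_excitatory + self.n_inhibitory

    def spikes_of(self, neuron: int) -> np.ndarray:
        return self.times[self.neurons == neuron]


def build_network(config: NetworkConfig) -> ConnectionTable:
    """Construct a random topology satisfying the wiring rules.

    Deterministic given ``config.seed``.  Duplicate (pre, post) pairs and
    self-connections are excluded by sampling targets without replacement,
    so no two connections share a (pre, post, delay) triple.
    """
    rng = np.random.default_rng(config.seed)
    n, n_exc = config.n_neurons, config.n_excitatory
    pre_blocks, post_blocks, delay_blocks = [], [], []
    for j in range(n):
        if j < n_exc:
            candidates = np.concatenate((np.arange(j), np.arange(j + 1, n)))
            targets = rng.choice(candidates, size=config.fan_out, replace=False)
            delays = rng.integers(
                config.delay_min, config.delay_max + 1, size=config.fan_out
            )
        else:
            # inhibitory cells project to excitatory cells only, delay 1 ms
            targets = rng.choice(n_exc, size=config.fan_out, replace=False)
            delays = np.ones(config.fan_out, dtype=np.int64)
        pre_blocks.append(np.full(config.fan_out, j))
        post_blocks.append(targets)
        delay_blocks.append(delays)
    pre = np.concatenate(pre_blocks)
    post = np.concatenate(post_blocks)
    delay = np.concatenate(delay_blocks)
    excitatory = pre < n_exc
    weight = np.where(excitatory, config.init_weight_exc, config.init_weight_inh)
    return ConnectionTable.from_arrays(pre, post, delay, weight, plastic=excitatory)
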