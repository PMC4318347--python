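"""Temporally asymmetric STDP with per-synapse derivative accumulation.

Each plastic synapse accumulates a *derivative*: the signed sum of pending
STDP changes since the last weight update.  Pairings use exponential traces
with reset-on-spike (nearest-event) semantics:

* LTP — when the post-synaptic cell fires at time t, each plastic afferent is
  potentiated by ``A_ltp * exp(-dt / tau_plus)`` where ``dt`` is the time
  since the pre-synaptic spike *arrived* (pre spike time + conduction delay).
* LTD — when a pre-synaptic spike arrives at time t, the synapse is depressed
  by ``A_ltd * exp(-dt / tau_minus)`` where ``dt`` is the time since the last
  post-synaptic spike.  A simultaneous arrival and post spike (dt = 0) counts
  as full potentiation, not depression.

Once per ``update_interval`` (1 s) the derivative is folded into the weight:

    weight <- clip(weight + drift + derivative, 0, w_max)
    derivative <- decay * derivative

The drift term gives quiet synapses a slow upward bias; the retained,
decaying derivative makes the drive signal an exponentially weighted history
of recent pairings rather than a per-second snapshot.  The amplitudes
``A_ltp``/``A_ltd`` are per post-synaptic neuron and may be modulated by
metaplasticity; their baselines are 0.1 and 0.12.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .network import ConnectionTable

__all__ = ["StdpParams", "ltp_increment", "ltd_decrement", "update_weights"]


@dataclass(frozen=True)
class StdpParams:
    """STDP constants.

    ``a_plus``/``a_minus`` are the baseline pairing amplitudes (and the
    quantities metaplasticity modulates); ``ltd_scale`` is an extra factor
    applied to every depression event, inherited from the reference network
    simulator this platform follows (its depression step applies 1.2x the
    LTD trace).  The net LTD bias (effective amplitude 0.144 vs 0.1 for
    LTP) is what prunes unused synapses during maturation.
    """

    a_plus: float = 0.1
    a_minus: float = 0.12
    ltd_scale: float = 1.2
    tau_plus: float = 20.0
    tau_minus: float = 20.0
    drift: float = 0.01
    decay: float = 0.9
    update_interval: int = 1000

    def __post_init__(self) -> None:
        if self.a_plus <= 0 or self.a_minus <= 0:
            raise ValueError("STDP amplitudes must be positive")
        if self.ltd_scale <= 0:
            raise ValueError("ltd_scale must be positive")
        if not 0 < self.decay < 1:
            raise ValueError(f"decay must lie in (0, 1), got {self.decay}")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("STDP time constants must be positive")
        if self.update_interval < 1:
            raise ValueError("update_interval must be >= 1 ms")


def ltp_increment(dt_ms: float, a_ltp: float, tau_plus: float) -> float:
    """Potentiation for a pre-arrival ``dt_ms`` before the post spike."""
    if dt_ms < 0:
        return 0.0
    return a_ltp * math.exp(-dt_ms / tau_plus)


def ltd_decrement(
    dt_ms: float, a_ltd: float, tau_minus: float, ltd_scale: float = 1.0
) -> float:
    """Depression for a pre-arrival ``dt_ms`` after the post spike."""
    if dt_ms <= 0:
        return 0.0
    return ltd_scale * a_ltd * math.exp(-dt_ms / tau_minus)


def update_weights(
    table: ConnectionTable, params: StdpParams, w_max: float = 10.0
) -> None:
    """Apply the once-per-second weight update in place.

    Plastic weights move by ``drift + derivative`` and are clipped to
    ``[0, w_max]``; the derivative then decays by ``params.decay``.
    Non-plastic synapses are untouched.
    """
    apply_weight_update(
        table.weight, table.derivative, table.plastic, params.drift, params.decay, w_max
    )


def apply_weight_update(weight, derivative, plastic, drift, decay, w_max) -> None:
    """In-place weight/derivative update for plastic synapses."""
    w = weight[plastic]
    np.clip(w + drift + derivative[plastic], 0.0, w_max, out=w)
    weight[plastic] = w
    derivative[plastic] *= decay
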