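"""Synaptic-drive metaplasticity: the weighting function, the per-neuron
modification threshold, and amplitude modulation.

The model regulates plasticity at the level of each post-synaptic cell.  Every
plastic synapse carries a *synaptic derivative* ``d`` (the pending STDP change
accumulated since the last weight update, a proxy for synaptic drive) and a
weight ``w``.  A weighting function turns each ``(d, w)`` pair into a
*resistance* value that is near zero over most of the (drive, weight) plane but
rises exponentially when a strongly driven synapse approaches a soft weight
limit:

    f(d, w) = r * exp(p * map(d)) * (w - soft_min)
            - r * exp(p * (10 - map(d))) * (soft_max - w)

where ``map`` affinely rescales the normal derivative range [-10, +10] into
[0, 10] and clips outside it.  Positive output opposes further potentiation
(large weight under positive drive); negative output opposes further
depression (small weight under negative drive).

The per-neuron modification threshold averages the resistances of the
neuron's plastic afferents and squashes through a tanh:

    theta = tanh(I * mean_i f(d_i, w_i))        theta in (-1, 1)

and the STDP amplitudes are shifted in direct proportion:

    A_ltp = A_ltp0 * (1 - theta)
    A_ltd = A_ltd0 * (1 + theta)

so each amplitude ranges over 0..2x its baseline and the identity
``A_ltp/A_ltp0 + A_ltd/A_ltd0 == 2`` holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MetaParams",
    "ThresholdState",
    "map_derivative",
    "weight_resistance",
    "modification_threshold",
    "modulate_amplitudes",
]


@dataclass(frozen=True)
class MetaParams:
    """Parameters of the metaplasticity model.

    r : resistance (overall amplitude of the weighting function)
    p : precision (curvature; how sharply resistance grows near the limits)
    inertia : sensitivity of the threshold to the mean resistance
    soft_min, soft_max : uncapped soft weight limits (mV) the model defends
    """

    r: float = 0.1
    p: float = 0.5
    inertia: float = 0.2
    soft_min: float = 0.0
    soft_max: float = 10.0

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError(f"resistance r must be >= 0, got {self.r}")
        if self.p < 0:
            raise ValueError(f"precision p must be >= 0, got {self.p}")
        if self.inertia <= 0:
            raise ValueError(f"inertia must be > 0, got {self.inertia}")
        if not self.soft_min < self.soft_max:
            raise ValueError(
                f"soft_min ({self.soft_min}) must be < soft_max ({self.soft_max})"
            )


@dataclass
class ThresholdState:
    """Per-neuron metaplastic state: threshold and modulated amplitudes."""

    theta: np.ndarray
    a_ltp: np.ndarray
    a_ltd: np.ndarray


def map_derivative(x):
    """Affinely map the normal derivative range [-10, +10] onto [0, 10].

    Values outside the normal range are clipped.  Accepts scalars or arrays.
    """
    return np.clip(0.5 * (np.asarray(x, dtype=float) + 10.0), 0.0, 10.0)


def weight_resistance(d, w, params: MetaParams):
    """Resistance to weight change for synapses with derivative ``d``, weight ``w``.

    Vectorised over ``d`` and ``w``.  Positive values oppose potentiation,
    negative values oppose depression; near zero over the central region.
    """
    m = map_derivative(d)
    w = np.asarray(w, dtype=float)
    up = params.r * np.exp(params.p * m) * (w - params.soft_min)
    down = params.r * np.exp(params.p * (10.0 - m)) * (params.soft_max - w)
    return up - down


def modification_threshold(resistances, inertia: float) -> float:
    """tanh-bounded modification threshold from per-afferent resistances.

    Raises ``ValueError`` on an empty afferent set: a neuron with no plastic
    afferent synapses has no defined threshold.
    """
    res = np.asarray(resistances, dtype=float)
    if res.size == 0:
        raise ValueError("modification threshold undefined: no plastic afferents")
    return float(np.tanh(inertia * res.mean()))


def modulate_amplitudes(theta, a_ltp0: float, a_ltd0: float):
    """Shift LTP/LTD amplitudes in direct proportion to the threshold.

    Positive theta suppresses LTP and boosts LTD by the same fraction.
    """
    theta = np.asarray(theta, dtype=float)
    return a_ltp0 - a_ltp0 * theta, a_ltd0 + a_ltd0 * theta
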