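"""Izhikevich point-neuron dynamics for RS (excitatory) and FS (inhibitory) cells.

The membrane follows the two-variable quadratic model

    v' = 0.04 v^2 + 5 v + 140 - u + I
    u' = a (b v - u)

with a spike cutoff at v = 30 mV followed by the reset v <- c, u <- u + d.
Integration uses two 0.5 ms forward-Euler substeps for v and one 1 ms step
for u per tick, with the cutoff checked after each substep.  RS cells are
integrators and show *spike latency*: a just-suprathreshold input pushes v
barely past the unstable equilibrium, and the spike is emitted only after a
slow drift of several tens of milliseconds.  Stronger input shortens the
latency; this latency/weight relationship is what the microcircuit demos
probe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NeuronParams",
    "NeuronState",
    "RS",
    "FS",
    "rest_state",
    "step_neuron",
    "spike_latency_curve",
    "SPIKE_CUTOFF_MV",
]

SPIKE_CUTOFF_MV = 30.0


@dataclass(frozen=True)
class NeuronParams:
    """Izhikevich cell parameters.

    a : recovery time scale (1/ms)
    b : recovery sensitivity (dimensionless)
    c : post-spike reset potential (mV)
    d : post-spike recovery increment
    """

    a: float
    b: float
    c: float
    d: float


#: Regular-spiking excitatory cell (integrator, shows spike latency).
RS = NeuronParams(a=0.02, b=0.2, c=-65.0, d=8.0)
#: Fast-spiking inhibitory cell.
FS = NeuronParams(a=0.1, b=0.2, c=-65.0, d=2.0)


@dataclass
class NeuronState:
    v: float
    u: float


def rest_state(params: NeuronParams) -> NeuronState:
    """Stable resting fixed point of the dynamics (v' = u' = 0, lower root)."""
    # 0.04 v^2 + (5 - b) v + 140 = 0; the more hyperpolarised root is stable.
    bq = 5.0 - params.b
    disc = bq * bq - 4.0 * 0.04 * 140.0
    v = (-bq - math.sqrt(disc)) / (2.0 * 0.04)
    return NeuronState(v=v, u=params.b * v)


def step_neuron(
    state: NeuronState, params: NeuronParams, input_mv: float
) -> tuple[NeuronState, bool]:
    """Advance one neuron by a single 1 ms tick.

    ``input_mv`` is the summed synaptic plus external input for the tick.
    Returns the new state and whether the cell fired; the post-spike reset is
    applied within the tick.  Raises ``FloatingPointError`` on numerical
    blow-up rather than propagating NaN.
    """
    v, u = state.v, state.u
    if not (math.isfinite(v) and math.isfinite(u) and math.isfinite(input_mv)):
        raise FloatingPointError(
            f"non-finite neuron state or input: v={v}, u={u}, I={input_mv}"
        )
    fired = False
    for _ in range(2):
        v += 0.5 * (0.04 * v * v + 5.0 * v + 140.0 - u + input_mv)
        if v >= SPIKE_CUTOFF_MV:
            fired = True
            break
    if fired:
        v = params.c
        u = u + params.d
    else:
        u = u + params.a * (params.b * v - u)
    if not (math.isfinite(v) and math.isfinite(u)):
        raise FloatingPointError(f"neuron state diverged: v={v}, u={u}")
    return NeuronState(v=v, u=u), fired


def _first_spike_time(
    weights: np.ndarray, delays: np.ndarray, params: NeuronParams, horizon_ms: int
) -> float | None:
    """Fire all inputs at t=0; return the output cell's spike time (ms) or None.

    Arrival of input k is at t = delays[k]; the reported time therefore
    includes conduction delays, measured from the common input firing time.
    """
    state = rest_state(params)
    for t in range(horizon_ms):
        drive = float(weights[delays == t].sum())
        state, fired = step_neuron(state, params, drive)
        if fired:
            return float(t)
    return None


def spike_latency_curve(
    weights,
    delays,
    sweep,
    params: NeuronParams = RS,
    horizon_ms: int = 100,
) -> list[tuple[float, float | None]]:
    """Output firing time as a function of combined input weight.

    ``weights`` are per-input base weights (mV) and ``delays`` per-input
    conduction delays (ms); all inputs fire simultaneously at frame start.
    For each combined-weight value in ``sweep`` the base weights are scaled
    together (proportionally to their base values) so that they sum to the
    sweep value, and the output cell's firing time — measured from the input
    firing time, so conduction delays are included — is recorded, or ``None``
    if the cell never fires within ``horizon_ms``.
    """
    weights = np.asarray(weights, dtype=float)
    delays = np.asarray(delays, dtype=int)
    sweep = np.asarray(sweep, dtype=float)
    if sweep.size == 0:
        raise ValueError("empty combined-weight sweep")
    if weights.shape != delays.shape:
        raise ValueError("weights and delays must have matching shapes")
    base_total = weights.sum()
    if base_total <= 0:
        raise ValueError("base weights must have a positive sum")
    curve: list[tuple[float, float | None]] = []
    for total in sweep:
        scaled = weights * (total / base_total)
        curve.append(
            (float(total), _first_spike_time(scaled, delays, params, horizon_ms))
        )
    return curve
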