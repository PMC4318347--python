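"""Mechanistic toy circuits: single-synapse regulation, spike-latency demos,
and input-space response (ISR) analysis.

These small deterministic circuits expose the mechanisms behind the
network-level results:

* the two-cell single-synapse run shows the metaplastic threshold holding a
  persistently driven weight below its hard cap;
* the three-inputs-to-one circuit shows spike latency (near-threshold input
  fires late; stronger input fires earlier) and the latency-driven reversal
  of synaptic drive on a slow connection during training;
* the six-cell circuit maps which input-timing combinations make a target
  cell fire (the *active input space*), and how tuning an afferent weight —
  thereby shifting the middle cell's firing time via spike latency — expands
  that space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import EventStream, Simulation
from .metaplasticity import MetaParams
from .network import ConnectionTable
from .neurons import RS, NeuronParams, spike_latency_curve
from .plasticity import StdpParams

__all__ = [
    "CircuitSpec",
    "single_synapse_circuit",
    "latency_circuit",
    "input_space_circuit",
    "run_single_synapse_demo",
    "latency_demo_curve",
    "run_weight_reversal_demo",
    "InputSpaceResult",
    "input_space_response",
    "optimize_latency",
    "fires_in_frame",
    "LATENCY_DELAYS",
    "LATENCY_WEIGHTS",
]

# Latency-demo defaults: delays/weights chosen so the combined-weight sweep is
# barely superthreshold at its 17 mV lower end (two strong coincident inputs
# plus one weak late one), which is what makes the near-threshold latency
# visible over the whole 17-30 mV sweep.
LATENCY_DELAYS = (10, 10, 13)
LATENCY_WEIGHTS = (8.0, 8.0, 0.8)

# Weight-reversal demo: slow connection C starts weaker and arrives later.
REVERSAL_DELAYS = (10, 10, 15)
REVERSAL_WEIGHTS = (8.0, 8.0, 6.0)


@dataclass
class CircuitSpec:
    """An explicit small circuit: cells, connections and weight cap."""

    cells: list[NeuronParams]
    pre: list[int]
    post: list[int]
    delay: list[int]
    weight: list[float]
    plastic: list[bool]
    w_max: float = 10.0

    @property
    def n(self) -> int:
        return len(self.cells)

    def table(self) -> ConnectionTable:
        return ConnectionTable.from_arrays(
            self.pre, self.post, self.delay, self.weight, self.plastic
        )

    def simulation(
        self,
        stdp: StdpParams = StdpParams(),
        meta: MetaParams | None = None,
    ) -> Simulation:
        return Simulation(
            self.table(),
            n_excitatory=self.n,
            cells=self.cells,
            stdp=stdp,
            meta=meta if meta is not None else MetaParams(soft_max=self.w_max),
            w_max=self.w_max,
            guard_hz=None,
        )


def single_synapse_circuit(weight: float = 6.0, w_max: float = 15.0) -> CircuitSpec:
    """Two RS cells joined by one plastic synapse (delay 1 ms)."""
    return CircuitSpec(
        cells=[RS, RS], pre=[0], post=[1], delay=[1],
        weight=[weight], plastic=[True], w_max=w_max,
    )


def latency_circuit(
    delays=REVERSAL_DELAYS, weights=REVERSAL_WEIGHTS, w_max: float = 10.0
) -> CircuitSpec:
    """Three RS input cells (0, 1, 2) converging on one RS output (3)."""
    return CircuitSpec(
        cells=[RS] * 4, pre=[0, 1, 2], post=[3, 3, 3],
        delay=list(delays), weight=list(weights), plastic=[True] * 3,
        w_max=w_max,
    )


def input_space_circuit(
    delay_4_to_6: int = 2,
    input_delays=REVERSAL_DELAYS,
    weight_1_to_4: float = 10.0,
    w_max: float = 10.0,
) -> CircuitSpec:
    """Six RS cells: 0,1,2 -> 3; 3 -> 5 and 4 -> 5.

    Cell 3 is the latency cell whose firing time depends on its input
    weights; cell 4 is an independent input with a 1 ms delay onto the
    target cell 5.  All weights default to the 10 mV cap.
    """
    return CircuitSpec(
        cells=[RS] * 6,
        pre=[0, 1, 2, 3, 4],
        post=[3, 3, 3, 5, 5],
        delay=[*input_delays, delay_4_to_6, 1],
        weight=[weight_1_to_4, w_max, w_max, w_max, w_max],
        plastic=[True] * 5,
        w_max=w_max,
    )


# -- single-synapse regulation demo ---------------------------------------


@dataclass
class SingleSynapseTrace:
    seconds: np.ndarray
    derivative: np.ndarray
    theta: np.ndarray
    weight: np.ndarray


def _burst_pair_events(
    duration_s: int,
    bursts_per_s: int = 2,
    pulses_per_burst: int = 6,
    pulse_interval_ms: int = 15,
    lead_ms: int = 5,
) -> EventStream:
    """Evenly spaced bursts of pre/post forced-spike pairs, pre leading."""
    burst_starts = np.arange(bursts_per_s) * (1000 // bursts_per_s)
    offsets = (burst_starts[:, None] + np.arange(pulses_per_burst) * pulse_interval_ms).ravel()
    seconds = np.arange(duration_s, dtype=np.int64) * 1000
    pre_times = (seconds[:, None] + offsets[None, :]).ravel()
    post_times = pre_times + lead_ms
    times = np.concatenate([pre_times, post_times])
    neurons = np.concatenate(
        [np.zeros(pre_times.size, np.int32), np.ones(post_times.size, np.int32)]
    )
    return EventStream.forced(times, neurons)


def run_single_synapse_demo(
    metaplasticity: bool,
    duration_s: int = 100,
    meta: MetaParams = MetaParams(r=0.1, p=0.05, inertia=0.2, soft_min=0.0, soft_max=15.0),
    stdp: StdpParams = StdpParams(),
    w_max: float = 15.0,
    bursts_per_s: int = 2,
    pulses_per_burst: int = 6,
    pulse_interval_ms: int = 15,
    lead_ms: int = 5,
) -> SingleSynapseTrace:
    """Drive a single synapse with sustained positive drive for ``duration_s``.

    Both cells receive forced-spike bursts (15 ms between pulses by
    default, two bursts per second) with the pre-synaptic pulse leading the
    post-synaptic one by ``lead_ms``, producing consistent positive synaptic
    drive.  Returns per-second series of the synaptic derivative, the
    post-synaptic cell's modification threshold and the weight, sampled at
    t = 0 and after each one-second weight update.
    """
    circuit = single_synapse_circuit(w_max=w_max)
    sim = circuit.simulation(stdp=stdp, meta=meta)
    events = _burst_pair_events(
        duration_s, bursts_per_s, pulses_per_burst, pulse_interval_ms, lead_ms
    )
    secs, sd, th, wt = [0], [0.0], [0.0], [sim.weights[0]]

    def record(s: Simulation, t_ms: int) -> None:
        secs.append(t_ms // 1000)
        sd.append(s.derivatives[0])
        th.append(s.theta[1])
        wt.append(s.weights[0])

    sim.run(
        duration_s * 1000, events,
        plasticity=True, metaplasticity=metaplasticity, on_second=record,
    )
    return SingleSynapseTrace(
        seconds=np.array(secs), derivative=np.array(sd),
        theta=np.array(th), weight=np.array(wt),
    )


# -- spike-latency sweep ----------------------------------------------------


def latency_demo_curve(
    weights=LATENCY_WEIGHTS,
    delays=LATENCY_DELAYS,
    sweep=None,
):
    """Firing time of the output cell across the combined-weight sweep.

    Defaults to the 17..30 mV sweep in 1 mV steps with the base weights
    stepped together (split proportionally to their base values).
    """
    if sweep is None:
        sweep = np.arange(17.0, 31.0, 1.0)
    return spike_latency_curve(weights, delays, sweep)


# -- weight-reversal demo ---------------------------------------------------


@dataclass
class WeightReversalTrace:
    seconds: np.ndarray
    weights: np.ndarray  # shape (3, n_seconds): connections A, B, C


def run_weight_reversal_demo(
    duration_s: int = 100,
    delays=REVERSAL_DELAYS,
    weights=REVERSAL_WEIGHTS,
    stimulus_hz: int = 5,
    stdp: StdpParams = StdpParams(),
    w_max: float = 10.0,
    plasticity: bool = True,
) -> WeightReversalTrace:
    """Repeatedly fire the three input cells together at ``stimulus_hz``.

    With delays (10, 10, 15) the slow connection C initially arrives before
    the latency-delayed output spike (potentiation), but as A and B
    strengthen the output fires earlier and C's arrivals fall after it,
    reversing the drive: its weight rises and then falls.
    """
    circuit = latency_circuit(delays, weights, w_max=w_max)
    sim = circuit.simulation(stdp=stdp)
    period = 1000 // stimulus_hz
    frame_starts = np.arange(duration_s * stimulus_hz, dtype=np.int64) * period
    times = np.repeat(frame_starts, 3)
    neurons = np.tile(np.array([0, 1, 2], np.int32), frame_starts.size)
    events = EventStream.forced(times, neurons)
    secs, wts = [], []

    def record(s: Simulation, t_ms: int) -> None:
        secs.append(t_ms // 1000)
        wts.append(s.weights[:3].copy())

    sim.run(duration_s * 1000, events, plasticity=plasticity, on_second=record)
    return WeightReversalTrace(seconds=np.array(secs), weights=np.array(wts).T)


# -- input space response ---------------------------------------------------


@dataclass
class InputSpaceResult:
    """Boolean activity map of a target cell over input-timing differences.

    Coordinates are the firing-time differences (t1 - t2, t2 - t3) of the
    three input cells; ``active[i, j]`` is the consistent-firing flag for
    ``(diffs[i], diffs[j])``.  ``best_weight`` holds the optimising weight
    where an optimisation sweep found one (NaN elsewhere).
    """

    diffs: np.ndarray
    active: np.ndarray
    target: int
    n_trials: int
    hit_min: int
    best_weight: np.ndarray | None = None

    @property
    def n_active(self) -> int:
        return int(self.active.sum())


def _representative_times(dt12: int, dt23: int) -> tuple[int, int, int]:
    """Non-negative firing times (t1, t2, t3) realising the differences."""
    t3 = 0
    t2 = dt23
    t1 = dt12 + t2
    shift = min(t1, t2, t3)
    return t1 - shift, t2 - shift, t3 - shift


def fires_in_frame(
    sim: Simulation,
    init_state: dict,
    target: int,
    forced: dict[int, int],
    frame_ms: int = 250,
) -> bool:
    """Reset ``sim`` to ``init_state``, force the given spikes, report firing.

    Each call is an independent trial frame: the circuit starts from the
    same fresh state, the listed cells are forced to fire at their offsets,
    and the return value says whether ``target`` fired within the frame.
    """
    sim.load_state_dict(init_state)
    times = np.array(list(forced.values()), np.int64)
    neurons = np.array(list(forced.keys()), np.int32)
    events = EventStream.forced(times, neurons)
    raster, _ = sim.run(frame_ms, events, plasticity=False, chunk_ms=frame_ms)
    return bool(np.any(raster.neurons == target))


def input_space_response(
    circuit: CircuitSpec,
    target: int,
    timing_range: tuple[int, int] = (0, 20),
    n_trials: int = 400,
    frame_ms: int = 250,
    hit_min: int = 100,
    noise_hz: float = 0.0,
    noise_seed: int = 0,
    extra_forced: dict[int, int] | None = None,
) -> InputSpaceResult:
    """Map the active input space of ``target`` over input-timing differences.

    Cells 0, 1 and 2 are forced to fire at times spanning ``timing_range``;
    the grid is reported in difference coordinates (t1 - t2, t2 - t3), which
    removes the redundancy of translated patterns.  A cell of the grid is
    active iff the target fires in at least ``hit_min`` of ``n_trials``
    frames.  Without background noise the frames are deterministic, so a
    single frame decides the cell; ``noise_hz`` adds per-frame Poisson
    background to make the trial count meaningful.
    """
    lo, hi = timing_range
    if hi <= lo:
        raise ValueError(f"degenerate timing range {timing_range}")
    span = hi - lo
    diffs = np.arange(-span, span + 1)
    active = np.zeros((diffs.size, diffs.size), bool)
    sim = circuit.simulation()
    init = sim.state_dict()
    from .stimuli import poisson_background  # local import avoids cycle

    for i, dt12 in enumerate(diffs):
        for j, dt23 in enumerate(diffs):
            if abs(int(dt12) + int(dt23)) > span:
                continue  # not realisable with all three times inside the range
            t1, t2, t3 = _representative_times(int(dt12), int(dt23))
            forced = {0: lo + t1, 1: lo + t2, 2: lo + t3}
            if extra_forced:
                forced.update(extra_forced)
            if noise_hz <= 0:
                if fires_in_frame(sim, init, target, forced, frame_ms):
                    active[i, j] = True
            else:
                hits = 0
                for trial in range(n_trials):
                    sim.load_state_dict(init)
                    noise = poisson_background(
                        noise_hz, sim.n, frame_ms, (noise_seed, i, j, trial)
                    )
                    times = np.array(list(forced.values()), np.int64)
                    nrns = np.array(list(forced.keys()), np.int32)
                    events = EventStream.forced(times, nrns).merge(noise)
                    raster, _ = sim.run(
                        frame_ms, events, plasticity=False, chunk_ms=frame_ms
                    )
                    hits += bool(np.any(raster.neurons == target))
                active[i, j] = hits >= hit_min
    return InputSpaceResult(
        diffs=diffs, active=active, target=target,
        n_trials=n_trials, hit_min=hit_min,
    )


def optimize_latency(
    delays_4_to_6=(2, 3, 4, 5),
    weight_steps=None,
    timing_range: tuple[int, int] = (0, 20),
    frame_ms: int = 250,
    neuron5_offset: int = 19,
    default_weight: float = 10.0,
) -> dict[int, tuple[InputSpaceResult, InputSpaceResult]]:
    """Expand the target cell's input space by tuning the 1->4 weight.

    For each delay on the 4->6 connection, the non-optimised map uses the
    default 1->4 weight; the optimised map marks a grid cell active iff any
    of the ``weight_steps`` (ten 1 mV steps over 0-10 mV by default) makes
    the target fire consistently.  Cell 4 (the paper's neuron 5) is forced
    at a fixed 19 ms offset in every frame.  Returns, per delay, the
    (non-optimised, optimised) pair; the optimised result records the first
    weight that worked in ``best_weight``.
    """
    if weight_steps is None:
        weight_steps = np.linspace(1.0, 10.0, 10)
    weight_steps = np.asarray(weight_steps, float)
    out: dict[int, tuple[InputSpaceResult, InputSpaceResult]] = {}
    lo, hi = timing_range
    span = hi - lo
    diffs = np.arange(-span, span + 1)
    target = 5
    for d46 in delays_4_to_6:
        sims = {}
        inits = {}
        for w in np.concatenate(([default_weight], weight_steps)):
            circ = input_space_circuit(delay_4_to_6=int(d46), weight_1_to_4=float(w))
            sims[float(w)] = circ.simulation()
            inits[float(w)] = sims[float(w)].state_dict()
        non_opt = np.zeros((diffs.size, diffs.size), bool)
        opt = np.zeros((diffs.size, diffs.size), bool)
        best = np.full((diffs.size, diffs.size), np.nan)
        for i, dt12 in enumerate(diffs):
            for j, dt23 in enumerate(diffs):
                if abs(int(dt12) + int(dt23)) > span:
                    continue
                t1, t2, t3 = _representative_times(int(dt12), int(dt23))
                forced = {0: lo + t1, 1: lo + t2, 2: lo + t3, 4: neuron5_offset}
                if fires_in_frame(
                    sims[default_weight], inits[default_weight], target, forced, frame_ms
                ):
                    non_opt[i, j] = True
                    opt[i, j] = True
                    best[i, j] = default_weight
                else:
                    for w in weight_steps:
                        if fires_in_frame(
                            sims[float(w)], inits[float(w)], target, forced, frame_ms
                        ):
                            opt[i, j] = True
                            best[i, j] = float(w)
                            break
        out[int(d46)] = (
            InputSpaceResult(diffs=diffs, active=non_opt, target=target,
                             n_trials=1, hit_min=1),
            InputSpaceResult(diffs=diffs, active=opt, target=target,
                             n_trials=1, hit_min=1, best_weight=best),
        )
    return out
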