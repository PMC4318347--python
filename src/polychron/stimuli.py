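"""External input generation and the maturation / training / probing protocol.

Background drive is an independent Poisson process per neuron; each event is
a 20 mV super-threshold current pulse.  Patterned stimulation uses a
:class:`StimulusPattern`: a fixed spatio-temporal set of (offset, neuron)
events repeated every ``frame_period`` ms.  Pattern events are *forced*
spikes, so the pattern neurons fire at exactly their offsets in every frame.

The standard experiment runs three phases on the same network:

1. maturation — background only, STDP on, metaplasticity off;
2. training — the pattern at 5 Hz superimposed on 1 Hz background, STDP on,
   metaplasticity on or off depending on the experimental arm;
3. probing — the pattern at 4 Hz with 1 Hz background and all plasticity
   frozen, producing the raster that the fingerprint analysis consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .engine import EventStream, Simulation
from .network import SpikeRaster

__all__ = [
    "StimulusPattern",
    "ascending_pattern",
    "poisson_background",
    "PhaseSpec",
    "ProtocolResult",
    "run_protocol",
]

PULSE_MV = 20.0  # super-threshold pulse delivered by background events


@dataclass(frozen=True)
class StimulusPattern:
    """A repeating spatio-temporal stimulus.

    ``offsets`` (ms within the frame) and ``neurons`` are parallel arrays;
    the pattern repeats every ``frame_period`` ms.
    """

    offsets: tuple[int, ...]
    neurons: tuple[int, ...]
    frame_period: int

    def __post_init__(self) -> None:
        if len(self.offsets) != len(self.neurons):
            raise ValueError("offsets and neurons must have equal length")
        if any(not 0 <= o < self.frame_period for o in self.offsets):
            raise ValueError("offsets must lie in [0, frame_period)")

    @property
    def n_events(self) -> int:
        return len(self.offsets)

    def with_period(self, frame_period: int) -> "StimulusPattern":
        """Same pattern presented at a different repetition rate."""
        return replace(self, frame_period=frame_period)

    def events(self, n_frames: int) -> EventStream:
        """Forced-spike events for ``n_frames`` consecutive frames."""
        off = np.asarray(self.offsets, dtype=np.int64)
        nrn = np.asarray(self.neurons, dtype=np.int32)
        frames = np.arange(n_frames, dtype=np.int64) * self.frame_period
        times = (frames[:, None] + off[None, :]).ravel()
        neurons = np.tile(nrn, n_frames)
        return EventStream.forced(times, neurons)


def ascending_pattern(
    neuron_ids=None, frame_period: int = 200
) -> StimulusPattern:
    """The standard training stimulus: forty firing events in ascending order.

    Event k (k = 1..40) fires ``neuron_ids[k-1]`` at offset k ms, so both
    offsets and neuron ids rise strictly through the first 40 ms of the
    frame.  Defaults to the 40 lowest neuron ids.
    """
    if neuron_ids is None:
        neuron_ids = list(range(40))
    ids = [int(i) for i in neuron_ids]
    if len(ids) != 40:
        raise ValueError(f"ascending pattern needs exactly 40 neuron ids, got {len(ids)}")
    if len(set(ids)) != 40:
        raise ValueError("ascending pattern neuron ids must be distinct")
    if any(b <= a for a, b in zip(ids, ids[1:])):
        raise ValueError("ascending pattern neuron ids must be strictly increasing")
    offsets = tuple(range(1, 41))
    return StimulusPattern(offsets=offsets, neurons=tuple(ids), frame_period=frame_period)


def poisson_background(
    rate_hz: float,
    n_neurons: int,
    duration_ms: int,
    seed,
    amplitude_mv: float = PULSE_MV,
) -> EventStream:
    """Independent Poisson input on each neuron, delivered as current pulses.

    Sampled as the superposition of the per-neuron processes: the population
    event count is Poisson with rate ``n_neurons * rate_hz``, with event
    times uniform over the run and target neurons uniform over the
    population — distributionally identical to independent per-neuron
    processes, and much faster to draw.
    """
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    mean_events = n_neurons * rate_hz * duration_ms / 1000.0
    n_events = int(rng.poisson(mean_events))
    times = rng.integers(0, duration_ms, size=n_events)
    neurons = rng.integers(0, n_neurons, size=n_events)
    return EventStream.pulses(times, neurons, amplitude_mv)


@dataclass(frozen=True)
class PhaseSpec:
    """Durations (s), stimulus rates (Hz) and toggles for the three phases."""

    maturation_s: int = 7200
    training_s: int = 180
    probing_s: int = 100
    background_hz: float = 1.0
    training_frame_ms: int = 200  # 5 Hz
    probing_frame_ms: int = 250   # 4 Hz
    metaplasticity_in_training: bool = True


@dataclass
class ProtocolResult:
    rasters: dict[str, SpikeRaster]
    snapshots: dict[str, dict]
    diagnostics: dict[str, dict]


def _phase_seeds(seed) -> dict[str, np.random.SeedSequence]:
    """Stateless per-phase seed derivation.

    Derivation must not depend on how often the parent sequence was used, so
    that repeated calls (e.g. both experimental arms) see identical phase
    input: each phase gets a fixed spawn-key extension of the parent.
    """
    names = ("maturation", "training", "probing")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = [
        np.random.SeedSequence(entropy=ss.entropy, spawn_key=(*ss.spawn_key, i))
        for i in range(len(names))
    ]
    return dict(zip(names, children))


def run_protocol(
    sim: Simulation,
    pattern: StimulusPattern | None,
    spec: PhaseSpec,
    seed,
    phases: tuple[str, ...] = ("maturation", "training", "probing"),
) -> ProtocolResult:
    """Run the experimental protocol phases in order on ``sim``.

    Phases must be a prefix-ordered subset of maturation -> training ->
    probing.  Training and probing require a pattern.  Snapshots of the full
    network state are taken at each phase boundary.
    """
    allowed = ("maturation", "training", "probing")
    if tuple(sorted(phases, key=allowed.index)) != tuple(phases):
        raise ValueError(f"phases must be ordered {allowed}, got {phases}")
    if pattern is None and any(p in phases for p in ("training", "probing")):
        raise ValueError("training/probing phases require a stimulus pattern")
    seeds = _phase_seeds(seed)
    rasters: dict[str, SpikeRaster] = {}
    snapshots: dict[str, dict] = {}
    diagnostics: dict[str, dict] = {}

    for phase in phases:
        if phase == "maturation":
            dur = spec.maturation_s * 1000
            events = poisson_background(spec.background_hz, sim.n, dur, seeds[phase])
            raster, diag = sim.run(dur, events, plasticity=True, metaplasticity=False)
        elif phase == "training":
            dur = spec.training_s * 1000
            bg = poisson_background(spec.background_hz, sim.n, dur, seeds[phase])
            stim = pattern.with_period(spec.training_frame_ms)
            events = bg.merge(stim.events(dur // spec.training_frame_ms))
            raster, diag = sim.run(
                dur, events, plasticity=True,
                metaplasticity=spec.metaplasticity_in_training,
            )
        else:  # probing: plasticity frozen
            dur = spec.probing_s * 1000
            bg = poisson_background(spec.background_hz, sim.n, dur, seeds[phase])
            stim = pattern.with_period(spec.probing_frame_ms)
            events = bg.merge(stim.events(dur // spec.probing_frame_ms))
            raster, diag = sim.run(dur, events, plasticity=False, metaplasticity=False)
        rasters[phase] = raster
        snapshots[phase] = sim.state_dict()
        diagnostics[phase] = diag
    return ProtocolResult(rasters=rasters, snapshots=snapshots, diagnostics=diagnostics)
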