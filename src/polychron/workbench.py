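"""Experiment orchestration: paired with/without-metaplasticity runs,
reproducible configuration, and deterministic test fixtures.

The headline experiment matures each network once, then trains two arms —
metaplasticity enabled and disabled — from the *same* matured snapshot with
the *same* training and probing input, so every per-network comparison is
paired.  Measurements per arm: PNG size (fingerprint), the three-way weight
census, the connection-activation partition of the probe raster, and the
excitatory firing rate at the end of training.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import (
    build_fingerprint,
    firing_rate,
    partition_connections,
    png_size,
    weight_census,
)
from .engine import Simulation
from .metaplasticity import MetaParams
from .network import NetworkConfig, SpikeRaster, build_network
from .plasticity import StdpParams
from .stimuli import PhaseSpec, ascending_pattern, poisson_background, run_protocol

__all__ = ["RunConfig", "ExperimentSummary", "run_experiment", "generate_fixtures"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a run depends on; a run is a pure function of this."""

    network: NetworkConfig = NetworkConfig()
    stdp: StdpParams = StdpParams()
    meta: MetaParams = MetaParams()
    phases: PhaseSpec = PhaseSpec()
    jitter_ms: int = 2
    consistency_threshold: float = 0.75
    rate_window_s: int = 10
    #: span of probe raster (s) used for the activation partition; over long
    #: spans chance spike pairs make every connection match eventually
    partition_s: int = 1
    guard_hz: float | None = 100.0
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            network=NetworkConfig(**raw["network"]),
            stdp=StdpParams(**raw["stdp"]),
            meta=MetaParams(**raw["meta"]),
            phases=PhaseSpec(**raw["phases"]),
            **{k: raw[k] for k in (
                "jitter_ms", "consistency_threshold", "rate_window_s",
                "partition_s", "guard_hz", "seed",
            )},
        )


#: Desk-scale defaults: 5 networks, 20 min maturation, 180 s training.
DESK_SCALE = RunConfig(phases=PhaseSpec(maturation_s=1200))


@dataclass
class ExperimentSummary:
    per_network: pd.DataFrame
    means: pd.DataFrame

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_network.to_csv(out / "per_network.tsv", sep="\t", index=False)
        self.means.to_csv(out / "arm_means.tsv", sep="\t")


def _measure_arm(
    sim: Simulation,
    config: RunConfig,
    training_raster: SpikeRaster,
    probe_raster: SpikeRaster,
) -> dict:
    table = sim.table()
    census = weight_census(table, w_max=sim.w_max)
    n_frames = config.phases.probing_s * 1000 // config.phases.probing_frame_ms
    fp = build_fingerprint(
        probe_raster,
        frame_period=config.phases.probing_frame_ms,
        n_frames=n_frames,
        consistency_threshold=config.consistency_threshold,
    )
    cut = np.searchsorted(probe_raster.times, config.partition_s * 1000)
    probe_window = SpikeRaster(
        times=probe_raster.times[:cut], neurons=probe_raster.neurons[:cut],
        n_excitatory=probe_raster.n_excitatory,
        n_inhibitory=probe_raster.n_inhibitory,
        duration_ms=config.partition_s * 1000,
    )
    part = partition_connections(probe_window, table, jitter=config.jitter_ms)
    t_end = config.phases.training_s * 1000
    rate = firing_rate(
        training_raster,
        np.arange(sim.n_excitatory),
        t_start_ms=t_end - config.rate_window_s * 1000,
        t_end_ms=t_end,
    )
    return {
        "png_size": png_size(fp),
        "pruned": census.pruned,
        "saturated": census.saturated,
        "other": census.other,
        "exc_rate_hz": rate,
        "active_excitatory": part.excitatory_active,
        "active_inhibitory": part.inhibitory_active,
        "active_total": part.total_active,
    }


def run_experiment(
    config: RunConfig = DESK_SCALE,
    n_networks: int = 5,
    arms: tuple[str, ...] = ("with", "without"),
    progress: bool = False,
) -> ExperimentSummary:
    """Paired comparison of metaplasticity arms over independent networks.

    Each network is built and matured once; both arms then train and probe
    from the same matured snapshot with identical input seeds, so arm
    differences are due to the metaplastic modulation alone.
    """
    if n_networks < 1:
        raise ValueError("need at least one network")
    rows = []
    children = np.random.SeedSequence(config.seed).spawn(n_networks)
    for k in range(n_networks):
        topo_seed = int(children[k].generate_state(1)[0] % (2**31))
        table = build_network(config.network.with_seed(topo_seed))
        pattern = ascending_pattern(
            list(range(40)), frame_period=config.phases.training_frame_ms
        )
        sim = Simulation(
            table,
            n_excitatory=config.network.n_excitatory,
            n_inhibitory=config.network.n_inhibitory,
            stdp=config.stdp,
            meta=config.meta,
            w_max=config.network.w_max,
            guard_hz=config.guard_hz,
        )
        protocol_seed = children[k].spawn(1)[0]
        run_protocol(sim, pattern, config.phases, protocol_seed, phases=("maturation",))
        matured = sim.state_dict()
        for arm in arms:
            if progress:
                print(f"network {k}: arm {arm}")
            sim.load_state_dict(matured)
            spec = replace(
                config.phases, metaplasticity_in_training=(arm == "with")
            )
            result = run_protocol(
                sim, pattern, spec, protocol_seed, phases=("training", "probing")
            )
            row = {"network": k, "arm": arm}
            row.update(
                _measure_arm(
                    sim, config, result.rasters["training"], result.rasters["probing"]
                )
            )
            rows.append(row)
    per_network = pd.DataFrame(rows)
    means = per_network.drop(columns="network").groupby("arm").mean()
    return ExperimentSummary(per_network=per_network, means=means)


# -- deterministic fixtures -------------------------------------------------


def generate_fixtures(kind: str, seed: int = 0, out_dir=None):
    """Small deterministic inputs for testing and demonstration.

    Kinds: ``planted-png-raster`` (400-frame raster with a 10-neuron
    polychronous chain plus 1 Hz noise), ``toy-network`` (20-cell random
    topology), ``toy-raster-for-partition`` (random spikes on 20 neurons),
    ``isr-circuit`` (the six-cell input-space circuit's connection table).
    If ``out_dir`` is given the fixture is also written as text.
    """
    from . import io as pio
    from .microcircuits import input_space_circuit

    rng = np.random.default_rng(seed)
    if kind == "planted-png-raster":
        n_neurons, n_frames, period = 100, 400, 250
        chain_neurons = np.arange(10)
        chain_offsets = 5 + 3 * np.arange(10)  # a polychronous (non-synchronous) chain
        frames = np.arange(n_frames) * period
        pl_times = (frames[:, None] + chain_offsets[None, :]).ravel()
        pl_neurons = np.tile(chain_neurons, n_frames)
        noise = poisson_background(1.0, n_neurons, n_frames * period, rng)
        times = np.concatenate([pl_times, noise.times])
        neurons = np.concatenate([pl_neurons.astype(np.int32), noise.neurons])
        order = np.argsort(times, kind="stable")
        fixture = SpikeRaster(
            times=times[order], neurons=neurons[order],
            n_excitatory=n_neurons, n_inhibitory=0,
            duration_ms=n_frames * period,
        )
        writer = pio.save_raster
    elif kind == "toy-network":
        cfg = NetworkConfig(
            n_neurons=20, n_excitatory=16, fan_out=5,
            seed=int(rng.integers(2**31)),
        )
        fixture = build_network(cfg)
        writer = pio.save_weights
    elif kind == "toy-raster-for-partition":
        n_neurons, n_spikes, span = 20, 200, 1000
        times = np.sort(rng.integers(0, span, n_spikes))
        neurons = rng.integers(0, n_neurons, n_spikes)
        fixture = SpikeRaster(
            times=times, neurons=neurons,
            n_excitatory=n_neurons, n_inhibitory=0, duration_ms=span,
        )
        writer = pio.save_raster
    elif kind == "isr-circuit":
        fixture = input_space_circuit().table()
        writer = pio.save_weights
    else:
        raise ValueError(f"unknown fixture kind: {kind!r}")
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        writer(out / f"{kind}.tsv", fixture)
    return fixture
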