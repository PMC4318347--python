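"""Plain-text file formats for rasters, weights, patterns and fingerprints.

All formats are line-oriented, tab-separated text with ``#``-prefixed
``key=value`` header lines, so runs can be archived and diffed.  Full binary
network snapshots (for exact resume) are handled by
:meth:`polychron.engine.Simulation.save`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .analysis import Fingerprint, FingerprintEntry
from .network import ConnectionTable, SpikeRaster
from .stimuli import StimulusPattern

__all__ = [
    "save_raster", "load_raster",
    "save_weights", "load_weights",
    "save_pattern", "load_pattern",
    "save_fingerprint", "load_fingerprint",
    "save_theta_series",
]


def _read_headers(path) -> dict[str, str]:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    return meta


def save_raster(path, raster: SpikeRaster) -> None:
    """One event per line: ``time_ms<TAB>neuron_id`` with population header."""
    with open(path, "w") as fh:
        fh.write(f"# n_excitatory={raster.n_excitatory}\n")
        fh.write(f"# n_inhibitory={raster.n_inhibitory}\n")
        fh.write(f"# duration_ms={raster.duration_ms}\n")
        for t, i in zip(raster.times, raster.neurons):
            fh.write(f"{t}\t{i}\n")


def load_raster(path) -> SpikeRaster:
    meta = _read_headers(path)
    data = np.loadtxt(path, dtype=np.int64, comments="#", ndmin=2)
    times = data[:, 0] if data.size else np.empty(0, np.int64)
    neurons = data[:, 1] if data.size else np.empty(0, np.int32)
    return SpikeRaster(
        times=times, neurons=neurons,
        n_excitatory=int(meta["n_excitatory"]),
        n_inhibitory=int(meta["n_inhibitory"]),
        duration_ms=int(meta.get("duration_ms", 0)),
    )


def save_weights(path, table: ConnectionTable) -> None:
    """Tabular weight snapshot: ``pre post delay weight plastic``."""
    df = table.to_frame().drop(columns="derivative")
    df["plastic"] = df["plastic"].astype(int)
    df.to_csv(path, sep="\t", index=False)


def load_weights(path) -> ConnectionTable:
    df = pd.read_csv(path, sep="\t")
    return ConnectionTable.from_arrays(
        df["pre"], df["post"], df["delay"], df["weight"], df["plastic"].astype(bool)
    )


def save_pattern(path, pattern: StimulusPattern) -> None:
    """Stimulus pattern: ``offset_ms neuron_id`` with a frame-period header."""
    with open(path, "w") as fh:
        fh.write(f"# frame_period={pattern.frame_period}\n")
        for off, nrn in zip(pattern.offsets, pattern.neurons):
            fh.write(f"{off}\t{nrn}\n")


def load_pattern(path) -> StimulusPattern:
    meta = _read_headers(path)
    data = np.loadtxt(path, dtype=np.int64, comments="#", ndmin=2)
    return StimulusPattern(
        offsets=tuple(int(x) for x in data[:, 0]),
        neurons=tuple(int(x) for x in data[:, 1]),
        frame_period=int(meta["frame_period"]),
    )


def save_fingerprint(path, fp: Fingerprint) -> None:
    """Fingerprint entries: ``neuron window_start window_end probability``."""
    with open(path, "w") as fh:
        fh.write(f"# consistency_threshold={fp.consistency_threshold}\n")
        fh.write(f"# n_frames={fp.n_frames}\n")
        fh.write(f"# frame_period={fp.frame_period}\n")
        for e in fp.entries:
            fh.write(f"{e.neuron}\t{e.window[0]}\t{e.window[1]}\t{e.probability:.6f}\n")


def load_fingerprint(path) -> Fingerprint:
    meta = _read_headers(path)
    entries = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            n, w0, w1, p = line.split("\t")
            entries.append(
                FingerprintEntry(int(n), (int(w0), int(w1)), float(p))
            )
    return Fingerprint(
        entries=entries,
        consistency_threshold=float(meta["consistency_threshold"]),
        n_frames=int(meta["n_frames"]),
        frame_period=int(meta["frame_period"]),
    )


def save_theta_series(path, samples: list[tuple[int, np.ndarray]]) -> None:
    """Modification-threshold time series: ``time_s neuron theta`` rows."""
    with open(path, "w") as fh:
        fh.write("time_s\tneuron\ttheta\n")
        for t_s, theta in samples:
            for i, th in enumerate(np.asarray(theta)):
                fh.write(f"{t_s}\t{i}\t{th:.9g}\n")
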