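"""Response analysis: fingerprints, PNG size, connection activation, weight
census and firing rates.

A *response fingerprint* summarises stimulus-locked firing over repeated
presentation frames: for every neuron, the peri-stimulus time histogram
(1 ms bins, one hit per frame per bin) is scanned for contiguous peak
regions, and a region becomes a fingerprint entry when the fraction of
frames with at least one spike inside it reaches the consistency threshold
(0.75 by default).  The number of distinct neurons holding at least one
entry is the *PNG size* — the count of cells reliably participating in the
polychronous response.

The *connection-activation partition* asks, for every connection, whether
the probe raster contains a pre/post spike pair whose separation matches the
conduction delay within a small jitter: ``delay <= t_post - t_pre <=
delay + jitter``.  Matching connections are labelled active — they plausibly
carried a causal contribution during PNG activation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .network import ConnectionTable, SpikeRaster

__all__ = [
    "Fingerprint",
    "FingerprintEntry",
    "WeightCensus",
    "ActivationPartition",
    "build_fingerprint",
    "png_size",
    "partition_connections",
    "weight_census",
    "firing_rate",
]


@dataclass(frozen=True)
class FingerprintEntry:
    neuron: int
    window: tuple[int, int]  # [start, end] ms, inclusive, relative to frame onset
    probability: float


@dataclass
class Fingerprint:
    entries: list[FingerprintEntry]
    consistency_threshold: float
    n_frames: int
    frame_period: int

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def neurons(self) -> set[int]:
        return {e.neuron for e in self.entries}


@dataclass(frozen=True)
class WeightCensus:
    """Three-way census of plastic (excitatory) weights."""

    pruned: int      # weight exactly 0
    saturated: int   # weight exactly w_max
    other: int

    @property
    def total(self) -> int:
        return self.pruned + self.saturated + self.other


@dataclass
class ActivationPartition:
    active: np.ndarray        # connection indices labelled active
    n_connections: int
    excitatory_active: int
    inhibitory_active: int
    jitter: int

    @property
    def total_active(self) -> int:
        return int(self.active.size)


def build_fingerprint(
    probe_raster: SpikeRaster,
    frame_period: int,
    n_frames: int,
    consistency_threshold: float = 0.75,
    bin_floor: float = 0.25,
    merge_gap: int = 1,
) -> Fingerprint:
    """Scan peri-stimulus histograms for consistent stimulus-locked windows.

    ``bin_floor`` is the per-bin frame-hit fraction above which a bin can
    seed a peak region; runs of such bins separated by at most ``merge_gap``
    sub-floor bins are merged into one candidate region.  A region is kept
    iff its frame-consistency (fraction of frames containing at least one
    spike inside it) reaches ``consistency_threshold``.
    """
    if n_frames < 1:
        raise ValueError("fingerprint needs at least one stimulus frame")
    if not 0.0 < consistency_threshold <= 1.0:
        raise ValueError("consistency threshold must lie in (0, 1]")
    span = n_frames * frame_period
    if probe_raster.duration_ms and probe_raster.duration_ms < span:
        raise ValueError(
            f"raster spans {probe_raster.duration_ms} ms < "
            f"{n_frames} frames of {frame_period} ms"
        )
    mask = probe_raster.times < span
    times = probe_raster.times[mask]
    neurons = probe_raster.neurons[mask]
    frames = times // frame_period
    offsets = times % frame_period

    entries: list[FingerprintEntry] = []
    for neuron in np.unique(neurons):
        sel = neurons == neuron
        fr = frames[sel]
        off = offsets[sel]
        # one hit per (frame, bin)
        key = fr * frame_period + off
        uniq = np.unique(key)
        ubin = uniq % frame_period
        hit_frac = np.bincount(ubin.astype(np.int64), minlength=frame_period) / n_frames
        above = hit_frac >= bin_floor
        for start, end in _merged_runs(above, merge_gap):
            in_region = (off >= start) & (off <= end)
            consistency = np.unique(fr[in_region]).size / n_frames
            if consistency >= consistency_threshold:
                entries.append(
                    FingerprintEntry(
                        neuron=int(neuron),
                        window=(int(start), int(end)),
                        probability=float(consistency),
                    )
                )
    return Fingerprint(
        entries=entries,
        consistency_threshold=consistency_threshold,
        n_frames=n_frames,
        frame_period=frame_period,
    )


def _merged_runs(above: np.ndarray, merge_gap: int) -> list[tuple[int, int]]:
    """Maximal runs of True bins, merging runs separated by <= merge_gap."""
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return []
    runs = []
    start = prev = idx[0]
    for b in idx[1:]:
        if b - prev <= merge_gap + 1:
            prev = b
        else:
            runs.append((int(start), int(prev)))
            start = prev = b
    runs.append((int(start), int(prev)))
    return runs


def png_size(fingerprint: Fingerprint) -> int:
    """Number of distinct neurons with at least one fingerprint entry."""
    return len(fingerprint.neurons)


@njit(cache=True)
def _active_mask(pre, post, delay, spk_ptr, spk_times, jitter):
    m = pre.size
    out = np.zeros(m, np.bool_)
    for s in range(m):
        p0, p1 = spk_ptr[pre[s]], spk_ptr[pre[s] + 1]
        q0, q1 = spk_ptr[post[s]], spk_ptr[post[s] + 1]
        if p1 == p0 or q1 == q0:
            continue
        lo, hi = delay[s], delay[s] + jitter
        q = q0
        for pi in range(p0, p1):
            t1 = spk_times[pi]
            while q < q1 and spk_times[q] < t1 + lo:
                q += 1
            if q < q1 and spk_times[q] <= t1 + hi:
                out[s] = True
                break
    return out


def partition_connections(
    raster: SpikeRaster, table: ConnectionTable, jitter: int = 2
) -> ActivationPartition:
    """Label each connection active iff some pre/post spike pair fits its delay.

    A connection is active when there exist spikes at ``t1`` (pre) and ``t2``
    (post) with ``delay <= t2 - t1 <= delay + jitter``.
    """
    n = raster.n_neurons
    order = np.argsort(raster.neurons, kind="stable")
    spk_n = raster.neurons[order]
    spk_t = raster.times[order].astype(np.int64)
    spk_ptr = np.searchsorted(spk_n, np.arange(n + 1)).astype(np.int64)
    mask = _active_mask(
        table.pre.astype(np.int64),
        table.post.astype(np.int64),
        table.delay.astype(np.int64),
        spk_ptr, spk_t, int(jitter),
    )
    active = np.flatnonzero(mask)
    exc = int(table.plastic[active].sum())
    return ActivationPartition(
        active=active,
        n_connections=len(table),
        excitatory_active=exc,
        inhibitory_active=int(active.size - exc),
        jitter=int(jitter),
    )


def weight_census(table: ConnectionTable, w_max: float = 10.0) -> WeightCensus:
    """Exact three-way census of the plastic (excitatory) weights.

    Exact comparison is valid because clipping lands weights exactly on the
    bounds 0 and ``w_max``.
    """
    w = table.weight[table.plastic]
    pruned = int((w == 0.0).sum())
    saturated = int((w == w_max).sum())
    return WeightCensus(
        pruned=pruned, saturated=saturated, other=int(w.size - pruned - saturated)
    )


def firing_rate(
    raster: SpikeRaster,
    population,
    t_start_ms: int = 0,
    t_end_ms: int | None = None,
) -> float:
    """Mean spikes per neuron per second over a population and time window."""
    population = np.asarray(population)
    if population.size == 0:
        raise ValueError("firing rate undefined for an empty population")
    if t_end_ms is None:
        t_end_ms = raster.duration_ms or (int(raster.times.max()) + 1 if len(raster) else 1000)
    window_s = (t_end_ms - t_start_ms) / 1000.0
    if window_s <= 0:
        raise ValueError("time window must have positive length")
    in_window = (raster.times >= t_start_ms) & (raster.times < t_end_ms)
    n_spikes = int(np.isin(raster.neurons[in_window], population).sum())
    return n_spikes / population.size / window_s
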