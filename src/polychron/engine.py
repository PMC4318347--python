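"""Millisecond-resolution simulation engine.

The engine advances an Izhikevich network on a 1 ms grid.  Spikes propagate
along their connections and the weight arrives at the post-synaptic cell
exactly ``delay`` ms after the spike; simultaneous arrivals sum linearly.
STDP pairing, derivative accumulation, the once-per-second weight update and
the metaplastic threshold update all happen inside a single compiled kernel,
so a run is a deterministic function of the initial state and the external
event stream.

External input is an :class:`EventStream` of timed events per neuron, either
current pulses (mV added to that tick's input) or forced spikes (the cell is
made to fire at exactly that tick, with the normal reset applied).

STDP bookkeeping uses per-neuron exponential traces with reset-on-spike
semantics.  The potentiation trace is kept as a short ring of per-neuron
trace values over the last ``delay_max + 1`` ticks, so that the trace seen by
a synapse can be read at the *arrival* time of the pre-synaptic spike
(spike time + conduction delay), which is what makes delays up to 20 ms
meaningful for pairing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit

from .metaplasticity import MetaParams
from .network import ConnectionTable, SpikeRaster
from .neurons import FS, RS, NeuronParams, rest_state
from .plasticity import StdpParams

__all__ = [
    "EventStream",
    "Simulation",
    "SimulationError",
    "RunawayFiringError",
    "run",
]

PULSE = 0  # event kind: current pulse (value in mV)
FORCE = 1  # event kind: forced spike


class SimulationError(RuntimeError):
    """Numerical fault during simulation (named neuron and tick)."""


class RunawayFiringError(RuntimeError):
    """Network-wide firing rate exceeded the configured guard."""

    def __init__(self, message: str, diagnostics: dict):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass
class EventStream:
    """Timed external events: (time ms, neuron, kind, value)."""

    times: np.ndarray
    neurons: np.ndarray
    kinds: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.int64)
        self.neurons = np.asarray(self.neurons, dtype=np.int32)
        self.kinds = np.asarray(self.kinds, dtype=np.int8)
        self.values = np.asarray(self.values, dtype=np.float64)
        order = np.argsort(self.times, kind="stable")
        self.times = self.times[order]
        self.neurons = self.neurons[order]
        self.kinds = self.kinds[order]
        self.values = self.values[order]

    def __len__(self) -> int:
        return int(self.times.size)

    @classmethod
    def empty(cls) -> "EventStream":
        return cls(np.empty(0, np.int64), np.empty(0, np.int32),
                   np.empty(0, np.int8), np.empty(0, np.float64))

    @classmethod
    def pulses(cls, times, neurons, amplitude_mv: float = 20.0) -> "EventStream":
        times = np.asarray(times, dtype=np.int64)
        return cls(times, neurons, np.full(times.size, PULSE, np.int8),
                   np.full(times.size, float(amplitude_mv)))

    @classmethod
    def forced(cls, times, neurons) -> "EventStream":
        times = np.asarray(times, dtype=np.int64)
        return cls(times, neurons, np.full(times.size, FORCE, np.int8),
                   np.zeros(times.size))

    def merge(self, other: "EventStream") -> "EventStream":
        return EventStream(
            np.concatenate([self.times, other.times]),
            np.concatenate([self.neurons, other.neurons]),
            np.concatenate([self.kinds, other.kinds]),
            np.concatenate([self.values, other.values]),
        )


@njit(cache=True)
def _advance(
    v, u, pa, pb, pc, pd,
    syn_pre, syn_post, syn_delay, syn_w, syn_sd, syn_plastic,
    blk_ptr, aff_ptr, aff_idx,
    ltp_ring, ltd_trace, fired_ring, fired_cnt,
    theta, a_ltp, a_ltd,
    ltp_decay, ltd_decay, ltd_scale,
    a_plus0, a_minus0, drift, sd_decay, update_interval,
    meta_r, meta_p, inertia, soft_min, soft_max, w_max,
    plasticity_on, meta_on,
    ev_t, ev_n, ev_kind, ev_val, ev_start,
    t0, n_ticks, delay_max,
    spike_t, spike_n,
):
    n = v.size
    H = delay_max + 1
    I = np.zeros(n)
    forced = np.zeros(n, np.uint8)
    nspk = 0
    ev_i = ev_start
    n_ev = ev_t.size
    status = 0
    bad_i = -1
    bad_t = -1
    for tick in range(n_ticks):
        t = t0 + tick
        h = t % H
        ph = (t - 1) % H
        for i in range(n):
            I[i] = 0.0
            forced[i] = 0
            ltp_ring[h, i] = ltp_ring[ph, i] * ltp_decay
            ltd_trace[i] *= ltd_decay
        fired_cnt[h] = 0
        while ev_i < n_ev and ev_t[ev_i] == t:
            i = ev_n[ev_i]
            if ev_kind[ev_i] == 0:
                I[i] += ev_val[ev_i]
            else:
                forced[i] = 1
            ev_i += 1
        # deliver spikes whose conduction delay elapses this tick
        for dly in range(1, delay_max + 1):
            hh = (t - dly) % H
            for k in range(fired_cnt[hh]):
                j = fired_ring[hh, k]
                base = j * (delay_max + 1) + dly
                for s in range(blk_ptr[base], blk_ptr[base + 1]):
                    po = syn_post[s]
                    I[po] += syn_w[s]
                    if plasticity_on and syn_plastic[s]:
                        syn_sd[s] -= ltd_scale * a_ltd[po] * ltd_trace[po]
        # integrate membranes; two 0.5 ms substeps for v, 1 ms step for u
        for i in range(n):
            if forced[i] == 1:
                vv = pc[i]
                uu = u[i] + pd[i]
                fired = True
            else:
                vv = v[i]
                uu = u[i]
                Ii = I[i]
                fired = False
                vv += 0.5 * (0.04 * vv * vv + 5.0 * vv + 140.0 - uu + Ii)
                if vv >= 30.0:
                    fired = True
                else:
                    vv += 0.5 * (0.04 * vv * vv + 5.0 * vv + 140.0 - uu + Ii)
                    if vv >= 30.0:
                        fired = True
                if fired:
                    vv = pc[i]
                    uu = uu + pd[i]
                else:
                    uu = uu + pa[i] * (pb[i] * vv - uu)
                if not (math.isfinite(vv) and math.isfinite(uu)):
                    status = 1
                    bad_i = i
                    bad_t = t
                    break
            v[i] = vv
            u[i] = uu
            if fired:
                spike_t[nspk] = t
                spike_n[nspk] = i
                nspk += 1
                fired_ring[h, fired_cnt[h]] = i
                fired_cnt[h] += 1
                ltp_ring[h, i] = 1.0
                ltd_trace[i] = 1.0
                if plasticity_on:
                    # potentiate plastic afferents by their pre-arrival trace
                    for q in range(aff_ptr[i], aff_ptr[i + 1]):
                        s = aff_idx[q]
                        ts = t - syn_delay[s]
                        syn_sd[s] += a_ltp[i] * ltp_ring[ts % H, syn_pre[s]]
        if status != 0:
            break
        # once-per-second update: threshold first, then weights
        if plasticity_on and (t + 1) % update_interval == 0:
            if meta_on:
                for i in range(n):
                    q0 = aff_ptr[i]
                    q1 = aff_ptr[i + 1]
                    if q1 > q0:
                        acc = 0.0
                        for q in range(q0, q1):
                            s = aff_idx[q]
                            m = 0.5 * (syn_sd[s] + 10.0)
                            if m < 0.0:
                                m = 0.0
                            elif m > 10.0:
                                m = 10.0
                            acc += (
                                meta_r * math.exp(meta_p * m)
                                * (syn_w[s] - soft_min)
                                - meta_r * math.exp(meta_p * (10.0 - m))
                                * (soft_max - syn_w[s])
                            )
                        th = math.tanh(inertia * acc / (q1 - q0))
                        theta[i] = th
                        a_ltp[i] = a_plus0 - a_plus0 * th
                        a_ltd[i] = a_minus0 + a_minus0 * th
            for s in range(syn_w.size):
                if syn_plastic[s]:
                    w = syn_w[s] + drift + syn_sd[s]
                    if w < 0.0:
                        w = 0.0
                    elif w > w_max:
                        w = w_max
                    syn_w[s] = w
                    syn_sd[s] *= sd_decay
    return nspk, ev_i, status, bad_i, bad_t


def _cell_arrays(cells: list[NeuronParams]):
    a = np.array([c.a for c in cells])
    b = np.array([c.b for c in cells])
    c_ = np.array([c.c for c in cells])
    d = np.array([c.d for c in cells])
    return a, b, c_, d


class Simulation:
    """Stateful network simulation: cells, synapses, traces and thresholds.

    Cells ``0..n_excitatory-1`` are RS unless ``cells`` overrides the
    per-neuron parameters; the remainder are FS.  The connection table is
    copied in; the current weights/derivatives are read back with
    :meth:`table`, preserving the caller's connection order.
    """

    def __init__(
        self,
        table: ConnectionTable,
        n_excitatory: int,
        n_inhibitory: int = 0,
        cells: Optional[list[NeuronParams]] = None,
        stdp: StdpParams = StdpParams(),
        meta: MetaParams = MetaParams(),
        w_max: float = 10.0,
        guard_hz: Optional[float] = 100.0,
    ):
        n = n_excitatory + n_inhibitory
        if cells is None:
            cells = [RS] * n_excitatory + [FS] * n_inhibitory
        if len(cells) != n:
            raise ValueError("cell parameter list does not match population size")
        if len(table) and (table.pre.min() < 0 or max(table.pre.max(), table.post.max()) >= n):
            raise ValueError("connection endpoints outside the population")
        if len(table) and table.delay.min() < 1:
            raise ValueError("conduction delays must be >= 1 ms")
        self.n = n
        self.n_excitatory = n_excitatory
        self.n_inhibitory = n_inhibitory
        self.stdp = stdp
        self.meta = meta
        self.w_max = float(w_max)
        self.guard_hz = guard_hz
        self._a, self._b, self._c, self._d = _cell_arrays(cells)
        self._cells = list(cells)

        D = int(table.delay.max()) if len(table) else 1
        self.delay_max = max(D, 1)
        # sort synapses into (pre, delay) blocks for arrival-time dispatch
        key = table.pre.astype(np.int64) * (self.delay_max + 1) + table.delay
        self._order = np.argsort(key, kind="stable")
        self._pre = table.pre[self._order].astype(np.int32)
        self._post = table.post[self._order].astype(np.int32)
        self._delay = table.delay[self._order].astype(np.int32)
        self._w = table.weight[self._order].astype(np.float64)
        self._sd = table.derivative[self._order].astype(np.float64)
        self._plastic = table.plastic[self._order].astype(np.bool_)
        sorted_key = key[self._order]
        self._blk_ptr = np.searchsorted(
            sorted_key, np.arange(self.n * (self.delay_max + 1) + 1)
        ).astype(np.int64)
        # plastic afferents grouped by post-synaptic cell
        plastic_idx = np.flatnonzero(self._plastic)
        by_post = plastic_idx[np.argsort(self._post[plastic_idx], kind="stable")]
        self._aff_idx = by_post.astype(np.int64)
        self._aff_ptr = np.searchsorted(
            self._post[by_post], np.arange(self.n + 1)
        ).astype(np.int64)

        # dynamic state
        self.t = 0
        self._v = np.empty(n)
        self._u = np.empty(n)
        for i, cp in enumerate(cells):
            st = rest_state(cp)
            self._v[i] = st.v
            self._u[i] = st.u
        H = self.delay_max + 1
        self._ltp_ring = np.zeros((H, n))
        self._ltd_trace = np.zeros(n)
        self._fired_ring = np.zeros((H, n), np.int32)
        self._fired_cnt = np.zeros(H, np.int64)
        self.theta = np.zeros(n)
        self._a_ltp = np.full(n, stdp.a_plus)
        self._a_ltd = np.full(n, stdp.a_minus)

    # -- state access -----------------------------------------------------

    def table(self) -> ConnectionTable:
        """Current synapses in the caller's original connection order."""
        m = self._pre.size
        out = ConnectionTable(
            pre=np.empty(m, np.int32), post=np.empty(m, np.int32),
            delay=np.empty(m, np.int32), weight=np.empty(m),
            derivative=np.empty(m), plastic=np.empty(m, bool),
        )
        out.pre[self._order] = self._pre
        out.post[self._order] = self._post
        out.delay[self._order] = self._delay
        out.weight[self._order] = self._w
        out.derivative[self._order] = self._sd
        out.plastic[self._order] = self._plastic
        return out

    @property
    def weights(self) -> np.ndarray:
        """Weights in original connection order (copy)."""
        w = np.empty(self._w.size)
        w[self._order] = self._w
        return w

    @property
    def derivatives(self) -> np.ndarray:
        sd = np.empty(self._sd.size)
        sd[self._order] = self._sd
        return sd

    def state_dict(self) -> dict:
        """Full dynamic state for exact snapshot/resume."""
        return {
            "t": np.int64(self.t),
            "v": self._v.copy(), "u": self._u.copy(),
            "w": self._w.copy(), "sd": self._sd.copy(),
            "ltp_ring": self._ltp_ring.copy(),
            "ltd_trace": self._ltd_trace.copy(),
            "fired_ring": self._fired_ring.copy(),
            "fired_cnt": self._fired_cnt.copy(),
            "theta": self.theta.copy(),
            "a_ltp": self._a_ltp.copy(), "a_ltd": self._a_ltd.copy(),
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self._v[:] = state["v"]
        self._u[:] = state["u"]
        self._w[:] = state["w"]
        self._sd[:] = state["sd"]
        self._ltp_ring[:] = state["ltp_ring"]
        self._ltd_trace[:] = state["ltd_trace"]
        self._fired_ring[:] = state["fired_ring"]
        self._fired_cnt[:] = state["fired_cnt"]
        self.theta[:] = state["theta"]
        self._a_ltp[:] = state["a_ltp"]
        self._a_ltd[:] = state["a_ltd"]

    def save(self, path) -> None:
        """Binary snapshot of the full network state (exact resume)."""
        np.savez_compressed(path, **self.state_dict())

    def restore(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})

    # -- running ----------------------------------------------------------

    def run(
        self,
        duration_ms: int,
        events: Optional[EventStream] = None,
        plasticity: bool = True,
        metaplasticity: bool = False,
        chunk_ms: int = 1000,
        on_second=None,
    ) -> tuple[SpikeRaster, dict]:
        """Advance the network by ``duration_ms``.

        Event times are relative to the start of this call, as are the times
        in the returned raster.  ``on_second(sim, t_ms)`` is called after
        every completed chunk (default 1 s), for time-series recording.
        Diagnostics include per-chunk excitatory firing rates and threshold
        summaries.
        """
        duration_ms = int(duration_ms)
        if duration_ms < 1:
            raise ValueError("duration must be >= 1 ms")
        if events is None:
            events = EventStream.empty()
        if len(events):
            if events.neurons.min() < 0 or events.neurons.max() >= self.n:
                bad = events.neurons[
                    (events.neurons < 0) | (events.neurons >= self.n)
                ][0]
                raise ValueError(f"unknown neuron id {bad} in input events")
        t_start = self.t
        ev_t = events.times + t_start
        ev_i = int(np.searchsorted(ev_t, t_start, side="left"))
        spike_buf_t = np.empty(self.n * chunk_ms, np.int64)
        spike_buf_n = np.empty(self.n * chunk_ms, np.int32)
        all_t, all_n = [], []
        rates = []
        theta_means = []
        done = 0
        while done < duration_ms:
            ticks = min(chunk_ms, duration_ms - done)
            nspk, ev_i, status, bad_i, bad_t = _advance(
                self._v, self._u, self._a, self._b, self._c, self._d,
                self._pre, self._post, self._delay, self._w, self._sd,
                self._plastic,
                self._blk_ptr, self._aff_ptr, self._aff_idx,
                self._ltp_ring, self._ltd_trace, self._fired_ring,
                self._fired_cnt,
                self.theta, self._a_ltp, self._a_ltd,
                math.exp(-1.0 / self.stdp.tau_plus),
                math.exp(-1.0 / self.stdp.tau_minus),
                self.stdp.ltd_scale,
                self.stdp.a_plus, self.stdp.a_minus,
                self.stdp.drift, self.stdp.decay, self.stdp.update_interval,
                self.meta.r, self.meta.p, self.meta.inertia,
                self.meta.soft_min, self.meta.soft_max, self.w_max,
                plasticity, metaplasticity,
                ev_t, events.neurons, events.kinds, events.values, ev_i,
                self.t, ticks, self.delay_max,
                spike_buf_t, spike_buf_n,
            )
            if status != 0:
                raise SimulationError(
                    f"non-finite membrane state in neuron {bad_i} at t={bad_t} ms"
                )
            all_t.append(spike_buf_t[:nspk].copy())
            all_n.append(spike_buf_n[:nspk].copy())
            self.t += ticks
            done += ticks
            exc_spikes = int((spike_buf_n[:nspk] < self.n_excitatory).sum())
            rate = exc_spikes / self.n_excitatory / (ticks / 1000.0)
            rates.append(rate)
            theta_means.append(float(self.theta.mean()))
            if self.guard_hz is not None:
                total_rate = nspk / self.n / (ticks / 1000.0)
                if total_rate > self.guard_hz:
                    raise RunawayFiringError(
                        f"network rate {total_rate:.1f} Hz exceeded the "
                        f"{self.guard_hz:.1f} Hz guard at t={self.t} ms",
                        diagnostics={
                            "rate_hz": total_rate,
                            "t_ms": self.t,
                            "theta_mean": float(self.theta.mean()),
                            "weight_mean": float(self._w[self._plastic].mean())
                            if self._plastic.any() else 0.0,
                        },
                    )
            if on_second is not None:
                on_second(self, self.t - t_start)
        times = np.concatenate(all_t) - t_start if all_t else np.empty(0, np.int64)
        nrns = np.concatenate(all_n) if all_n else np.empty(0, np.int32)
        raster = SpikeRaster(
            times=times, neurons=nrns,
            n_excitatory=self.n_excitatory, n_inhibitory=self.n_inhibitory,
            duration_ms=duration_ms,
        )
        diagnostics = {
            "rate_hz_exc": rates,
            "theta_mean": theta_means,
            "n_spikes": int(len(raster)),
        }
        return raster, diagnostics


def run(
    table: ConnectionTable,
    events: Optional[EventStream],
    duration_ms: int,
    n_excitatory: int,
    n_inhibitory: int = 0,
    plasticity: bool = True,
    metaplasticity: bool = False,
    stdp: StdpParams = StdpParams(),
    meta: MetaParams = MetaParams(),
    w_max: float = 10.0,
    guard_hz: Optional[float] = 100.0,
    cells: Optional[list[NeuronParams]] = None,
) -> tuple[SpikeRaster, ConnectionTable, dict]:
    """One-shot run: build a fresh simulation, advance it, return results."""
    sim = Simulation(
        table, n_excitatory, n_inhibitory, cells=cells,
        stdp=stdp, meta=meta, w_max=w_max, guard_hz=guard_hz,
    )
    raster, diagnostics = sim.run(
        duration_ms, events, plasticity=plasticity, metaplasticity=metaplasticity
    )
    return raster, sim.table(), diagnostics
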