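"""Fingerprints, PNG size, activation partitioning, census and rates."""

import numpy as np
import pytest

from polychron import (
    ConnectionTable,
    SpikeRaster,
    build_fingerprint,
    firing_rate,
    partition_connections,
    png_size,
    weight_census,
)
from polychron.workbench import generate_fixtures

from conftest import random_small_table


def _raster(times, neurons, n=100, duration=0):
    order = np.argsort(times, kind="stable")
    return SpikeRaster(
        times=np.asarray(times)[order], neurons=np.asarray(neurons)[order],
        n_excitatory=n, n_inhibitory=0, duration_ms=duration,
    )


class TestFingerprint:
    def test_planted_always_firing_neuron(self):
        frames, period = 400, 250
        times = np.arange(frames) * period + 12
        raster = _raster(times, np.full(frames, 7), duration=frames * period)
        fp = build_fingerprint(raster, period, frames, 0.75)
        assert len(fp.entries) == 1
        entry = fp.entries[0]
        assert entry.neuron == 7
        assert entry.window[0] <= 12 <= entry.window[1]
        assert entry.probability == 1.0
        assert png_size(fp) == 1

    def test_below_threshold_excluded(self):
        frames, period = 400, 250
        times = np.arange(0, frames, 2) * period + 12  # 50% of frames
        raster = _raster(times, np.full(times.size, 7), duration=frames * period)
        fp = build_fingerprint(raster, period, frames, 0.75)
        assert png_size(fp) == 0

    def test_background_only_gives_png_size_zero(self):
        """1 Hz Poisson firing cannot hit any window in >= 75% of frames."""
        rng = np.random.default_rng(17)
        frames, period, n = 400, 250, 200
        span = frames * period
        n_ev = rng.poisson(n * 1.0 * span / 1000)
        raster = _raster(
            rng.integers(0, span, n_ev), rng.integers(0, n, n_ev),
            n=n, duration=span,
        )
        fp = build_fingerprint(raster, period, frames, 0.75)
        assert png_size(fp) == 0

    def test_threshold_monotonicity(self):
        fixture = generate_fixtures("planted-png-raster", seed=3)
        sizes = [
            png_size(build_fingerprint(fixture, 250, 400, thr))
            for thr in (0.3, 0.5, 0.75, 0.9, 1.0)
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_planted_chain_recovered_exactly(self):
        fixture = generate_fixtures("planted-png-raster", seed=0)
        fp = build_fingerprint(fixture, 250, 400, 0.75)
        assert fp.neurons == set(range(10))
        assert png_size(fp) == 10

    def test_multi_window_neuron_counted_once(self):
        frames, period = 100, 250
        t1 = np.arange(frames) * period + 12
        t2 = np.arange(frames) * period + 60
        raster = _raster(
            np.concatenate([t1, t2]), np.full(2 * frames, 3),
            duration=frames * period,
        )
        fp = build_fingerprint(raster, period, frames, 0.75)
        assert len(fp.entries) == 2
        assert png_size(fp) == 1
        (w1, w2) = sorted(e.window for e in fp.entries)
        assert w1[1] < w2[0]  # windows disjoint

    def test_zero_frames_faults(self):
        raster = _raster([1], [0])
        with pytest.raises(ValueError):
            build_fingerprint(raster, 250, 0, 0.75)


class TestPartition:
    def _single(self, delay, pre_t, post_t, jitter=2):
        table = ConnectionTable.from_arrays([0], [1], [delay], [5.0], [True])
        raster = _raster([pre_t, post_t], [0, 1], n=2)
        return partition_connections(raster, table, jitter).total_active

    def test_pair_within_jitter_active(self):
        assert self._single(5, 10, 16) == 1  # 5 <= 6 <= 7

    def test_pair_beyond_jitter_inactive(self):
        assert self._single(5, 10, 18) == 0  # 8 > 7

    def test_pair_before_delay_inactive(self):
        assert self._single(5, 10, 14) == 0  # 4 < 5

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        table = random_small_table(rng, n=20, m=80)
        raster = generate_fixtures("toy-raster-for-partition", seed=seed)
        part = partition_connections(raster, table, jitter=2)
        expected = set()
        for s in range(len(table)):
            pre_times = raster.spikes_of(int(table.pre[s]))
            post_times = raster.spikes_of(int(table.post[s]))
            for t1 in pre_times:
                for t2 in post_times:
                    if table.delay[s] <= t2 - t1 <= table.delay[s] + 2:
                        expected.add(s)
        assert set(part.active.tolist()) == expected
        assert part.excitatory_active + part.inhibitory_active == part.total_active


class TestWeightCensus:
    def test_three_way_example(self):
        table = ConnectionTable.from_arrays(
            [0, 1, 2], [3, 3, 3], [1, 1, 1], [0.0, 10.0, 4.3], [True] * 3
        )
        census = weight_census(table, w_max=10.0)
        assert (census.pruned, census.saturated, census.other) == (1, 1, 1)

    def test_initial_network_all_other(self, default_table):
        census = weight_census(default_table)
        assert (census.pruned, census.saturated) == (0, 0)
        assert census.other == census.total == 80_000

    def test_conservation_after_clipping(self, default_table):
        table = default_table.copy()
        rng = np.random.default_rng(0)
        table.weight[table.plastic] = np.clip(
            rng.normal(5, 6, int(table.plastic.sum())), 0.0, 10.0
        )
        census = weight_census(table)
        assert census.total == 80_000
        assert census.pruned > 0 and census.saturated > 0


class TestFiringRate:
    def test_arithmetic(self):
        rng = np.random.default_rng(1)
        times = np.sort(rng.integers(0, 1000, 4800))
        neurons = rng.integers(0, 800, 4800)
        raster = _raster(times, neurons, n=800, duration=1000)
        assert firing_rate(raster, np.arange(800)) == pytest.approx(6.0)

    def test_empty_raster_zero(self):
        raster = SpikeRaster(
            np.empty(0, int), np.empty(0, int),
            n_excitatory=10, n_inhibitory=0, duration_ms=1000,
        )
        assert firing_rate(raster, np.arange(10)) == 0.0

    def test_window_scaling_stationary(self):
        rng = np.random.default_rng(2)
        times = np.sort(rng.integers(0, 10_000, 5000))
        neurons = rng.integers(0, 50, 5000)
        raster = _raster(times, neurons, n=50, duration=10_000)
        full = firing_rate(raster, np.arange(50))
        half = firing_rate(raster, np.arange(50), t_end_ms=5000)
        assert half == pytest.approx(full, rel=0.1)

    def test_empty_population_faults(self):
        raster = _raster([1], [0])
        with pytest.raises(ValueError):
            firing_rate(raster, [])
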