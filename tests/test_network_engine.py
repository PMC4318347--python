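"""Topology construction and the simulation engine's contracts."""

import numpy as np
import pytest

from polychron import (
    ConnectionTable,
    EventStream,
    MetaParams,
    NetworkConfig,
    RunawayFiringError,
    Simulation,
    build_network,
    poisson_background,
)
from polychron.neurons import RS, rest_state, step_neuron

from conftest import random_small_table


class TestBuildNetwork:
    def test_default_population_and_counts(self, default_table):
        assert len(default_table) == 100_000
        assert int(default_table.plastic.sum()) == 80_000
        exc = default_table.pre < 800
        assert np.array_equal(exc, default_table.plastic)

    def test_delay_rules(self, default_table):
        exc = default_table.pre < 800
        assert default_table.delay[exc].min() >= 1
        assert default_table.delay[exc].max() <= 20
        assert np.all(default_table.delay[~exc] == 1)

    def test_inhibitory_targets_excitatory_only(self, default_table):
        inh = default_table.pre >= 800
        assert default_table.post[inh].max() < 800

    def test_initial_weights(self, default_table):
        exc = default_table.plastic
        assert np.all(default_table.weight[exc] == 3.0)
        assert np.all(default_table.weight[~exc] == -2.0)

    def test_fan_out_no_self_no_duplicates(self, toy_table, toy_config):
        for j in range(toy_config.n_neurons):
            out = toy_table.post[toy_table.pre == j]
            assert out.size == toy_config.fan_out
            assert j not in out
            assert np.unique(out).size == out.size  # no duplicate (pre, post)

    def test_same_seed_identical(self, toy_config):
        a = build_network(toy_config)
        b = build_network(toy_config)
        for field in ("pre", "post", "delay", "weight", "plastic"):
            assert np.array_equal(getattr(a, field), getattr(b, field))

    def test_infeasible_fan_out_faults(self):
        with pytest.raises(ValueError):
            NetworkConfig(n_neurons=100, n_excitatory=20, fan_out=50)


def brute_force_run(table, cells, events, duration):
    """Reference event-queue simulation built on the scalar neuron stepper."""
    n = len(cells)
    states = [rest_state(c) for c in cells]
    arrivals: dict[tuple[int, int], float] = {}
    pulses: dict[tuple[int, int], float] = {}
    forced: set[tuple[int, int]] = set()
    for t, i, k, val in zip(events.times, events.neurons, events.kinds, events.values):
        if k == 0:
            pulses[(int(t), int(i))] = pulses.get((int(t), int(i)), 0.0) + val
        else:
            forced.add((int(t), int(i)))
    spikes = []
    for t in range(duration):
        fired_now = []
        for i in range(n):
            if (t, i) in forced:
                states[i].v = cells[i].c
                states[i].u = states[i].u + cells[i].d
                fired_now.append(i)
                continue
            drive = arrivals.pop((t, i), 0.0) + pulses.get((t, i), 0.0)
            states[i], fired = step_neuron(states[i], cells[i], drive)
            if fired:
                fired_now.append(i)
        for i in fired_now:
            spikes.append((t, i))
            sel = table.pre == i
            for post, delay, weight in zip(
                table.post[sel], table.delay[sel], table.weight[sel]
            ):
                key = (t + int(delay), int(post))
                arrivals[key] = arrivals.get(key, 0.0) + float(weight)
    return spikes


class TestEngineContracts:
    def test_delay_contract_single_connection(self):
        table = ConnectionTable.from_arrays([0], [1], [7], [20.0], [True])
        sim = Simulation(table, n_excitatory=2, guard_hz=None)
        raster, _ = sim.run(50, EventStream.forced([10], [0]), plasticity=False)
        events = list(zip(raster.times.tolist(), raster.neurons.tolist()))
        assert (10, 0) in events
        post_spikes = [t for t, i in events if i == 1]
        # 20 mV arrives at t=17; the post cell fires a few ms later
        assert post_spikes and 17 <= post_spikes[0] <= 25

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_matches_brute_force_event_queue(self, seed):
        """Spike-for-spike agreement with a per-event reference simulator on
        random 10-cell circuits (plasticity off)."""
        rng = np.random.default_rng(seed)
        table = random_small_table(rng)
        cells = [RS] * 10
        ev_t = rng.integers(0, 200, 40)
        ev_n = rng.integers(0, 10, 40)
        events = EventStream.pulses(ev_t, ev_n, 20.0)
        sim = Simulation(table, n_excitatory=10, guard_hz=None)
        raster, _ = sim.run(300, events, plasticity=False)
        got = list(zip(raster.times.tolist(), raster.neurons.tolist()))
        expected = brute_force_run(table, cells, events, 300)
        assert sorted(got) == sorted(expected)

    def test_no_input_is_silent(self, toy_table):
        sim = Simulation(toy_table, n_excitatory=16, n_inhibitory=4, guard_hz=None)
        raster, _ = sim.run(1000, None, plasticity=False)
        assert len(raster) == 0

    def test_plasticity_off_preserves_weights(self, toy_table):
        sim = Simulation(toy_table, n_excitatory=16, n_inhibitory=4, guard_hz=None)
        before = sim.weights.copy()
        events = poisson_background(20.0, 20, 2000, 9)
        sim.run(2000, events, plasticity=False)
        assert np.array_equal(sim.weights, before)

    def test_raster_counts_consistent(self, toy_table):
        sim = Simulation(toy_table, n_excitatory=16, n_inhibitory=4, guard_hz=None)
        events = poisson_background(20.0, 20, 2000, 10)
        raster, diag = sim.run(2000, events, plasticity=False)
        per_neuron = sum(raster.spikes_of(i).size for i in range(20))
        assert per_neuron == len(raster) == diag["n_spikes"]

    def test_determinism(self, toy_table):
        events = poisson_background(10.0, 20, 1500, 11)
        rasters = []
        for _ in range(2):
            sim = Simulation(toy_table, n_excitatory=16, n_inhibitory=4, guard_hz=None)
            raster, _ = sim.run(1500, events, plasticity=True)
            rasters.append(raster)
        assert np.array_equal(rasters[0].times, rasters[1].times)
        assert np.array_equal(rasters[0].neurons, rasters[1].neurons)

    def test_unknown_neuron_id_faults(self, toy_table):
        sim = Simulation(toy_table, n_excitatory=16, n_inhibitory=4)
        with pytest.raises(ValueError, match="unknown neuron"):
            sim.run(100, EventStream.forced([5], [99]))

    def test_runaway_guard_trips(self):
        # all-to-all strong excitation with continuous forcing
        n = 10
        pre, post = np.meshgrid(np.arange(n), np.arange(n))
        mask = pre.ravel() != post.ravel()
        table = ConnectionTable.from_arrays(
            pre.ravel()[mask], post.ravel()[mask],
            np.ones(mask.sum(), int), np.full(mask.sum(), 30.0),
            np.ones(mask.sum(), bool),
        )
        sim = Simulation(table, n_excitatory=n, guard_hz=50.0)
        times = np.repeat(np.arange(0, 1000, 2), n)
        neurons = np.tile(np.arange(n), 500)
        with pytest.raises(RunawayFiringError) as exc:
            sim.run(1000, EventStream.forced(times, neurons), plasticity=False)
        assert "rate_hz" in exc.value.diagnostics


class TestSnapshotResume:
    def test_resume_is_bit_exact(self, toy_table, tmp_path):
        events = poisson_background(10.0, 20, 4000, 21)

        sim1 = Simulation(toy_table, n_excitatory=16, n_inhibitory=4, guard_hz=None)
        r1, _ = sim1.run(4000, events, plasticity=True)

        sim2 = Simulation(toy_table, n_excitatory=16, n_inhibitory=4, guard_hz=None)
        first = EventStream(
            events.times[events.times < 2000], events.neurons[events.times < 2000],
            events.kinds[events.times < 2000], events.values[events.times < 2000],
        )
        second = EventStream(
            events.times[events.times >= 2000] - 2000,
            events.neurons[events.times >= 2000],
            events.kinds[events.times >= 2000],
            events.values[events.times >= 2000],
        )
        ra, _ = sim2.run(2000, first, plasticity=True)
        path = tmp_path / "snap.npz"
        sim2.save(path)
        sim3 = Simulation(toy_table, n_excitatory=16, n_inhibitory=4, guard_hz=None)
        sim3.restore(path)
        rb, _ = sim3.run(2000, second, plasticity=True)

        merged_times = np.concatenate([ra.times, rb.times + 2000])
        merged_neurons = np.concatenate([ra.neurons, rb.neurons])
        assert np.array_equal(merged_times, r1.times)
        assert np.array_equal(merged_neurons, r1.neurons)
        assert np.array_equal(sim3.weights, sim1.weights)
        assert np.array_equal(sim3.derivatives, sim1.derivatives)


class TestMetaplasticityNeutrality:
    def test_r_zero_reproduces_disabled_trajectory_bitwise(self, toy_table):
        """With r = 0 the weighting function vanishes, the threshold stays
        0 and the run is bit-identical to metaplasticity disabled."""
        events = poisson_background(15.0, 20, 3000, 31)
        runs = {}
        for meta_on, r in ((True, 0.0), (False, 0.1)):
            sim = Simulation(
                toy_table, n_excitatory=16, n_inhibitory=4,
                meta=MetaParams(r=r), guard_hz=None,
            )
            raster, _ = sim.run(3000, events, plasticity=True, metaplasticity=meta_on)
            runs[meta_on] = (raster, sim.weights, sim.derivatives, sim.theta.copy())
        r_on, w_on, sd_on, th_on = runs[True]
        r_off, w_off, sd_off, _ = runs[False]
        assert np.array_equal(r_on.times, r_off.times)
        assert np.array_equal(r_on.neurons, r_off.neurons)
        assert np.array_equal(w_on, w_off)
        assert np.array_equal(sd_on, sd_off)
        assert np.all(th_on == 0.0)
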