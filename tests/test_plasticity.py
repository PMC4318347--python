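"""STDP pairing rules, derivative accumulation and the per-second update.

The engine's accumulated derivative is checked against an offline oracle
that sums over all (pre-arrival, post-spike) nearest-event pairs directly.
"""

import math

import numpy as np
import pytest

from polychron import ConnectionTable, EventStream, Simulation
from polychron.plasticity import (
    StdpParams,
    ltd_decrement,
    ltp_increment,
    update_weights,
)


class TestClosedFormIncrements:
    def test_ltp_five_ms_lead(self):
        assert ltp_increment(5.0, 0.1, 20.0) == pytest.approx(0.1 * math.exp(-0.25))

    def test_ltd_one_ms_lag(self):
        assert ltd_decrement(1.0, 0.12, 20.0) == pytest.approx(0.12 * math.exp(-1 / 20))

    def test_ltd_reference_scale(self):
        # the platform's depression step applies 1.2x the LTD trace
        assert ltd_decrement(1.0, 0.12, 20.0, ltd_scale=1.2) == pytest.approx(
            1.2 * 0.12 * math.exp(-1 / 20)
        )

    def test_no_pre_activity_means_zero(self):
        assert ltp_increment(-3.0, 0.1, 20.0) == 0.0
        assert ltd_decrement(0.0, 0.12, 20.0) == 0.0


class TestUpdateWeights:
    def _table(self, weights, plastic=None):
        m = len(weights)
        plastic = [True] * m if plastic is None else plastic
        return ConnectionTable.from_arrays(
            list(range(m)), [m] * m, [1] * m, weights, plastic
        )

    def test_drift_only(self):
        t = self._table([5.0])
        update_weights(t, StdpParams(drift=0.01))
        assert t.weight[0] == pytest.approx(5.01)

    def test_clip_to_cap(self):
        t = self._table([9.99])
        t.derivative[:] = 5.0
        update_weights(t, StdpParams())
        assert t.weight[0] == 10.0

    def test_clip_to_zero_prunes(self):
        t = self._table([0.005])
        t.derivative[:] = -5.0
        update_weights(t, StdpParams())
        assert t.weight[0] == 0.0

    def test_derivative_decays(self):
        t = self._table([5.0])
        t.derivative[:] = 2.0
        update_weights(t, StdpParams(decay=0.9))
        assert t.derivative[0] == pytest.approx(1.8)

    def test_non_plastic_untouched(self):
        t = self._table([5.0, -2.0], plastic=[True, False])
        t.derivative[:] = 1.0
        update_weights(t, StdpParams())
        assert t.weight[1] == -2.0
        assert t.derivative[1] == 1.0


def _scripted_run(pre_times, post_times, delay, duration=900, stdp=StdpParams()):
    """Two cells, one plastic synapse; both cells forced on script."""
    table = ConnectionTable.from_arrays([0], [1], [delay], [5.0], [True])
    sim = Simulation(table, n_excitatory=2, stdp=stdp, guard_hz=None)
    times = np.concatenate([pre_times, post_times])
    neurons = np.concatenate(
        [np.zeros(len(pre_times), int), np.ones(len(post_times), int)]
    )
    sim.run(duration, EventStream.forced(times, neurons), plasticity=True)
    return sim.derivatives[0]


def _pair_sum_oracle(pre_times, post_times, delay, stdp=StdpParams()):
    """Direct nearest-event pair sum over arrival/post-spike times."""
    arrivals = sorted(t + delay for t in pre_times)
    posts = sorted(post_times)
    sd = 0.0
    # LTP: each post spike pairs with the latest arrival at or before it
    for t2 in posts:
        earlier = [a for a in arrivals if a <= t2]
        if earlier:
            sd += stdp.a_plus * math.exp(-(t2 - earlier[-1]) / stdp.tau_plus)
    # LTD: each arrival pairs with the latest post spike strictly before it
    for a in arrivals:
        earlier = [t2 for t2 in posts if t2 < a]
        if earlier:
            sd -= stdp.ltd_scale * stdp.a_minus * math.exp(
                -(a - earlier[-1]) / stdp.tau_minus
            )
    return sd


class TestDerivativeOracle:
    def test_single_causal_pair(self):
        # arrival at 101, post at 106: pure LTP at dt=5
        sd = _scripted_run([100], [106], delay=1)
        assert sd == pytest.approx(0.1 * math.exp(-5 / 20), rel=1e-12)

    def test_single_acausal_pair_baseline(self):
        # post at 100, arrival at 101: pure LTD at dt=1, amplitude A- exactly
        sd = _scripted_run([100], [100], delay=1, stdp=StdpParams(ltd_scale=1.0))
        assert sd == pytest.approx(-0.12 * math.exp(-1 / 20), rel=1e-12)

    def test_single_acausal_pair_with_reference_scale(self):
        sd = _scripted_run([100], [100], delay=1)
        assert sd == pytest.approx(-1.2 * 0.12 * math.exp(-1 / 20), rel=1e-12)

    def test_simultaneous_arrival_counts_as_potentiation(self):
        # arrival and post spike on the same tick: dt=0 -> full LTP, no LTD
        sd = _scripted_run([100], [103], delay=3)
        assert sd == pytest.approx(0.1, rel=1e-12)

    def test_far_apart_events_nearly_independent(self):
        # the second pairing repeats the first; cross-pair tails are below 1e-9
        sd = _scripted_run([100, 500], [106, 506], delay=1)
        assert sd == pytest.approx(2 * 0.1 * math.exp(-5 / 20), abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_script_matches_pair_sum(self, seed):
        rng = np.random.default_rng(seed)
        pre = np.unique(rng.integers(0, 880, 25))
        post = np.unique(rng.integers(0, 880, 25))
        delay = int(rng.integers(1, 21))
        sd = _scripted_run(pre, post, delay)
        assert sd == pytest.approx(_pair_sum_oracle(pre, post, delay), rel=1e-9)

    def test_zero_amplitude_leaves_only_drift(self):
        """With vanishing amplitudes the derivative stays 0 and weights move
        by drift alone."""
        stdp = StdpParams(a_plus=1e-300, a_minus=1e-300, drift=0.01)
        table = ConnectionTable.from_arrays([0], [1], [1], [5.0], [True])
        sim = Simulation(table, n_excitatory=2, stdp=stdp, guard_hz=None)
        times = np.arange(0, 3000, 100)
        neurons = np.tile([0, 1], times.size // 2)
        sim.run(3000, EventStream.forced(times, neurons), plasticity=True)
        assert sim.derivatives[0] == pytest.approx(0.0, abs=1e-290)
        assert sim.weights[0] == pytest.approx(5.03, rel=1e-9)
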