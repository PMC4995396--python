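import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from sdssa import Channel, DelayQueue, System, ensemble_mean, run
from sdssa.sd_ssa import (SystemState, constant_delay, draw_waiting,
                          mass_action, michaelis_menten, propensities,
                          schedule_initial_imaginary, state_dependent_delay,
                          step, time_varying)


def decay_system(k=1.0, x0=10):
    """Plain one-species decay, no delays."""
    return System(species=("X",), initial={"X": x0},
                  channels=[Channel(name="decay",
                                    propensity=mass_action(k, "X"),
                                    nu={"X": -1})])


def delayed_birth_system(rate=2.0, tau=3.0):
    return System(
        species=("I", "P"), initial={},
        channels=[Channel(name="birth", propensity=mass_action(rate, None),
                          nu={"I": +1}, u={"I": -1, "P": +1},
                          delay=constant_delay(tau), imaginary="I")])


class TestDelayQueue:
    @given(st.lists(st.floats(0.0, 1e6), min_size=1, max_size=50))
    @settings(max_examples=60, derandomize=True)
    def test_pops_in_time_order(self, times):
        q = DelayQueue()
        for i, t in enumerate(times):
            q.push(t, i % 3)
        assert q.delta_min == min(times)
        popped = [q.pop()[0] for _ in range(len(times))]
        assert popped == sorted(times)

    def test_empty_queue_sentinel(self):
        assert DelayQueue().delta_min == math.inf


class TestChannelValidation:
    def test_delayed_channel_needs_imaginary(self):
        with pytest.raises(ValueError, match="imaginary"):
            Channel(name="bad", propensity=mass_action(1.0, "X"),
                    nu={"X": -1}, u={"P": +1}, delay=constant_delay(1.0))

    def test_stoichiometry_must_route_through_imaginary(self):
        with pytest.raises(ValueError, match="imaginary"):
            Channel(name="bad", propensity=mass_action(1.0, "X"),
                    nu={"X": -1}, u={"P": +1}, delay=constant_delay(1.0),
                    imaginary="I")

    def test_plain_channel_cannot_manifest(self):
        with pytest.raises(ValueError, match="manifesting"):
            Channel(name="bad", propensity=mass_action(1.0, "X"),
                    nu={"X": -1}, u={"P": +1})

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError, match="unknown species"):
            System(species=("X",), initial={},
                   channels=[Channel(name="c", propensity=mass_action(1, "X"),
                                     nu={"Y": -1})])


class TestPropensities:
    def test_empty_state_gives_zeros(self):
        system = decay_system(x0=0)
        a, a0 = propensities(SystemState(system.initial_counts()),
                             system.channels, system)
        assert a0 == 0.0 and np.all(a == 0.0)

    def test_first_order(self):
        system = decay_system(k=0.5, x0=10)
        _, a0 = propensities(SystemState(system.initial_counts()),
                             system.channels, system)
        assert a0 == pytest.approx(5.0)

    def test_michaelis_menten_rate_value(self):
        system = System(species=("E1",), initial={"E1": 100},
                        channels=[Channel(name="mm",
                                          propensity=michaelis_menten(
                                              37.07, 23859200.0, "E1"),
                                          nu={"E1": -1})])
        _, a0 = propensities(SystemState(system.initial_counts()),
                             system.channels, system)
        assert a0 == pytest.approx(1.5537e-4, rel=1e-3)

    def test_time_varying_evaluated_at_t(self):
        system = System(species=("X",), initial={},
                        channels=[Channel(name="tv",
                                          propensity=time_varying(lambda t: 2 * t),
                                          nu={"X": +1})])
        _, a0 = propensities(SystemState(system.initial_counts(), 3.0),
                             system.channels, system)
        assert a0 == pytest.approx(6.0)


class _StubRng:
    """Deterministic stand-in exposing the Generator surface used."""

    def __init__(self, uniforms):
        self._u = list(uniforms)

    def random(self):
        return self._u.pop(0)


class TestDrawWaiting:
    def test_inverse_transform(self):
        assert draw_waiting(1.0, _StubRng([1 / math.e])) == pytest.approx(1.0)

    def test_zero_total_propensity(self):
        assert draw_waiting(0.0, _StubRng([0.5])) == math.inf

    def test_exponential_moment(self, rng):
        mu = np.array([draw_waiting(2.0, rng) for _ in range(10000)])
        se = mu.std(ddof=1) / np.sqrt(len(mu))
        assert abs(mu.mean() - 0.5) < 3 * se


class TestStepSemantics:
    def test_reduces_to_plain_ssa_without_delays(self):
        # first-event time of a pure-decay system is Exp(k*x0)
        k, x0 = 1.0, 10
        rng = np.random.default_rng(7)
        firsts = []
        for _ in range(3000):
            traj = run(decay_system(k, x0), 5.0, rng)
            firsts.append(traj.times[1])
        res = stats.kstest(firsts, "expon", args=(0, 1 / (k * x0)))
        assert res.pvalue > 0.01

    def test_constant_delay_manifests_exactly_tau_later(self):
        system = delayed_birth_system(rate=2.0, tau=3.0)
        traj = run(system, 20.0, seed=1)
        births = traj.times[np.diff(traj.column("I"), prepend=0.0) > 0]
        arrivals = traj.times[np.diff(traj.column("P"), prepend=0.0) > 0]
        resolved = births[births + 3.0 <= 20.0]
        assert np.allclose(np.sort(resolved + 3.0), arrivals[: len(resolved)])

    def test_negative_count_is_invariant_breach(self):
        bad = System(species=("X",), initial={"X": 0},
                     channels=[Channel(name="c",
                                       propensity=mass_action(1.0, None),
                                       nu={"X": -1})])
        with pytest.raises(RuntimeError, match="negative count"):
            run(bad, 10.0, seed=0)


class TestRun:
    def test_zero_horizon_returns_initial_state(self):
        traj = run(decay_system(), 0.0, seed=0)
        assert len(traj.times) == 1
        assert traj.counts[0, 0] == 10

    def test_bit_identical_under_seed(self):
        a = run(delayed_birth_system(), 30.0, seed=5)
        b = run(delayed_birth_system(), 30.0, seed=5)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.counts, b.counts)

    def test_queue_species_invariant_maintained(self):
        from sdssa import build_rpl30
        system = build_rpl30(s0=40, y0=10)
        rng = np.random.default_rng(3)
        state = SystemState(system.initial_counts(), 0.0)
        queue = DelayQueue()
        idx = {c.name: j for j, c in enumerate(system.channels)}
        for name, count, window in system.preload:
            schedule_initial_imaginary(count, window, idx[name], rng, queue)
            state.counts[system.index[system.channels[idx[name]].imaginary]] += count
        for _ in range(150):
            if not step(state, queue, system, rng):
                break
            system.validate(state, queue)

    def test_conservation_in_reduced_decay(self):
        from sdssa import build_rpl30
        traj = run(build_rpl30(s0=30, y0=5), 200.0, seed=9)
        assert np.allclose(traj.counts.sum(axis=1), 30.0)

    def test_ensemble_mean_reports_standard_errors(self):
        mean = ensemble_mean(decay_system(), 3.0, np.linspace(0, 3, 7),
                             reps=50, seed=2)
        assert mean.se is not None and mean.se.shape == mean.counts.shape
        assert np.all(mean.se[1:, 0] > 0)
        assert np.all(np.diff(mean.counts[:, 0]) <= 0)


class TestScheduleInitialImaginary:
    def test_zero_count_leaves_queue_empty(self, rng):
        q = DelayQueue()
        schedule_initial_imaginary(0, 5.0, 0, rng, q)
        assert len(q) == 0

    def test_all_times_within_window(self, rng):
        q = DelayQueue()
        times = schedule_initial_imaginary(200, 7.5, 1, rng, q)
        assert len(q) == 200
        assert np.all((times >= 0) & (times <= 7.5))
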