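"""Stochastic engine: acceptance draws, waiting times, steps, schedules."""

import math

import numpy as np
import pytest

from admarkov import (
    AbsorbedStateError,
    ModelOptions,
    ParameterSet,
    StateVector,
    StochasticConfig,
    VARIABLES,
    channel_rates,
    draw_acceptance,
    draw_waiting_times,
    make_jump_schedule,
    simulate,
    step,
)
from admarkov.deterministic import euler_path
from conftest import random_states


class TestAcceptanceDraw:
    def test_zero_noise_returns_the_mean(self, rng):
        cfg = StochasticConfig(sigma=0.0)
        assert draw_acceptance(0.3, cfg, rng) == 0.3

    def test_probabilities_clip_to_unit_interval(self, rng):
        cfg = StochasticConfig(sigma=0.0)
        assert draw_acceptance(1.5, cfg, rng) == 1.0
        cfg = StochasticConfig(sigma=0.5)
        draws = [draw_acceptance(0.5, cfg, rng) for _ in range(2000)]
        assert all(0.0 <= d <= 1.0 for d in draws)

    def test_sample_mean_matches_the_relative_propensity(self, rng):
        cfg = StochasticConfig(sigma=0.1)
        n = 100_000
        draws = np.array([draw_acceptance(0.3, cfg, rng) for _ in range(n)])
        se = 0.1 / math.sqrt(n)
        # clipping at 0/1 is 3 sigma away, so its bias is well under 3 SE
        assert abs(draws.mean() - 0.3) < 3 * se + 5e-4

    def test_force_fire_always_accepts(self, rng):
        cfg = StochasticConfig(force_fire=True, sigma=0.3)
        assert draw_acceptance(0.01, cfg, rng) == 1.0

    def test_relative_noise_silences_zero_mean_channels(self, rng):
        cfg = StochasticConfig(sigma=0.1, relative_noise=True)
        assert draw_acceptance(0.0, cfg, rng) == 0.0

    def test_negative_mean_rejected(self, rng):
        with pytest.raises(ValueError):
            draw_acceptance(-0.1, StochasticConfig(), rng)


@pytest.fixture(scope="module")
def single_channel_state(params, opts):
    # only intraneuronal tangles present and no neurons: the sole active
    # channel is the F_i -> F_o emigration feeding F_o's birth
    state = StateVector.from_array(
        np.array([0, 0, 0, 0, 1e-9, 0, 0, 0, 0], dtype=float)
    )
    ch = channel_rates(state, params, opts)
    assert (ch.total() > 0).sum() == 1
    return state


class TestWaitingTimes:
    def test_single_active_channel_waits_average_one_step_scale(
        self, single_channel_state, params, opts, rng
    ):
        cfg = StochasticConfig(step_scale=1.0)
        ch = channel_rates(single_channel_state, params, opts)
        waits = np.array(
            [draw_waiting_times(ch, cfg, rng)[VARIABLES.index("F_o")]
             for _ in range(10_000)]
        )
        assert waits.mean() == pytest.approx(1.0, rel=0.05)

    def test_inactive_variables_wait_forever(
        self, single_channel_state, params, opts, rng
    ):
        ch = channel_rates(single_channel_state, params, opts)
        waits = draw_waiting_times(ch, StochasticConfig(), rng)
        active = VARIABLES.index("F_o")
        assert np.isfinite(waits[active])
        assert np.all(np.isinf(np.delete(waits, active)))

    def test_fixed_dt_overrides_every_active_wait(self, initial, params, opts, rng):
        ch = channel_rates(initial, params, opts)
        waits = draw_waiting_times(ch, StochasticConfig(fixed_dt=0.5), rng)
        assert np.all(waits[ch.total() > 0] == 0.5)

    def test_all_rates_zero_signals_absorption(self, params, opts, rng):
        ch = channel_rates(np.zeros(9), params, opts)
        with pytest.raises(AbsorbedStateError):
            draw_waiting_times(ch, StochasticConfig(), rng)


class TestStep:
    def test_forced_step_equals_one_euler_step(self, initial, params, opts, rng):
        cfg = StochasticConfig(force_fire=True, fixed_dt=1.0)
        new, elapsed, fired = step(initial, 0.0, params, opts, cfg, rng)
        assert elapsed == 1.0
        assert new.N == pytest.approx(0.14 - 2.38e-5, rel=1e-12)
        assert new.N == pytest.approx(0.1399762, rel=1e-10)
        oracle = euler_path(initial.as_array(), params, opts, np.array([1.0]))[-1]
        np.testing.assert_allclose(new.as_array(), oracle, rtol=1e-15)
        assert all(fired.values())  # every species is active at onset

    def test_absorbed_state_is_returned_unchanged(self, params, opts, rng):
        zero = StateVector.from_array(np.zeros(9))
        new, elapsed, fired = step(
            zero, 0.0, params, opts, StochasticConfig(), rng, max_dt=123.0
        )
        assert new == zero
        assert elapsed == 123.0
        assert not any(fired.values())

    def test_outputs_are_always_non_negative(self, params, opts, rng):
        cfg = StochasticConfig(step_scale=0.5, sigma=0.3)
        for x in random_states(100, seed=42):
            new, _, _ = step(
                StateVector.from_array(x), 0.0, params, opts, cfg, rng
            )
            assert np.all(new.as_array() >= 0)

    def test_acceptance_means_partition_unity(self, initial, params, opts):
        """Channel propensity means sum to 1 at any instant, under every
        coupling policy (they partition the total event rate)."""
        ch = channel_rates(initial, params, opts)
        tot = ch.total().sum()
        for policy in ("emigration", "all", "none"):
            mask = StochasticConfig(coupling=policy).coupled_mask
            means = []
            for j in range(9):
                if mask[j]:
                    means.append(ch.total()[j] / tot)
                else:
                    means.extend([ch.birth[j] / tot, ch.death[j] / tot])
            assert sum(means) == pytest.approx(1.0, rel=1e-12)


class TestSimulate:
    def test_degenerate_limit_reproduces_euler_over_100_steps(
        self, initial, params, opts
    ):
        cfg = StochasticConfig(force_fire=True, fixed_dt=1.0, seed=3)
        traj = simulate(initial, params, opts, cfg, horizon_days=100.0)
        oracle = euler_path(initial.as_array(), params, opts, np.full(100, 1.0))
        assert len(traj) == 101
        scale = np.maximum(np.abs(oracle), 1e-300)
        assert np.max(np.abs(traj.states - oracle) / scale) < 1e-12

    def test_same_seed_gives_bit_identical_trajectories(self, initial, params, opts):
        cfg = StochasticConfig(seed=7)
        a = simulate(initial, params, opts, cfg, horizon_days=30.0)
        b = simulate(initial, params, opts, cfg, horizon_days=30.0)
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_array_equal(a.states, b.states)

    def test_neurons_only_lose_mass(self, initial, params, opts):
        traj = simulate(
            initial, params, opts, StochasticConfig(seed=1), horizon_days=100.0
        )
        n = traj.variable("N")
        assert np.all(np.diff(n) <= 0)
        assert traj.final.N < initial.N

    def test_states_remain_non_negative_and_grid_increases(
        self, initial, params, opts
    ):
        traj = simulate(
            initial, params, opts, StochasticConfig(seed=9, sigma=0.3),
            horizon_days=60.0,
        )
        assert np.all(traj.states >= 0)
        assert np.all(np.diff(traj.times) > 0)
        assert traj.times[-1] == pytest.approx(60.0)


class TestJumpSchedule:
    def test_fixed_dt_gives_the_exact_unit_grid(self, params, opts):
        sched = make_jump_schedule(
            params, opts, StochasticConfig(fixed_dt=1.0), 3650.0, seed=1
        )
        assert len(sched) == 3650
        assert np.all(sched.increments == 1.0)

    def test_increments_cover_the_horizon(self, params, opts):
        sched = make_jump_schedule(params, opts, StochasticConfig(), 100.0, seed=5)
        assert np.all(sched.increments > 0)
        assert sched.total >= 100.0

    def test_same_seed_same_schedule(self, params, opts):
        a = make_jump_schedule(params, opts, StochasticConfig(), 50.0, seed=11)
        b = make_jump_schedule(params, opts, StochasticConfig(), 50.0, seed=11)
        np.testing.assert_array_equal(a.increments, b.increments)

    def test_matched_replicates_share_the_grid_but_not_the_noise(
        self, initial, params, opts
    ):
        sched = make_jump_schedule(params, opts, StochasticConfig(), 40.0, seed=2)
        a = simulate(initial, params, opts, StochasticConfig(seed=3), 40.0, sched)
        b = simulate(initial, params, opts, StochasticConfig(seed=4), 40.0, sched)
        np.testing.assert_array_equal(a.times, b.times)
        assert not np.array_equal(a.states, b.states)
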