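"""Reward filtering, tracking-cost adaptation and the deliberation cost."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgd.filters import (
    FilterState,
    advance,
    deliberation_cost,
    effective_tau,
    stepwise_update,
    trial_update,
)


class TestStepwiseUpdate:
    def test_arithmetic(self):
        assert stepwise_update(0.1, 0.3, tau=1.0) == pytest.approx(0.2)

    def test_limits(self):
        assert stepwise_update(0.1, 5.0, tau=1e12) == pytest.approx(0.1)
        assert stepwise_update(0.1, 5.0, tau=0.0) == 5.0


class TestTrialUpdate:
    def test_arithmetic(self):
        # beta = 1/2, T = 2: 0.25 * 0.1 + 0.75 * 0.3
        assert trial_update(0.1, 0.6, duration=2, tau=1.0) == pytest.approx(0.25)

    def test_fixed_point(self):
        est = 0.0
        for _ in range(2000):
            est = trial_update(est, 0.6, duration=3.0, tau=20.0)
        assert est == pytest.approx(0.2, rel=1e-9)

    @given(
        tau=st.floats(0.5, 500.0),
        duration=st.integers(1, 40),
        reward=st.floats(-2.0, 2.0),
        start=st.floats(-1.0, 1.0),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_equals_repeated_stepwise_updates(self, tau, duration, reward, start):
        """The cumulative update is exactly T step-wise updates of R/T."""
        cumulative = trial_update(start, reward, duration, tau)
        stepped = start
        for _ in range(duration):
            stepped = stepwise_update(stepped, reward / duration, tau)
        assert cumulative == pytest.approx(stepped, abs=1e-12)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            trial_update(0.1, 0.3, duration=0, tau=1.0)


class TestEffectiveTau:
    def test_matched_timescales_halve_tau(self):
        for nu in (0.5, 1.0, 4.0):
            assert effective_tau(100.0, 10.0, 10.0, nu) == pytest.approx(50.0)

    def test_vanishing_tracking_cost(self):
        assert effective_tau(100.0, 1e-9, 10.0, 2.0) == pytest.approx(100.0)

    def test_switch_asymmetry_at_high_sensitivity(self):
        # entering a slower environment (T_sys > T_track) shrinks tau more
        fast_to_slow = effective_tau(100.0, t_sys=20.0, t_track=10.0, nu=4.0)
        slow_to_fast = effective_tau(100.0, t_sys=10.0, t_track=20.0, nu=4.0)
        assert fast_to_slow < slow_to_fast

    def test_bounds(self):
        for q in (0.1, 1.0, 10.0):
            tau = effective_tau(100.0, q, 1.0, 2.0)
            assert 0.0 < tau <= 100.0


class TestAdvance:
    def test_first_trial_seeds_with_sample(self):
        state = advance(FilterState(), reward=0.8, duration=16.0)
        assert state.rho_long == pytest.approx(0.05)
        assert state.rho_context == pytest.approx(0.05)
        assert state.t_track == pytest.approx(16.0)

    def test_stationary_fixed_point(self):
        state = FilterState(tau_long=200.0, tau_context_base=50.0)
        for _ in range(5000):
            state = advance(state, reward=0.8, duration=16.0)
        assert state.rho_long == pytest.approx(0.05, rel=1e-6)
        assert state.rho_context == pytest.approx(0.05, rel=1e-6)
        assert state.offset == pytest.approx(0.0, abs=1e-8)

    def test_reward_scale_linearity(self):
        s1 = FilterState(K=1.0)
        s2 = FilterState(K=2.0)
        for r, d in [(0.6, 12.0), (0.9, 20.0), (0.4, 9.5)]:
            s1 = advance(s1, r, d)
            s2 = advance(s2, r, d)
        assert s2.rho_long == pytest.approx(2 * s1.rho_long)
        assert s2.rho_context == pytest.approx(2 * s1.rho_context)

    def test_offset_identity(self):
        state = FilterState()
        for r, d in [(0.6, 12.0), (0.9, 20.0)]:
            state = advance(state, r, d)
        assert state.offset == pytest.approx(
            (state.rho_context - state.rho_long) * 20.0
        )


class TestDeliberationCost:
    def test_modes(self):
        state = FilterState(rho_long=0.04, rho_context=0.06, offset=0.4, n_trials=5)
        assert deliberation_cost(state, 10, "trial_aware") == pytest.approx(0.8)
        assert deliberation_cost(state, 10, "trial_unaware") == pytest.approx(0.6)
        assert deliberation_cost(state, 10, "stationary") == pytest.approx(0.4)

    def test_reduces_to_stationary_when_contexts_agree(self):
        state = FilterState(rho_long=0.05, rho_context=0.05, offset=0.0)
        for t in range(16):
            assert deliberation_cost(state, t, "trial_aware") == pytest.approx(0.05 * t)

    def test_zero_at_trial_start_with_zero_offset(self):
        state = FilterState(rho_long=0.04, rho_context=0.06, offset=0.0)
        for mode in ("trial_aware", "trial_unaware", "stationary"):
            assert deliberation_cost(state, 0, mode) == 0.0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            deliberation_cost(FilterState(), 1, "bogus")


def test_leading_order_filter_mass():
    """For tau much larger than the elapsed time the step-wise filter is a
    scaled running sum of rewards: rho_t ~ beta * sum(R)."""
    rng = np.random.default_rng(0)
    rewards = rng.uniform(0, 1, size=30)
    tau = 1e5
    est = 0.0
    for r in rewards:
        est = stepwise_update(est, r, tau)
    assert est == pytest.approx(rewards.sum() / (1 + tau), rel=1e-3)


def test_trial_aware_offset_is_context_signed_and_balanced(periodic_session):
    """The trial-aware cost offset carries the sign of rho_alpha - rho
    (positive in fast blocks, negative in slow ones) and largely cancels
    across evenly distributed contexts."""
    log, _ = periodic_session
    offsets = log.meta["filters"].offset.to_numpy()
    alpha = log.frame.alpha.to_numpy()
    keep = np.arange(len(offsets)) >= 600  # whole periods, past burn-in
    mean_fast = offsets[keep & (alpha == 0.75)].mean()
    mean_slow = offsets[keep & (alpha == 0.25)].mean()
    assert mean_fast > 0 > mean_slow
    residual = abs(offsets[keep].mean())
    assert residual < 0.5 * (abs(mean_fast) + abs(mean_slow)) / 2


def test_snapshot_serializes(tmp_path):
    state = advance(FilterState(), 0.7, 15.0)
    snap = state.snapshot()
    assert set(snap) >= {"rho_long", "rho_context", "offset", "t_track"}
    import json

    assert json.loads(state.to_json()) == snap
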