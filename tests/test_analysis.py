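"""Survival surfaces, aligned averages, accounting and urgency prediction."""

import numpy as np
import pandas as pd
import pytest

from pgd import PgdParams, make_schedule, run_session
from pgd.agent import TrialLog
from pgd.analysis import (
    predict_urgency,
    reward_rate_accounting,
    survival_surface,
    switch_aligned_means,
)


def _one_and_done_log(n_trials=200, seed=0):
    rng = np.random.default_rng(seed)
    walks = np.where(rng.random((n_trials, 15)) < 0.5, 1, -1)
    partial = np.concatenate([np.zeros((n_trials, 1), int), np.cumsum(walks, 1)], 1)
    frame = pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "alpha": 0.25,
            "t_dec": 1,
            "n_dec": partial[:, 1],
            "report": partial[:, 1],
            "reward": (partial[:, 1] * partial[:, -1] > 0).astype(float),
            "duration": 1 + 0.75 * 14 + 7.5,
        }
    )
    return TrialLog(frame=frame, walks=walks)


class TestSurvivalSurface:
    def test_survival_is_one_at_trial_start(self, periodic_session):
        log, _ = periodic_session
        surf = survival_surface(log)
        assert surf.at(0, 0) == pytest.approx(1.0)

    def test_one_and_done_log(self):
        surf = survival_surface(_one_and_done_log())
        assert surf.at(0, 0) == 1.0
        for t in range(1, 16):
            row = surf.survival[:, t]
            visited = ~np.isnan(row)
            assert (row[visited] == 0).all()

    def test_missing_cells_are_nan_not_zero(self):
        surf = survival_surface(_one_and_done_log(n_trials=5))
        assert np.isnan(surf.survival[0, 0])  # n = -15 at t = 0 is unreachable
        frame = surf.to_frame()
        assert (frame["count"] > 0).all()

    def test_invariant_to_trial_order(self, periodic_session):
        log, _ = periodic_session
        perm = np.random.default_rng(0).permutation(len(log))
        shuffled = TrialLog(
            frame=log.frame.iloc[perm].reset_index(drop=True),
            walks=log.walks[perm],
        )
        a, b = survival_surface(log), survival_surface(shuffled)
        both = ~np.isnan(a.survival)
        assert (b.survival[both] == a.survival[both]).all()

    def test_requires_walks(self):
        log = _one_and_done_log()
        log.walks = None
        with pytest.raises(ValueError):
            survival_surface(log)

    def test_fast_context_contour_earlier(self, periodic_session):
        log, _ = periodic_session
        f = log.frame
        burn = f.trial >= 300
        fast = (burn & (f.alpha == 0.75)).to_numpy()
        slow = (burn & (f.alpha == 0.25)).to_numpy()
        surf_fast = survival_surface(
            TrialLog(frame=f[fast].reset_index(drop=True), walks=log.walks[fast])
        )
        surf_slow = survival_surface(
            TrialLog(frame=f[slow].reset_index(drop=True), walks=log.walks[slow])
        )
        shared_n = range(-3, 4)
        cf = surf_fast.half_contour(shared_n)
        cs = surf_slow.half_contour(shared_n)
        common = set(cf) & set(cs)
        assert common
        assert np.mean([cf[n] for n in common]) < np.mean([cs[n] for n in common])


class TestSwitchAligned:
    def test_constant_decision_times_give_flat_series(self):
        sched = make_schedule("periodic", n_trials=600, t_block=100)
        frame = pd.DataFrame(
            {"trial": np.arange(600), "alpha": sched.alphas, "t_dec": 7,
             "n_dec": 1, "report": 1, "reward": 1.0, "duration": 20.0}
        )
        series = switch_aligned_means(TrialLog(frame=frame), sched, window=10)
        for ev in ("slow_to_fast", "fast_to_slow"):
            assert series.mean[ev] == pytest.approx(np.full(20, 7.0))

    def test_relaxation_toward_block_baselines(self, periodic_session):
        log, sched = periodic_session
        series = switch_aligned_means(log, sched, window=20)
        s2f = series.mean["slow_to_fast"]
        f2s = series.mean["fast_to_slow"]
        # decision times drop after slow->fast switches and rise after fast->slow
        assert s2f[:10].mean() > s2f[-10:].mean()
        assert f2s[:10].mean() < f2s[-10:].mean()

    def test_output_frame_schema(self, periodic_session):
        log, sched = periodic_session
        frame = switch_aligned_means(log, sched, window=5).to_frame()
        assert set(frame.columns) == {"offset", "event_type", "mean", "se", "n_events"}
        assert len(frame) == 2 * 2 * 5

    def test_warns_when_window_exceeds_interior_block(self):
        alphas = np.repeat([0.25, 0.75, 0.25], [30, 10, 30])
        sched = make_schedule("custom", alpha_sequence=alphas)
        frame = pd.DataFrame(
            {"trial": np.arange(70), "alpha": alphas, "t_dec": 7, "n_dec": 1,
             "report": 1, "reward": 1.0, "duration": 20.0}
        )
        with pytest.warns(UserWarning, match="alignment window"):
            switch_aligned_means(TrialLog(frame=frame), sched, window=20)

    def test_requires_switches(self):
        sched = make_schedule("custom", alpha_sequence=np.full(50, 0.25))
        frame = pd.DataFrame(
            {"trial": np.arange(50), "alpha": 0.25, "t_dec": 7, "n_dec": 1,
             "report": 1, "reward": 1.0, "duration": 20.0}
        )
        with pytest.raises(ValueError):
            switch_aligned_means(TrialLog(frame=frame), sched, window=5)


class TestRewardRateAccounting:
    def test_perfect_accuracy_ignores_penalty(self):
        assert reward_rate_accounting(1.0, 0.5, 37.0, 1.0) == pytest.approx(1 / 1.5)

    def test_published_two_and_four_choice_rates(self):
        rho_2 = reward_rate_accounting(0.71, 0.527, 1.0, 1.0)
        rho_4 = reward_rate_accounting(0.49, 0.725, 1.0, 1.0)
        assert rho_2 == pytest.approx(0.40, abs=0.01)
        assert rho_4 == pytest.approx(0.22, abs=0.01)

    def test_matches_simulator_identity(self):
        """sum(R)/sum(T) of a single-context session equals the accounting
        formula applied to its aggregate accuracy and mean times."""
        sched = make_schedule("custom", alpha_sequence=np.full(800, 0.25))
        log = run_session(sched, PgdParams(), seed=3)
        f = log.frame
        accuracy = f.reward.mean()
        response = (f.duration - 7.5).mean()
        assert log.reward_rate() == pytest.approx(
            reward_rate_accounting(accuracy, response, 0.0, 7.5), abs=1e-12
        )

    def test_input_validation(self):
        with pytest.raises(ValueError):
            reward_rate_accounting(1.2, 1.0, 1.0, 1.0)
        with pytest.raises(ZeroDivisionError):
            reward_rate_accounting(0.5, 0.0, 0.0, 0.0)


@pytest.fixture(scope="module")
def urgency():
    sched = make_schedule("periodic", n_trials=2400, t_block=300)
    return predict_urgency(PgdParams(), sched, seed=2, burn_in=300)


class TestPredictUrgency:
    def test_shared_slope_across_contexts(self, urgency):
        slopes = urgency.groupby("context").apply(
            lambda g: np.polyfit(g.t, g["mean"], 1)[0], include_groups=False
        )
        rel_diff = abs(slopes[0.75] - slopes[0.25]) / abs(slopes[0.25])
        assert rel_diff < 0.05

    def test_fast_context_offset_higher(self, urgency):
        offsets = urgency[urgency.t == 0].set_index("context")["mean"]
        assert offsets[0.75] > offsets[0.25]

    def test_single_context_offset_near_zero(self):
        sched = make_schedule("custom", alpha_sequence=np.full(1500, 0.25))
        curves = predict_urgency(PgdParams(), sched, seed=2, burn_in=300)
        offset = curves[curves.t == 0]["mean"].iloc[0]
        slope_cost = curves[curves.t == 15]["mean"].iloc[0]
        assert abs(offset) < 0.1 * slope_cost
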