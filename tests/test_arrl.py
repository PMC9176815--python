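"""Average-reward dynamic programming: optimality equations and oracles."""

import numpy as np
import pytest
from scipy import stats

from pgd.arrl import (
    TaskConfig,
    backward_induction,
    best_c_fit,
    discounted_reference_policy,
    evaluate_policy_exact,
    is_one_and_done,
    is_wait_for_certainty,
    one_and_done_policy,
    policy_decision_times,
    solve_self_consistent,
    wait_for_certainty_policy,
)
from pgd.agent import TrialLog
import pandas as pd


class TestExactEvaluator:
    def test_report_at_start_closed_form(self):
        # accuracy 1/2, duration 0.25 * 15 + 7.5 = 11.25 at alpha = 3/4
        policy = np.zeros((31, 16), dtype=bool)
        policy[15, 0] = True
        rho = evaluate_policy_exact(policy, 0.75)
        assert rho == pytest.approx(0.5 / 11.25, abs=1e-12)

    def test_one_and_done_closed_form(self):
        # accuracy P(Binom(14, 1/2) >= 7), duration 1 + 0.25*14 + 7.5 = 12
        accuracy = float(stats.binom.sf(6, 14, 0.5))
        rho = evaluate_policy_exact(one_and_done_policy(), 0.75)
        assert rho == pytest.approx(accuracy / 12.0, abs=1e-12)

    def test_wait_for_certainty_is_perfectly_accurate(self):
        for alpha in (0.0, 0.5, 1.0):
            policy = wait_for_certainty_policy()
            cfg = TaskConfig()
            # accuracy 1: rate = 1 / mean duration
            rho = evaluate_policy_exact(policy, alpha, cfg)
            walks = np.where(
                ((np.arange(1 << 15)[:, None] >> np.arange(15)) & 1) == 1, 1, -1
            )
            t_dec = policy_decision_times(policy, walks, 15)
            durations = t_dec + (1 - alpha) * (15 - t_dec) + 7.5
            assert rho == pytest.approx(1.0 / durations.mean(), abs=1e-12)

    def test_horizon_cap(self):
        with pytest.raises(ValueError):
            evaluate_policy_exact(np.zeros((47, 24), bool), 0.5, TaskConfig(t_max=23))


class TestBackwardInduction:
    def test_self_consistency_at_converged_rho(self):
        sol = solve_self_consistent(0.75, 0.0)
        # at the self-consistent rho the expected trial return vanishes,
        # i.e. the start-of-trial value equals the next trial's start value (0)
        assert sol.V[15, 0] == pytest.approx(0.0, abs=1e-8)

    def test_value_is_max_of_action_values(self):
        sol = backward_induction(0.5, 0.01, 0.05)
        for t in range(15):
            for n in range(-t, t + 1, 2):
                i = n + 15
                assert sol.V[i, t] == pytest.approx(
                    max(sol.Q_report[i, t], sol.Q_wait[i, t])
                )

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            backward_induction(1.5, 0.0, 0.05)


class TestSelfConsistentSolutions:
    def test_one_and_done_at_full_incentive(self):
        sol = solve_self_consistent(1.0, 0.0)
        assert is_one_and_done(sol.policy, 15)
        assert sol.rho == pytest.approx(
            evaluate_policy_exact(one_and_done_policy(), 1.0), abs=1e-10
        )

    def test_wait_for_certainty_at_zero_incentive(self):
        sol = solve_self_consistent(0.0, 0.0)
        assert is_wait_for_certainty(sol.policy, 15)

    def test_rho_matches_exact_evaluation(self):
        for alpha, c in [(0.25, 0.0), (0.75, 0.02), (0.5, 0.05)]:
            sol = solve_self_consistent(alpha, c)
            assert sol.rho == pytest.approx(
                evaluate_policy_exact(sol.policy, alpha), abs=1e-10
            )

    def test_rho_nondecreasing_in_alpha(self):
        rhos = [solve_self_consistent(a, 0.0).rho for a in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert (np.diff(rhos) >= -1e-12).all()

    def test_deliberation_cost_rate_shortens_decisions(self):
        from pgd.arrl import _all_walks

        walks = _all_walks(15)
        t_free = policy_decision_times(solve_self_consistent(0.25, 0.0).policy, walks, 15)
        t_cost = policy_decision_times(solve_self_consistent(0.25, 0.05).policy, walks, 15)
        assert (t_cost <= t_free).all()
        assert t_cost.mean() < t_free.mean()

    def test_no_reports_at_ambiguous_states_mid_trial(self):
        """AR-RL boundaries hug the edges of the state space: the optimal
        policy never reports at N = 0 at intermediate times."""
        for c in (0.0, 0.01, 0.05):
            for alpha in (0.25, 0.75):
                sol = solve_self_consistent(alpha, c)
                assert not any(sol.policy[15, t] for t in range(2, 14, 2))

    def test_strategy_plane_interpolates_monotonically(self):
        """Policies move from wait-for-certainty toward one-and-done as
        either the incentive alpha or the cost rate c grows."""
        from pgd.arrl import _all_walks

        walks = _all_walks(15)
        assert is_one_and_done(solve_self_consistent(0.9, 0.05).policy, 15)
        mean_t = lambda a, c: policy_decision_times(
            solve_self_consistent(a, c).policy, walks, 15
        ).mean()
        for c in (0.0, 0.02):
            row = [mean_t(a, c) for a in (0.0, 0.5, 1.0)]
            assert row[0] >= row[1] >= row[2]
        for a in (0.25, 0.75):
            col = [mean_t(a, c) for c in (0.0, 0.02, 0.05)]
            assert col[0] >= col[1] >= col[2]

    def test_discounted_value_iteration_reaches_same_policy(self):
        for alpha in (0.0, 0.25, 0.75):
            sol = solve_self_consistent(alpha, 0.0)
            assert (discounted_reference_policy(alpha) == sol.policy).all()


class TestBestCFit:
    def _log_from_policy(self, policy, alpha, n_trials=400, seed=0):
        rng = np.random.default_rng(seed)
        walks = np.where(rng.random((n_trials, 15)) < 0.5, 1, -1)
        t_dec = policy_decision_times(policy, walks, 15)
        partial = np.concatenate(
            [np.zeros((n_trials, 1), int), np.cumsum(walks, axis=1)], axis=1
        )
        n_dec = partial[np.arange(n_trials), t_dec]
        frame = pd.DataFrame(
            {
                "trial": np.arange(n_trials),
                "alpha": alpha,
                "t_dec": t_dec,
                "n_dec": n_dec,
                "report": np.where(n_dec >= 0, 1, -1),
                "reward": 1.0,
                "duration": t_dec + (1 - alpha) * (15 - t_dec) + 7.5,
            }
        )
        return TrialLog(frame=frame, walks=walks)

    def test_recovers_generating_cost_rate(self):
        grid = [0.0, 0.01, 0.03, 0.06]
        truth = 0.03
        log = self._log_from_policy(
            solve_self_consistent(0.25, truth).policy, 0.25
        )
        c_star, table = best_c_fit(log, 0.25, grid)
        assert c_star == truth
        assert table.mean_abs_dt.min() == 0.0
        assert {"c", "mean_abs_dt", "rss", "rho"} <= set(table.columns)

    def test_empty_grid_rejected(self):
        log = self._log_from_policy(one_and_done_policy(), 0.25)
        with pytest.raises(ValueError):
            best_c_fit(log, 0.25, [])
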