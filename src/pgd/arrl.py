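"""Average-reward dynamic programming for the tokens task.

Reference solutions against which PGD is compared.  The episodic
average-reward formulation conditions value on within-trial time: waiting is
an incremental action costing the opportunity rate, while reporting collapses
the remainder of the trial.  With the value shift fixed so the start-of-trial
value is zero, the optimality equations read

    Q(n, +/-|t) = rbar_a(n, t) - rho * (T(t) - t)
    Q(n, wait|t) = -(rho + c) + E[ V(n', t+1) ]
    V(n|t)       = max_a Q(n, a|t)

where ``c`` is an auxiliary deliberation cost rate incurred only before the
decision, and ``T(t)`` the contraction-rule trial duration for deciding at t.
The self-consistent reward rate solves rho = Rbar(pi_rho) / Tbar(pi_rho) for
the greedy policy pi_rho, recovering the defining long-run rate.  An exact
enumeration oracle over all 2^t_max equiprobable walks verifies the forward
propagation used inside the solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
import pandas as pd

from .tokens.beliefs import BeliefTable, PayoffMatrix
from .tokens.env import DEFAULT_T_ITI

__all__ = [
    "TaskConfig",
    "ArrlSolution",
    "backward_induction",
    "solve_self_consistent",
    "evaluate_policy_exact",
    "policy_decision_times",
    "best_c_fit",
    "one_and_done_policy",
    "wait_for_certainty_policy",
    "discounted_reference_policy",
]

# reporting wins exact value ties (waiting at a tie can only delay)
_TIE_TOL = 1e-12

_ENUM_T_MAX = 21


@dataclass(frozen=True)
class TaskConfig:
    """Static tokens-task parameters shared by the DP routines."""

    t_max: int = 15
    p: float = 0.5
    t_iti: float = DEFAULT_T_ITI
    payoff: PayoffMatrix = field(default_factory=PayoffMatrix.identity)
    movement_cost: float = 0.0  # constant cost on report actions

    def duration(self, t_dec: float, alpha: float) -> float:
        return t_dec + (1.0 - alpha) * (self.t_max - t_dec) + self.t_iti


def _reward_tables(config: TaskConfig) -> tuple[np.ndarray, np.ndarray]:
    """Dense best-report expected reward rbar[n+t_max, t] and p_plus table."""
    table = BeliefTable(t_max=config.t_max, p=config.p)
    t_max = config.t_max
    r = config.payoff.array
    rbar = np.full((2 * t_max + 1, t_max + 1), np.nan)
    p_plus_arr = np.full_like(rbar, np.nan)
    for (n, t), p_plus in table.values.items():
        ra = p_plus * r[0, 0] + (1 - p_plus) * r[1, 0]
        rb = p_plus * r[0, 1] + (1 - p_plus) * r[1, 1]
        rbar[n + t_max, t] = max(ra, rb)
        p_plus_arr[n + t_max, t] = p_plus
    return rbar, p_plus_arr


@dataclass
class ArrlSolution:
    """Value tables, greedy policy and reward rate for one (alpha, c)."""

    alpha: float
    c: float
    rho: float
    V: np.ndarray  # [n + t_max, t]
    Q_report: np.ndarray
    Q_wait: np.ndarray
    policy: np.ndarray  # bool, True = report at (n, t)
    config: TaskConfig
    converged: bool = True
    iterations: int = 0

    @property
    def t_max(self) -> int:
        return self.config.t_max

    def decision_boundary(self) -> dict[int, int]:
        """Earliest reporting |n| per t (None omitted where never reporting)."""
        out = {}
        t_max = self.t_max
        for t in range(t_max + 1):
            ns = [
                abs(n)
                for n in range(-t, t + 1, 2)
                if self.policy[n + t_max, t]
            ]
            if ns:
                out[t] = min(ns)
        return out

    def to_frames(self) -> tuple[pd.DataFrame, dict]:
        rows = []
        t_max = self.t_max
        for t in range(t_max + 1):
            for n in range(-t, t + 1, 2):
                rows.append(
                    {
                        "n": n,
                        "t": t,
                        "V": self.V[n + t_max, t],
                        "Q_wait": self.Q_wait[n + t_max, t],
                        "Q_report": self.Q_report[n + t_max, t],
                        "act": "report" if self.policy[n + t_max, t] else "wait",
                    }
                )
        meta = {
            "alpha": self.alpha,
            "c": self.c,
            "rho": self.rho,
            "t_max": t_max,
            "p": self.config.p,
            "t_iti": self.config.t_iti,
        }
        return pd.DataFrame(rows), meta

    def export(self, csv_path, json_path) -> None:
        frame, meta = self.to_frames()
        frame.to_csv(csv_path, index=False)
        with open(json_path, "w") as fh:
            json.dump(meta, fh, indent=2)


def backward_induction(
    alpha: float,
    c: float,
    rho: float,
    config: TaskConfig | None = None,
    rbar: np.ndarray | None = None,
) -> ArrlSolution:
    """Solve the optimality equations at a fixed rho (unnormalized).

    The recursion is seeded at t_max with the best reporting action (never
    reporting is always sub-optimal) and filled backward; the expectation for
    the wait action uses the walk's jump probabilities.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha={alpha} outside [0, 1]")
    config = config or TaskConfig()
    t_max = config.t_max
    if t_max < 1:
        raise ValueError("horizon must be positive")
    if rbar is None:
        rbar, _ = _reward_tables(config)
    p = config.p
    shape = (2 * t_max + 1, t_max + 1)
    V = np.full(shape, np.nan)
    Q_report = np.full(shape, np.nan)
    Q_wait = np.full(shape, np.nan)
    policy = np.zeros(shape, dtype=bool)
    for t in range(t_max, -1, -1):
        remaining = config.duration(t, alpha) - t
        for n in range(-t, t + 1, 2):
            i = n + t_max
            q_rep = rbar[i, t] - rho * remaining - config.movement_cost
            Q_report[i, t] = q_rep
            if t == t_max:
                V[i, t] = q_rep
                policy[i, t] = True
                continue
            ev_next = p * V[i + 1, t + 1] + (1.0 - p) * V[i - 1, t + 1]
            q_wait = -(rho + c) + ev_next
            Q_wait[i, t] = q_wait
            if q_rep >= q_wait - _TIE_TOL:
                V[i, t] = q_rep
                policy[i, t] = True
            else:
                V[i, t] = q_wait
    return ArrlSolution(
        alpha=alpha, c=c, rho=rho, V=V, Q_report=Q_report, Q_wait=Q_wait,
        policy=policy, config=config,
    )


def _policy_rate(policy: np.ndarray, alpha: float, config: TaskConfig,
                 rbar: np.ndarray) -> tuple[float, float]:
    """Exact (Rbar, Tbar) of a lattice policy by forward probability flow."""
    t_max, p = config.t_max, config.p
    mass = np.zeros(2 * t_max + 1)
    mass[t_max] = 1.0
    R_bar = 0.0
    T_bar = 0.0
    for t in range(t_max + 1):
        for n in range(-t, t + 1, 2):
            i = n + t_max
            m = mass[i]
            if m == 0.0:
                continue
            if policy[i, t] or t == t_max:
                R_bar += m * rbar[i, t]
                T_bar += m * config.duration(t, alpha)
                mass[i] = 0.0
        if t < t_max:
            new = np.zeros_like(mass)
            idx = np.flatnonzero(mass)
            new[idx + 1] += p * mass[idx]
            new[idx - 1] += (1.0 - p) * mass[idx]
            mass = new
    return R_bar, T_bar


def solve_self_consistent(
    alpha: float,
    c: float = 0.0,
    config: TaskConfig | None = None,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> ArrlSolution:
    """Find the self-consistent reward rate rho = Rbar/Tbar of the greedy policy.

    Bisection on g(rho) = Rbar(pi_rho) - rho * Tbar(pi_rho) over
    [0, r_max/T_ITI], then a fixed-point polish rho <- Rbar/Tbar which is
    exact once the policy stabilizes (g is piecewise linear in rho).
    """
    config = config or TaskConfig()
    rbar, _ = _reward_tables(config)

    def g(rho: float) -> tuple[float, ArrlSolution]:
        sol = backward_induction(alpha, c, rho, config, rbar=rbar)
        R_bar, T_bar = _policy_rate(sol.policy, alpha, config, rbar)
        return R_bar - rho * T_bar, sol

    lo, hi = 0.0, config.payoff.r_max / config.t_iti
    g_lo, _ = g(lo)
    g_hi, _ = g(hi)
    if g_lo < 0:
        raise RuntimeError("self-consistency bracket invalid at rho=0")
    if g_hi > 0:
        hi *= 2.0
        g_hi, _ = g(hi)
        if g_hi > 0:
            raise RuntimeError(
                f"failed to bracket self-consistent rho in [0, {hi}] "
                f"(g={g_lo:.3g} at 0, {g_hi:.3g} at {hi})"
            )
    it = 0
    while hi - lo > 1e-6 and it < max_iter:
        mid = 0.5 * (lo + hi)
        g_mid, _ = g(mid)
        if g_mid > 0:
            lo = mid
        else:
            hi = mid
        it += 1
    # fixed-point polish: within a policy cell g is linear with root Rbar/Tbar
    rho = 0.5 * (lo + hi)
    sol = None
    for _ in range(50):
        it += 1
        sol = backward_induction(alpha, c, rho, config, rbar=rbar)
        R_bar, T_bar = _policy_rate(sol.policy, alpha, config, rbar)
        rho_new = R_bar / T_bar
        if abs(rho_new - rho) <= tol:
            rho = rho_new
            sol = backward_induction(alpha, c, rho, config, rbar=rbar)
            sol.rho = rho
            sol.iterations = it
            return sol
        rho = rho_new
    # degenerate boundary case (c > 0 only): the greedy objective includes
    # the pre-decision cost c, so the plain-rate map rho -> Rbar/Tbar can
    # jump across the diagonal at a policy switch and the polish 2-cycles.
    # Return the better of the two boundary policies, with its exact rate.
    best = None
    for rho_side in (lo, hi):
        cand = backward_induction(alpha, c, rho_side, config, rbar=rbar)
        R_bar, T_bar = _policy_rate(cand.policy, alpha, config, rbar)
        if best is None or R_bar / T_bar > best.rho:
            cand.rho = R_bar / T_bar
            best = cand
    best.iterations = it
    if abs(hi - lo) > 1e-6:
        best.converged = False
        raise RuntimeError(
            f"self-consistent rho did not converge after {it} iterations; "
            f"bracket [{lo}, {hi}]"
        )
    return best


def _all_walks(t_max: int) -> np.ndarray:
    """All 2^t_max jump sequences as a (+1/-1) matrix."""
    if t_max > _ENUM_T_MAX:
        raise ValueError(
            f"exhaustive enumeration limited to t_max <= {_ENUM_T_MAX}, got {t_max}"
        )
    n = 1 << t_max
    bits = (np.arange(n)[:, None] >> np.arange(t_max)[None, :]) & 1
    return np.where(bits == 1, 1, -1)


def policy_decision_times(policy: np.ndarray, walks: np.ndarray, t_max: int) -> np.ndarray:
    """First reporting time of a lattice policy along each walk."""
    partial = np.concatenate(
        [np.zeros((len(walks), 1), dtype=int), np.cumsum(walks, axis=1)], axis=1
    )
    t_dec = np.full(len(walks), t_max, dtype=int)
    undecided = np.ones(len(walks), dtype=bool)
    for t in range(t_max + 1):
        hit = undecided & policy[partial[:, t] + t_max, t]
        t_dec[hit] = t
        undecided &= ~hit
    return t_dec


def evaluate_policy_exact(
    policy: np.ndarray, alpha: float, config: TaskConfig | None = None
) -> float:
    """Exact reward rate of a stationary lattice policy at p = 1/2.

    Enumerates all 2^t_max equiprobable walks, applies the policy with greedy
    reporting (ties at n = 0 scored at the average of the two actions), and
    returns sum(R)/sum(T).
    """
    config = config or TaskConfig()
    if config.p != 0.5:
        raise ValueError("exact enumeration assumes p = 1/2")
    t_max = config.t_max
    walks = _all_walks(t_max)
    partial = np.concatenate(
        [np.zeros((len(walks), 1), dtype=int), np.cumsum(walks, axis=1)], axis=1
    )
    t_dec = policy_decision_times(policy, walks, t_max)
    n_dec = partial[np.arange(len(walks)), t_dec]
    final = partial[:, -1]
    r = config.payoff.array
    rewards = np.where(
        n_dec > 0,
        np.where(final > 0, r[0, 0], r[1, 0]),
        np.where(
            n_dec < 0,
            np.where(final > 0, r[0, 1], r[1, 1]),
            0.5 * np.where(final > 0, r[0, 0] + r[0, 1], r[1, 0] + r[1, 1]),
        ),
    )
    durations = t_dec + (1.0 - alpha) * (t_max - t_dec) + config.t_iti
    return float(rewards.sum() / durations.sum())


def one_and_done_policy(config: TaskConfig | None = None) -> np.ndarray:
    """Report at t = 1 in the direction of the first jump."""
    config = config or TaskConfig()
    t_max = config.t_max
    policy = np.zeros((2 * t_max + 1, t_max + 1), dtype=bool)
    for t in range(1, t_max + 1):
        for n in range(-t, t + 1, 2):
            policy[n + t_max, t] = True
    return policy


def wait_for_certainty_policy(config: TaskConfig | None = None) -> np.ndarray:
    """Report only once the outcome is certain (|n| >= t_max - t)."""
    config = config or TaskConfig()
    t_max = config.t_max
    policy = np.zeros((2 * t_max + 1, t_max + 1), dtype=bool)
    for t in range(t_max + 1):
        for n in range(-t, t + 1, 2):
            policy[n + t_max, t] = abs(n) >= t_max - t
    return policy


def is_one_and_done(policy: np.ndarray, t_max: int) -> bool:
    """True if the policy waits at (0, 0) and reports at every t = 1 state."""
    return (
        not policy[t_max, 0]
        and bool(policy[t_max + 1, 1])
        and bool(policy[t_max - 1, 1])
    )


def is_wait_for_certainty(policy: np.ndarray, t_max: int) -> bool:
    """True if reporting happens exactly on the certainty cone."""
    for t in range(t_max + 1):
        for n in range(-t, t + 1, 2):
            certain = abs(n) >= t_max - t
            if policy[n + t_max, t] != certain:
                return False
    return True


def best_c_fit(
    observed_log,
    alpha: float,
    c_grid,
    config: TaskConfig | None = None,
) -> tuple[float, pd.DataFrame]:
    """Choose the auxiliary cost rate whose AR-RL policy best matches a log.

    For each c on the grid, the self-consistent policy at (alpha, c) is
    applied to the *same walks* as the observed trials (restricted to context
    alpha); the score is the mean |t_dec difference|.  Returns the argmin and
    a per-c table with mean error and residual sum of squares.
    """
    c_grid = list(c_grid)
    if not c_grid:
        raise ValueError("c_grid must be non-empty")
    config = config or TaskConfig()
    if observed_log.walks is None:
        raise ValueError("observed log must carry its walks")
    mask = observed_log.frame.alpha.to_numpy() == alpha
    if not mask.any():
        raise ValueError(f"log contains no trials at alpha={alpha}")
    walks = np.asarray(observed_log.walks)[mask]
    t_obs = observed_log.frame.t_dec.to_numpy()[mask]
    rows = []
    best = (np.inf, None)
    for c in c_grid:
        sol = solve_self_consistent(alpha, c, config)
        t_model = policy_decision_times(sol.policy, walks, config.t_max)
        diff = np.abs(t_model - t_obs)
        mean_err = float(diff.mean())
        rows.append(
            {"c": c, "mean_abs_dt": mean_err, "rss": float((diff.astype(float) ** 2).sum()),
             "rho": sol.rho}
        )
        if mean_err < best[0]:
            best = (mean_err, c)
    return best[1], pd.DataFrame(rows)


def discounted_reference_policy(
    alpha: float,
    config: TaskConfig | None = None,
    gamma: float = 1.0 - 1e-5,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Discount-reward value iteration; near gamma = 1 it recovers the
    average-reward policy (Blackwell limit).  Cross-check only, c = 0."""
    config = config or TaskConfig()
    rbar, _ = _reward_tables(config)
    t_max, p = config.t_max, config.p
    W = 0.0  # value of standing at a trial start

    def greedy(W: float) -> np.ndarray:
        V = np.full((2 * t_max + 1, t_max + 1), np.nan)
        pol = np.zeros_like(V, dtype=bool)
        for t in range(t_max, -1, -1):
            remaining = config.duration(t, alpha) - t
            for n in range(-t, t + 1, 2):
                i = n + t_max
                q_rep = gamma**remaining * (rbar[i, t] + W)
                if t == t_max:
                    V[i, t] = q_rep
                    pol[i, t] = True
                    continue
                q_wait = gamma * (p * V[i + 1, t + 1] + (1 - p) * V[i - 1, t + 1])
                if q_rep >= q_wait - _TIE_TOL:
                    V[i, t] = q_rep
                    pol[i, t] = True
                else:
                    V[i, t] = q_wait
        return pol

    def start_value(pol: np.ndarray, W: float) -> float:
        # exact W for a fixed policy: W solves W = A + B*W with
        # A = E[gamma^T rbar], B = E[gamma^T] under the policy flow
        mass = np.zeros(2 * t_max + 1)
        mass[t_max] = 1.0
        A = B = 0.0
        for t in range(t_max + 1):
            disc = gamma ** config.duration(t, alpha)
            for n in range(-t, t + 1, 2):
                i = n + t_max
                m = mass[i]
                if m == 0.0:
                    continue
                if pol[i, t] or t == t_max:
                    A += m * disc * rbar[i, t]
                    B += m * disc
                    mass[i] = 0.0
            if t < t_max:
                new = np.zeros_like(mass)
                idx = np.flatnonzero(mass)
                new[idx + 1] += p * mass[idx]
                new[idx - 1] += (1.0 - p) * mass[idx]
                mass = new
        return A / (1.0 - B)

    policy = greedy(W)
    for _ in range(max_iter):
        W_new = start_value(policy, W)
        new_policy = greedy(W_new)
        if abs(W_new - W) < tol and (new_policy == policy).all():
            return new_policy
        W, policy = W_new, new_policy
    return policy
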