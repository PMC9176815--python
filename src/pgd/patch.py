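"""Analytically tractable patch-leaving task.

An agent samples patches (with replacement) whose return saturates as
``r_s(t) = r_max_s * (1 - (lambda t)^-1)``.  Maximizing the average-adjusted
return ``r - rho t`` gives the leave time ``t* = sqrt(r_max / (lambda rho))``,
which is also exactly the PGD crossing condition ``rho t = r_max/(lambda t)``;
the self-consistent optimal rate is ``rho* = lambda mu_1^2 / (4 mu_1/2^2)``
with ``mu_n`` the n-th moment of the richness distribution.  (The published
leave-time expression ``r_max/(lambda rho)`` is dimensionally inconsistent
with this profile; the square-root maximizer, which reproduces rho*, is used.)

Two learners are provided: a PGD learner that only filters its own reward
history and reads the current patch's richness, and a tabular AR-RL learner
that stores an average-adjusted return per *patch label* and is therefore
vulnerable to a random permutation of those labels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import math

import numpy as np
import pandas as pd

from .filters import trial_update

__all__ = [
    "PatchEnvironment",
    "analytic_optimum",
    "pgd_patch_run",
    "arrl_patch_run",
    "permute_states",
    "uniform_moments",
]


@dataclass(frozen=True)
class PatchEnvironment:
    """d patches of fixed richness with a shared saturating return profile."""

    r_max: np.ndarray  # per-patch richness, > 0
    lam: float = 0.2  # saturation rate, 1/steps
    t_cap: int | None = None  # decision grid is 1..t_cap

    def __post_init__(self) -> None:
        r = np.asarray(self.r_max, dtype=float)
        if (r <= 0).any():
            raise ValueError("patch richness must be positive")
        object.__setattr__(self, "r_max", r)
        if self.t_cap is None:
            rho_ref = self.lam * r.mean() ** 2 / (4.0 * (np.sqrt(r).mean() ** 2))
            cap = math.ceil(4.0 * math.sqrt(r.max() / (self.lam * rho_ref)))
            object.__setattr__(self, "t_cap", cap)

    @property
    def d(self) -> int:
        return len(self.r_max)

    def returns(self, s: int, t) -> np.ndarray:
        """Return after staying t steps in patch s (negative for tiny t)."""
        t = np.asarray(t, dtype=float)
        return self.r_max[s] * (1.0 - 1.0 / (self.lam * t))

    @classmethod
    def uniform(
        cls, d: int = 300, lam: float = 0.2, rng=None, low: float = 0.0, high: float = 1.0
    ) -> "PatchEnvironment":
        """Richness sampled uniformly on (low, high]; the study condition."""
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        r = low + (high - low) * (1.0 - rng.random(d))  # excludes exact 0
        return cls(r_max=r, lam=lam)


def uniform_moments(low: float = 0.0, high: float = 1.0) -> tuple[float, float]:
    """(mu_1, mu_1/2) of the uniform richness distribution."""
    mu1 = 0.5 * (low + high)
    # E[sqrt(r)] for r ~ U(low, high)
    mu_half = (2.0 / 3.0) * (high**1.5 - low**1.5) / (high - low)
    return mu1, mu_half


def analytic_optimum(mu1: float, mu_half: float, lam: float):
    """Optimal rate rho* = lam mu1^2 / (4 mu_1/2^2) and t*(r_max) map."""
    if mu1 <= 0 or mu_half <= 0 or lam <= 0:
        raise ValueError("moments and rate must be positive")
    rho_star = lam * mu1**2 / (4.0 * mu_half**2)

    def t_star(r_max):
        return np.sqrt(np.asarray(r_max, dtype=float) / (lam * rho_star))

    return rho_star, t_star


def _pgd_leave_time(r_max: float, lam: float, rho: float, t_cap: int) -> int:
    """First grid time at which rho*t >= r_max/(lam*t): ceil of the crossing."""
    if rho <= 0:
        return t_cap
    t = math.ceil(math.sqrt(r_max / (lam * rho)))
    return min(max(t, 1), t_cap)


def _policy_rate(env: PatchEnvironment, leave_times: np.ndarray) -> float:
    """Patch-averaged reward rate of a per-patch leave-time policy."""
    rewards = env.r_max * (1.0 - 1.0 / (env.lam * leave_times))
    return float(rewards.sum() / leave_times.sum())


def pgd_patch_run(
    env: PatchEnvironment,
    tau: float = 1.0e4,
    n_steps: int = 1_000_000,
    seed=None,
    eval_every: int = 2_000,
    rho_init: float | None = None,
) -> pd.DataFrame:
    """PGD learning curve on the patch task.

    The agent visits uniformly sampled patches, leaves when its filtered rate
    estimate satisfies the crossing condition on the integer grid, and
    filters the realized reward through the cumulative update at timescale
    tau.  Relative loss is measured against the analytic optimum by exact
    evaluation of the *current greedy policy* over all patches.  Returns a
    frame (step, relative_loss, rho_hat).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mu1 = float(env.r_max.mean())
    mu_half = float(np.sqrt(env.r_max).mean())
    rho_star = env.lam * mu1**2 / (4.0 * mu_half**2)
    rho_hat = rho_init if rho_init is not None else 0.0
    first = rho_hat == 0.0
    step = 0
    out = []
    next_eval = 0
    while step < n_steps:
        if step >= next_eval:
            times = np.array(
                [_pgd_leave_time(r, env.lam, rho_hat, env.t_cap) for r in env.r_max]
            )
            rho_policy = _policy_rate(env, times)
            out.append(
                {"step": step, "relative_loss": (rho_star - rho_policy) / rho_star,
                 "rho_hat": rho_hat}
            )
            next_eval += eval_every
        s = int(rng.integers(env.d))
        t_leave = _pgd_leave_time(env.r_max[s], env.lam, rho_hat, env.t_cap)
        reward = float(env.returns(s, t_leave))
        if first:
            rho_hat = reward / t_leave
            first = False
        else:
            rho_hat = trial_update(rho_hat, reward, t_leave, tau)
        step += t_leave
    return pd.DataFrame(out)


def arrl_patch_run(
    env: PatchEnvironment,
    tau: float = 1.0e4,
    n_steps: int = 1_000_000,
    permute_at: int | None = 500_000,
    seed=None,
    eval_every: int = 2_000,
    q_init: float = -1.0,
) -> pd.DataFrame:
    """Tabular AR-RL learning curve with optional state-label permutation.

    The learner estimates the average-adjusted return Qhat(s, t) per patch
    *label*, trained off-policy from the decisions of a PGD learner running
    alongside with the same learning rate (a comparison generous to AR-RL:
    no exploration needed).  Its greedy policy is t*_s = argmax_t Qhat(s, t).
    At ``permute_at`` steps the labels are randomly permuted: the table now
    addresses the wrong patches and performance collapses until relearned,
    while the PGD learner is unaffected.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mu1 = float(env.r_max.mean())
    mu_half = float(np.sqrt(env.r_max).mean())
    rho_star = env.lam * mu1**2 / (4.0 * mu_half**2)
    t_grid = np.arange(1, env.t_cap + 1, dtype=float)
    Q = np.full((env.d, env.t_cap), q_init)
    beta = 1.0 / (1.0 + tau)
    rho_hat = 0.0
    first = True
    # label -> environment patch mapping, scrambled at the permutation event
    label_of = np.arange(env.d)
    permuted = permute_at is None
    step = 0
    out = []
    next_eval = 0
    while step < n_steps:
        if step >= next_eval:
            greedy_t = np.argmax(Q, axis=1) + 1
            # the table is indexed by label; the environment patch behind
            # label s is label_of[s]
            rewards = env.r_max[label_of] * (1.0 - 1.0 / (env.lam * greedy_t))
            rho_policy = float(rewards.sum() / greedy_t.sum())
            out.append(
                {"step": step, "relative_loss": (rho_star - rho_policy) / rho_star,
                 "rho_hat": rho_hat}
            )
            next_eval += eval_every
        if not permuted and step >= permute_at:
            label_of = rng.permutation(env.d)
            permuted = True
        s_label = int(rng.integers(env.d))
        s_env = label_of[s_label]
        t_leave = _pgd_leave_time(env.r_max[s_env], env.lam, rho_hat, env.t_cap)
        reward = float(env.r_max[s_env] * (1.0 - 1.0 / (env.lam * t_leave)))
        # off-policy update of the visited entry toward the observed
        # average-adjusted return; same learning-rate machinery as the filter
        target = reward - rho_hat * t_leave
        Q[s_label, t_leave - 1] += (1.0 - (1.0 - beta) ** t_leave) * (
            target - Q[s_label, t_leave - 1]
        )
        if first:
            rho_hat = reward / t_leave
            first = False
        else:
            rho_hat = trial_update(rho_hat, reward, t_leave, tau)
        step += t_leave
    return pd.DataFrame(out)


def permute_states(env: PatchEnvironment, seed=None) -> PatchEnvironment:
    """Uniform random permutation of patch identities (richness multiset kept)."""
    if env.d < 2:
        raise ValueError("need at least two patches to permute")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return replace(env, r_max=env.r_max[rng.permutation(env.d)])
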