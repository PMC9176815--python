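"""The PGD decision rule and the closed loop over whole sessions.

PGD reports at the first within-trial time at which the accumulated
opportunity cost of deliberation meets or exceeds the opportunity cost of
commitment:

    t_dec = min{ t : C_del(t) >= C_com(t) },  capped at t_max.

No value function is consulted: the rule needs only the commitment-cost
lattice (learned statistics of the environment) and the running performance
filters (the agent's own reward history).  Equivalently, the decision
boundary in belief space is r_max - C_del(t), independent of evidence at
fixed trial time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .filters import FilterState, deliberation_cost
from .tokens.beliefs import BeliefTable, PayoffMatrix
from .tokens.env import (
    DEFAULT_T_ITI,
    ContextSchedule,
    WalkRealization,
    sample_walk,
    trial_duration,
)

__all__ = ["PgdParams", "CostTrajectory", "decide", "run_session", "TrialLog"]


@dataclass(frozen=True)
class PgdParams:
    """The four behavioural parameters of a PGD agent.

    tau_long, tau_context: filter integration times in steps; K: subjective
    reward scale; nu: tracking-cost sensitivity.
    """

    tau_long: float = 2.0e4
    tau_context: float = 1.0e3
    K: float = 1.0
    nu: float = 4.0

    def __post_init__(self) -> None:
        if not (self.tau_long > 0 and self.tau_context > 0):
            raise ValueError("integration times must be positive")
        if self.K < 0 or self.nu < 0:
            raise ValueError("K and nu must be nonnegative")

    def initial_filter_state(self, offset_noise_sd: float = 0.0) -> FilterState:
        return FilterState(
            tau_long=self.tau_long,
            tau_context_base=self.tau_context,
            K=self.K,
            nu=self.nu,
            offset_noise_sd=offset_noise_sd,
        )


@dataclass
class CostTrajectory:
    """Per-step commitment and deliberation costs for one trial."""

    c_com: np.ndarray
    c_del: np.ndarray
    t_dec: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": np.arange(len(self.c_del)), "C_del": self.c_del,
             "C_com": self.c_com}
        )


def decide(
    walk: WalkRealization,
    filter_state: FilterState,
    belief_table: BeliefTable,
    payoff: PayoffMatrix | None = None,
    mode: str = "trial_aware",
    rng: np.random.Generator | None = None,
    c_com_dense: np.ndarray | None = None,
    return_costs: bool = False,
):
    """Apply the PGD rule to one walk.

    Returns ``(t_dec, report)`` (plus the CostTrajectory when requested).
    The report is the action with the largest expected reward at the decision
    state; an exact tie (N_t = 0 under a symmetric payoff) is broken by a
    seeded uniform draw.
    """
    payoff = payoff or PayoffMatrix.identity()
    t_max = belief_table.t_max
    if c_com_dense is None:
        c_com_dense = belief_table.commitment_cost_dense(payoff)
    r = payoff.array
    t_dec = t_max
    for t in range(t_max + 1):
        n = walk.n_at(t)
        c_del = deliberation_cost(filter_state, t, mode)
        c_com = c_com_dense[n + t_max, t]
        if c_del >= c_com:
            t_dec = t
            break
    n_dec = walk.n_at(t_dec)
    p_plus = belief_table[(n_dec, t_dec)]
    per_action = np.array([p_plus, 1.0 - p_plus]) @ r
    if per_action[0] > per_action[1]:
        report = 1
    elif per_action[1] > per_action[0]:
        report = -1
    else:
        report = 1 if (rng is None or rng.random() < 0.5) else -1
    if not return_costs:
        return t_dec, report
    ts = np.arange(t_max + 1)
    c_del_curve = np.array([deliberation_cost(filter_state, t, mode) for t in ts])
    c_com_curve = np.array(
        [c_com_dense[walk.n_at(t) + t_max, t] for t in ts]
    )
    return t_dec, report, CostTrajectory(c_com_curve, c_del_curve, t_dec)


@dataclass
class TrialLog:
    """Tabular record of a session, one row per trial."""

    frame: pd.DataFrame
    walks: np.ndarray | None = None  # (n_trials, t_max) jump matrix
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def t_max(self) -> int:
        return int(self.meta.get("t_max", 15))

    def reward_rate(self, alpha: float | None = None) -> float:
        """Realized sum(R)/sum(T), optionally conditioned on context."""
        df = self.frame if alpha is None else self.frame[self.frame.alpha == alpha]
        return float(df.reward.sum() / df.duration.sum())


def run_session(
    schedule: ContextSchedule,
    params: PgdParams,
    t_max: int = 15,
    p: float = 0.5,
    t_iti: float = DEFAULT_T_ITI,
    payoff: PayoffMatrix | None = None,
    mode: str = "trial_aware",
    seed: int | np.random.Generator | None = None,
    belief_table: BeliefTable | None = None,
    offset_noise_sd: float = 0.0,
    record_filters: bool = False,
    walks: np.ndarray | None = None,
) -> TrialLog:
    """Play a full session of the tokens task with a PGD agent.

    Each trial: sample a walk (or use a supplied jump row), apply the PGD
    rule with the current filter state, score the outcome against the true
    final sign, compute the duration from the contraction rule, then advance
    the filters with the *expected* reward at the decision state.  Fully
    reproducible given the seed.
    """
    payoff = payoff or PayoffMatrix.identity()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    table = belief_table or BeliefTable(t_max=t_max, p=p)
    c_com = table.commitment_cost_dense(payoff)
    r_arr = payoff.array
    state = params.initial_filter_state(offset_noise_sd=offset_noise_sd)
    n_trials = len(schedule)

    if walks is None:
        jumps = np.where(rng.random((n_trials, t_max)) < p, 1, -1)
    else:
        jumps = np.asarray(walks)
        if jumps.shape != (n_trials, t_max):
            raise ValueError("walks must have shape (n_trials, t_max)")
    partials = np.concatenate(
        [np.zeros((n_trials, 1), dtype=int), np.cumsum(jumps, axis=1)], axis=1
    )
    # commitment-cost profile along each walk, gathered once for the session
    ts = np.arange(t_max + 1)
    c_paths = c_com[partials + t_max, ts[None, :]]

    rows = np.empty((n_trials, 7))
    filter_rows = [] if record_filters else None
    # filter state unrolled to plain floats; semantics identical to advance()
    K_scale, nu = state.K, state.nu
    tau_long, tau_ctx = state.tau_long, state.tau_context_base
    decay_long = 1.0 - 1.0 / (1.0 + tau_long)
    rho_long_f = rho_ctx_f = t_track = offset = 0.0
    noise_sd = state.offset_noise_sd
    r00, r01, r10, r11 = r_arr[0, 0], r_arr[0, 1], r_arr[1, 0], r_arr[1, 1]
    p_of = table.values
    alphas_arr = schedule.alphas
    for k in range(n_trials):
        alpha = alphas_arr[k]
        ns = partials[k]
        if mode == "trial_aware":
            rho, off = rho_long_f, offset
        elif mode == "trial_unaware":
            rho, off = rho_ctx_f, 0.0
        else:
            rho, off = rho_long_f, 0.0
        crossed = rho * ts + off >= c_paths[k]
        t_dec = int(np.argmax(crossed)) if crossed.any() else t_max
        n_dec = ns[t_dec]
        p_plus = p_of[(n_dec, t_dec)]
        ra_plus = p_plus * r00 + (1.0 - p_plus) * r10
        ra_minus = p_plus * r01 + (1.0 - p_plus) * r11
        if ra_plus > ra_minus:
            report = 1
        elif ra_minus > ra_plus:
            report = -1
        else:
            report = 1 if rng.random() < 0.5 else -1
        s_row = ns[t_max] <= 0
        reward = (r10 if s_row else r00) if report > 0 else (r11 if s_row else r01)
        duration = t_dec + (1.0 - alpha) * (t_max - t_dec) + t_iti
        r_bar = ra_plus if ra_plus >= ra_minus else ra_minus
        rows[k] = (k, alpha, t_dec, n_dec, report, reward, duration)
        r_in = K_scale * r_bar
        if k == 0:
            rho_long_f = rho_ctx_f = r_in / duration
            t_track = duration
        else:
            dl = decay_long**duration
            rho_long_f = dl * rho_long_f + (1.0 - dl) * (r_in / duration)
            tau_eff = tau_ctx / (1.0 + (duration / t_track) ** nu)
            dc = (tau_eff / (1.0 + tau_eff)) ** duration
            rho_ctx_f = dc * rho_ctx_f + (1.0 - dc) * (r_in / duration)
            dt_ = (tau_ctx / (1.0 + tau_ctx)) ** duration
            t_track = dt_ * t_track + (1.0 - dt_) * duration
        offset = (rho_ctx_f - rho_long_f) * duration
        if noise_sd > 0.0:
            offset += noise_sd * rng.standard_normal()
        if record_filters:
            filter_rows.append(
                {"rho_long": rho_long_f, "rho_context": rho_ctx_f,
                 "t_track": t_track, "offset": offset, "n_trials": k + 1}
            )

    frame = pd.DataFrame(
        rows, columns=["trial", "alpha", "t_dec", "n_dec", "report", "reward", "duration"]
    )
    for col in ("trial", "t_dec", "n_dec", "report"):
        frame[col] = frame[col].astype(int)
    meta = {
        "t_max": t_max,
        "p": p,
        "t_iti": t_iti,
        "mode": mode,
        "params": {
            "tau_long": params.tau_long,
            "tau_context": params.tau_context,
            "K": params.K,
            "nu": params.nu,
        },
    }
    if record_filters:
        meta["filters"] = pd.DataFrame(filter_rows)
    return TrialLog(frame=frame, walks=jumps, meta=meta)
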