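"""Multi-timescale performance filtering and the deliberation-cost curve.

The agent tracks its own reward rate with exponential low-pass filters at two
timescales: a long one (tau_long) estimating the stationary rate rho, and a
context one (tau_context) estimating the context-conditioned rate rho_alpha.
The within-trial opportunity cost of deliberation is built from these:

    trial-aware    C_del(t) = rho_long * t + (rho_context - rho_long) * T_prev
    trial-unaware  C_del(t) = rho_context * t
    stationary     C_del(t) = rho_long * t

The trial-aware offset is the context-specific cost deviation of a whole
trial, paid up-front at trial start; it vanishes in expectation when contexts
are evenly mixed.  The context filter's integration time is itself shrunk by
a tracking cost Q = T_sys / T_track with sensitivity nu, which makes
adaptation after fast-to-slow context switches quicker than the reverse for
nu > 1.

A subjective reward scale K multiplies the rewards fed into the performance
filters (and only those; objective performance metrics use unscaled rewards).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import json

__all__ = [
    "FilterState",
    "stepwise_update",
    "trial_update",
    "effective_tau",
    "advance",
    "deliberation_cost",
    "COST_MODES",
]

COST_MODES = ("trial_aware", "trial_unaware", "stationary")


def stepwise_update(estimate: float, reward: float, tau: float) -> float:
    """One step of the low-pass filter: (1-beta)*old + beta*R, beta = 1/(1+tau)."""
    if tau < 0:
        raise ValueError(f"tau must be nonnegative, got {tau}")
    beta = 1.0 / (1.0 + tau)
    return (1.0 - beta) * estimate + beta * reward


def trial_update(estimate: float, reward: float, duration: float, tau: float) -> float:
    """Cumulative end-of-trial update equivalent to ``duration`` step-wise
    updates with the reward smoothed uniformly over the trial.

    Resolving the geometric series gives
    ``(1-beta)^T * old + (1 - (1-beta)^T) * (R/T)``.
    """
    if duration <= 0:
        raise ValueError(f"trial duration must be positive, got {duration}")
    if tau < 0:
        raise ValueError(f"tau must be nonnegative, got {tau}")
    beta = 1.0 / (1.0 + tau)
    decay = (1.0 - beta) ** duration
    return decay * estimate + (1.0 - decay) * (reward / duration)


def effective_tau(tau_base: float, t_sys: float, t_track: float, nu: float) -> float:
    """Context integration time shrunk by the tracking cost.

    Q = t_sys / t_track is the timescale-mismatch ratio; the filter runs at
    tau_base / (1 + Q^nu), which lies in (0, tau_base].  Larger mismatch (a
    system faster than the current tracking timescale) shrinks tau more, so
    adaptation speeds up exactly when tracking is most stale.
    """
    if t_track <= 0:
        raise ValueError(f"t_track must be positive, got {t_track}")
    if nu < 0:
        raise ValueError(f"nu must be nonnegative, got {nu}")
    q = t_sys / t_track
    return tau_base / (1.0 + q**nu)


@dataclass(frozen=True)
class FilterState:
    """Running performance estimates of a PGD agent.

    rho_long / rho_context are reward-rate estimates (reward per step) on the
    long and context timescales; t_track is the filtered trial duration used
    as the tracking timescale; offset is the trial-aware cost offset
    (rho_context - rho_long) * T_prev recomputed after every trial.
    """

    tau_long: float = 2.0e4
    tau_context_base: float = 1.0e3
    K: float = 1.0
    nu: float = 4.0
    rho_long: float = 0.0
    rho_context: float = 0.0
    t_track: float = 0.0
    offset: float = 0.0
    n_trials: int = 0
    offset_noise_sd: float = 0.0

    def snapshot(self) -> dict:
        return {
            "tau_long": self.tau_long,
            "tau_context_base": self.tau_context_base,
            "K": self.K,
            "nu": self.nu,
            "rho_long": self.rho_long,
            "rho_context": self.rho_context,
            "t_track": self.t_track,
            "offset": self.offset,
            "n_trials": self.n_trials,
        }

    def to_json(self) -> str:
        return json.dumps(self.snapshot())


def advance(state: FilterState, reward: float, duration: float, rng=None) -> FilterState:
    """Incorporate one completed trial into the filter state.

    ``reward`` should be the expected reward at decision (the agent is assumed
    to have learned it); it is scaled by K before entering the performance
    filters.  The long filter runs at tau_long, the context filter at an
    effective tau shrunk by the tracking cost with T_sys = this trial's
    duration, and the duration filter at the base context tau.  The first
    trial seeds every filter with its own sample instead of relaxing from 0.
    """
    if duration <= 0:
        raise ValueError(f"trial duration must be positive, got {duration}")
    r = state.K * reward
    if state.n_trials == 0:
        rho_long = r / duration
        rho_context = r / duration
        t_track = duration
    else:
        rho_long = trial_update(state.rho_long, r, duration, state.tau_long)
        tau_eff = effective_tau(
            state.tau_context_base, duration, state.t_track, state.nu
        )
        rho_context = trial_update(state.rho_context, r, duration, tau_eff)
        t_track = trial_update(
            state.t_track, duration * duration, duration, state.tau_context_base
        )
    offset = (rho_context - rho_long) * duration
    if state.offset_noise_sd > 0.0 and rng is not None:
        offset += state.offset_noise_sd * rng.standard_normal()
    return replace(
        state,
        rho_long=rho_long,
        rho_context=rho_context,
        t_track=t_track,
        offset=offset,
        n_trials=state.n_trials + 1,
    )


def deliberation_cost(state: FilterState, t: float, mode: str = "trial_aware") -> float:
    """Opportunity cost of having deliberated up to within-trial time t."""
    if t < 0:
        raise ValueError(f"t must be nonnegative, got {t}")
    if mode == "trial_aware":
        return state.rho_long * t + state.offset
    if mode == "trial_unaware":
        return state.rho_context * t
    if mode == "stationary":
        return state.rho_long * t
    raise ValueError(f"unknown deliberation-cost mode {mode!r}; use one of {COST_MODES}")
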