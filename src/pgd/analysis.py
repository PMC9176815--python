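"""Analytics shared by model and data.

Survival surfaces (visit-debiased summaries of the action policy),
context-switch-aligned decision-time averages, reward-rate accounting for
reaction-time tasks, urgency-curve prediction from fitted agents, and the
filter error-scaling experiment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agent import PgdParams, TrialLog, run_session
from .tokens.env import ContextSchedule

__all__ = [
    "SurvivalSurface",
    "SwitchAlignedSeries",
    "survival_surface",
    "switch_aligned_means",
    "reward_rate_accounting",
    "predict_urgency",
    "error_scaling",
]


@dataclass
class SurvivalSurface:
    """P(t < t_dec | N_t = n, t) on the lattice, with per-cell visit counts.

    Cells never visited are NaN (missing), never imputed as zero.
    """

    survival: np.ndarray  # [n + t_max, t]
    counts: np.ndarray
    t_max: int

    def at(self, n: int, t: int) -> float:
        return float(self.survival[n + self.t_max, t])

    def half_contour(self, n_values=None) -> dict[int, float]:
        """Per-n earliest time at which survival drops to 0.5 (interpolated).

        Only n with a crossing inside the observed range are returned.
        """
        out = {}
        ns = n_values if n_values is not None else range(-self.t_max, self.t_max + 1)
        for n in ns:
            row = self.survival[n + self.t_max]
            prev_t, prev_v = None, None
            for t in range(self.t_max + 1):
                v = row[t]
                if np.isnan(v):
                    continue
                if v <= 0.5:
                    if prev_v is None or prev_v <= 0.5:
                        out[n] = float(t)
                    else:
                        frac = (prev_v - 0.5) / (prev_v - v)
                        out[n] = prev_t + frac * (t - prev_t)
                    break
                prev_t, prev_v = t, v
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in range(self.t_max + 1):
            for n in range(-t, t + 1, 2):
                c = self.counts[n + self.t_max, t]
                if c > 0:
                    rows.append(
                        {"n": n, "t": t,
                         "survival": self.survival[n + self.t_max, t],
                         "count": int(c)}
                    )
        return pd.DataFrame(rows)


def survival_surface(log: TrialLog, walks: np.ndarray | None = None) -> SurvivalSurface:
    """Visit-normalized conditional survival of the no-decision-yet event.

    Needs every trial's full walk: visits at (n, t) are counted along the
    whole walk (the token stream continues past the report), and the survival
    cell is the fraction of those visits that occurred before the trial's
    decision.  Decision times are used at token-step resolution.
    """
    walks = walks if walks is not None else log.walks
    if walks is None:
        raise ValueError("survival surface requires per-trial walks to de-bias visits")
    walks = np.asarray(walks)
    t_max = walks.shape[1]
    partial = np.concatenate(
        [np.zeros((len(walks), 1), dtype=int), np.cumsum(walks, axis=1)], axis=1
    )
    t_dec = log.frame.t_dec.to_numpy()
    counts = np.zeros((2 * t_max + 1, t_max + 1))
    alive = np.zeros_like(counts)
    for t in range(t_max + 1):
        idx = partial[:, t] + t_max
        np.add.at(counts, (idx, t), 1.0)
        np.add.at(alive, (idx[t < t_dec], t), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        surv = np.where(counts > 0, alive / np.maximum(counts, 1), np.nan)
    return SurvivalSurface(survival=surv, counts=counts, t_max=t_max)


@dataclass
class SwitchAlignedSeries:
    """Mean decision times around context switches, per event type."""

    offsets: np.ndarray  # -window..window-1, switch at offset 0
    mean: dict[str, np.ndarray]  # keys 'slow_to_fast', 'fast_to_slow'
    se: dict[str, np.ndarray]
    n_events: dict[str, int]

    def stacked(self) -> np.ndarray:
        """Concatenated mean series (slow_to_fast then fast_to_slow)."""
        return np.concatenate(
            [self.mean["slow_to_fast"], self.mean["fast_to_slow"]]
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ev in ("slow_to_fast", "fast_to_slow"):
            for off, m, s in zip(self.offsets, self.mean[ev], self.se[ev]):
                rows.append(
                    {"offset": int(off), "event_type": ev, "mean": m, "se": s,
                     "n_events": self.n_events[ev]}
                )
        return pd.DataFrame(rows)


def switch_aligned_means(
    log: TrialLog | pd.DataFrame,
    schedule: ContextSchedule,
    window: int = 20,
) -> SwitchAlignedSeries:
    """Average decision times in a fixed trial window around each switch type.

    Windows extending past the session edges are truncated (those trials
    simply do not contribute to the event average).
    """
    frame = log.frame if isinstance(log, TrialLog) else log
    t_dec = frame.t_dec.to_numpy(dtype=float)
    n = len(t_dec)
    offsets = np.arange(-window, window)
    events = schedule.switch_events()
    if not events:
        raise ValueError("schedule contains no context switches")
    # the final block is routinely cut short by the session end; only whole
    # interior blocks shorter than the window merit a warning
    block_lengths = np.diff(schedule.block_bounds)
    if len(block_lengths) and window > block_lengths.min():
        warnings.warn(
            f"alignment window ({window}) exceeds the shortest block "
            f"({int(block_lengths.min())} trials); windows overlap "
            "neighbouring blocks",
            stacklevel=2,
        )
    acc = {
        "slow_to_fast": np.zeros(2 * window),
        "fast_to_slow": np.zeros(2 * window),
    }
    cnt = {k: np.zeros(2 * window) for k in acc}
    n_events = {k: 0 for k in acc}
    for idx, a_before, a_after in events:
        ev = "slow_to_fast" if a_after > a_before else "fast_to_slow"
        n_events[ev] += 1
        pos = idx + offsets
        ok = (pos >= 0) & (pos < n)
        acc[ev][ok] += t_dec[pos[ok]]
        cnt[ev][ok] += 1
    mean, se = {}, {}
    for ev in acc:
        with np.errstate(invalid="ignore", divide="ignore"):
            mean[ev] = np.where(cnt[ev] > 0, acc[ev] / np.maximum(cnt[ev], 1), np.nan)
        # spread of per-event samples around the mean
        sq = np.zeros(2 * window)
        for idx, a_before, a_after in events:
            this = "slow_to_fast" if a_after > a_before else "fast_to_slow"
            if this != ev:
                continue
            pos = idx + offsets
            ok = (pos >= 0) & (pos < n)
            sq[ok] += (t_dec[pos[ok]] - mean[ev][ok]) ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            se[ev] = np.where(
                cnt[ev] > 1, np.sqrt(sq / np.maximum(cnt[ev] - 1, 1) / np.maximum(cnt[ev], 1)), np.nan
            )
    return SwitchAlignedSeries(offsets=offsets, mean=mean, se=se, n_events=n_events)


def reward_rate_accounting(
    accuracy: float, t_response: float, penalty: float, iti: float
) -> float:
    """Reward rate of a reaction-time task from its aggregate statistics.

    rate = accuracy / (t_response + (1 - accuracy) * penalty + iti): the trial
    time is the response time, plus the time penalty weighted by the error
    rate, plus the inter-trial interval.  Times in seconds give a rate in
    rewards per second.
    """
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError(f"accuracy={accuracy} outside [0, 1]")
    if min(t_response, penalty, iti) < 0:
        raise ValueError("times must be nonnegative")
    denom = t_response + (1.0 - accuracy) * penalty + iti
    if denom == 0:
        raise ZeroDivisionError("trial time is zero")
    return accuracy / denom


def predict_urgency(
    params: PgdParams,
    schedule: ContextSchedule,
    seed=None,
    t_max: int = 15,
    mode: str = "trial_aware",
    burn_in: int = 100,
    **session_kwargs,
) -> pd.DataFrame:
    """Context-conditioned mean +/- sd deliberation-cost curves.

    Runs the agent on the alpha sequence, reconstructs each trial's within-
    trial cost line C_del(t) = offset + rho_long * t from the filter history,
    and aggregates by context.  Output columns: t, context, mean, sd (cost
    units; any affine map to firing rate is presentation-only).
    """
    log = run_session(
        schedule, params, t_max=t_max, mode=mode, seed=seed,
        record_filters=True, **session_kwargs,
    )
    filters: pd.DataFrame = log.meta["filters"]
    # the cost curve of trial k is built from the state *entering* trial k
    rho = np.concatenate([[0.0], filters.rho_long.to_numpy()[:-1]])
    off = np.concatenate([[0.0], filters.offset.to_numpy()[:-1]])
    alphas = log.frame.alpha.to_numpy()
    ts = np.arange(t_max + 1)
    rows = []
    keep = np.arange(len(log)) >= burn_in
    for alpha in np.unique(alphas):
        sel = keep & (alphas == alpha)
        curves = off[sel, None] + rho[sel, None] * ts[None, :]
        rows.extend(
            {"t": int(t), "context": float(alpha),
             "mean": float(curves[:, t].mean()), "sd": float(curves[:, t].std())}
            for t in ts
        )
    return pd.DataFrame(rows)


def error_scaling(
    tau_long_grid,
    t_block_grid,
    seeds,
    params_base: PgdParams | None = None,
    measure_blocks: int = 20,
    burn_in_taus: float = 3.0,
    **session_kwargs,
) -> tuple[float, pd.DataFrame]:
    """Scaling of the long filter's estimation error with T_block / tau_long.

    For each (tau_long, T_block) cell and seed, runs a periodic-schedule
    session (burn-in of ``burn_in_taus`` filter timescales, then an integer
    number of block periods), measures the mean unsigned deviation of
    rho_long from its period-averaged value, and regresses log(error) on
    log(tau_long / T_block).  In the T_block << tau_long regime the
    within-block relaxation is linear and the residual zigzag deviation
    scales as T_block / tau_long, i.e. slope -1.
    """
    from .tokens.env import make_schedule

    params_base = params_base or PgdParams()
    rows = []
    for tau_long in tau_long_grid:
        for t_block in t_block_grid:
            # ~17 steps per trial at the default task parameters
            burn_in_trials = int(np.ceil(burn_in_taus * tau_long / 17.0))
            burn_in_trials = ((burn_in_trials // t_block) + 1) * t_block
            n_trials = burn_in_trials + measure_blocks * t_block
            devs = []
            params = PgdParams(
                tau_long=tau_long, tau_context=params_base.tau_context,
                K=params_base.K, nu=params_base.nu,
            )
            for seed in seeds:
                sched = make_schedule("periodic", n_trials=n_trials,
                                      t_block=t_block)
                log = run_session(sched, params, seed=seed, record_filters=True,
                                  **session_kwargs)
                filters = log.meta["filters"]
                rho_hat = filters.rho_long.to_numpy()[burn_in_trials:]
                # period-averaged value estimates the stationary rate the
                # filter is tracking (whole periods -> unbiased)
                devs.append(np.abs(rho_hat - rho_hat.mean()).mean())
            rows.append(
                {"tau_long": tau_long, "t_block": t_block,
                 "ratio": tau_long / t_block, "mean_abs_dev": float(np.mean(devs))}
            )
    frame = pd.DataFrame(rows)
    slope = float(
        np.polyfit(np.log(frame.ratio), np.log(frame.mean_abs_dev), 1)[0]
    )
    return slope, frame
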