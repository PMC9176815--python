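"""Fitting a PGD agent to observed decision-time dynamics.

The observable used for fitting is the pair of context-switch-aligned mean
decision-time series (slow-to-fast and fast-to-slow events): baselines and
relaxation after switches identify the context timescale, the reward scale
and the tracking-cost sensitivity, while the dependence on the long
timescale is intentionally weak.  The model series is obtained by running
the PGD agent on the *same* alpha sequence as the data with model-generated
walks (several repetitions average out walk noise), and the uniformly
weighted squared error between the two stacked series is minimized with
Nelder-Mead on log-transformed parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .agent import PgdParams, TrialLog, run_session
from .analysis import SwitchAlignedSeries, predict_urgency, switch_aligned_means
from .tokens.env import ContextSchedule

__all__ = ["PGDBehaviourModel", "PGDBehaviourResults", "fit_pgd"]

_PARAM_NAMES = ("tau_long", "tau_context", "K", "nu")


@dataclass
class PGDBehaviourResults:
    """Container for a fitted PGD behavioural model."""

    model: "PGDBehaviourModel"
    params: PgdParams
    loss: float
    converged: bool
    n_iter: int
    n_fev: int
    start_params: PgdParams
    aligned_data: SwitchAlignedSeries
    aligned_model: SwitchAlignedSeries = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            "PGD behavioural fit",
            "=" * 46,
            f"{'trials':<22}{len(self.model.log):>24}",
            f"{'switch events':<22}{self.model.n_events:>24}",
            f"{'window (trials)':<22}{self.model.window:>24}",
            f"{'loss (MSE, steps^2)':<22}{self.loss:>24.6f}",
            f"{'converged':<22}{str(self.converged):>24}",
            f"{'iterations':<22}{self.n_iter:>24}",
            "-" * 46,
            f"{'parameter':<14}{'estimate':>16}{'start':>16}",
        ]
        for name in _PARAM_NAMES:
            lines.append(
                f"{name:<14}{getattr(self.params, name):>16.4g}"
                f"{getattr(self.start_params, name):>16.4g}"
            )
        lines.append("=" * 46)
        return "\n".join(lines)

    def predict_urgency(self, seed=None, **kwargs) -> pd.DataFrame:
        """Context-conditioned deliberation-cost curves of the fitted agent."""
        return predict_urgency(
            self.params, self.model.schedule, seed=seed, **{**self.model.session_kwargs, **kwargs}
        )

    def to_json_dict(self) -> dict:
        return {
            "params": {n: getattr(self.params, n) for n in _PARAM_NAMES},
            "loss": self.loss,
            "iterations": self.n_iter,
            "n_fev": self.n_fev,
            "converged": self.converged,
        }


class PGDBehaviourModel:
    """Fits the four PGD parameters to a session's decision-time dynamics.

    Parameters
    ----------
    log : TrialLog or DataFrame
        Observed session with per-trial decision times.
    schedule : ContextSchedule
        The alpha sequence the subject experienced (switch events are read
        from it).
    window : int
        Trials kept on each side of a switch for the aligned averages.
    n_reps : int
        Model repetitions per objective evaluation (walk-noise averaging).
    """

    def __init__(
        self,
        log: TrialLog | pd.DataFrame,
        schedule: ContextSchedule,
        window: int = 20,
        n_reps: int = 5,
        seed: int = 0,
        **session_kwargs,
    ) -> None:
        self.log = log if isinstance(log, TrialLog) else TrialLog(frame=log)
        self.schedule = schedule
        self.window = window
        self.n_reps = n_reps
        self.seed = seed
        self.session_kwargs = session_kwargs
        self.aligned_data = switch_aligned_means(self.log, schedule, window)
        self.n_events = sum(self.aligned_data.n_events.values())
        self._target = self.aligned_data.stacked()

    @classmethod
    def from_csv(cls, log_path, schedule_path, **kwargs) -> "PGDBehaviourModel":
        from .io import read_trial_log

        log = read_trial_log(log_path)
        schedule = ContextSchedule.from_csv(schedule_path)
        return cls(log, schedule, **kwargs)

    def model_series(self, params: PgdParams) -> SwitchAlignedSeries:
        """Switch-aligned series of the agent at ``params``.

        Uses common random numbers (seeds fixed per repetition) so the
        objective is deterministic in the parameters.
        """
        stacked, last = None, None
        for rep in range(self.n_reps):
            log = run_session(
                self.schedule, params, seed=self.seed + rep, **self.session_kwargs
            )
            last = switch_aligned_means(log, self.schedule, self.window)
            s = last.stacked()
            stacked = s if stacked is None else stacked + s
        mean_stacked = stacked / self.n_reps
        w = 2 * self.window
        return SwitchAlignedSeries(
            offsets=last.offsets,
            mean={
                "slow_to_fast": mean_stacked[:w],
                "fast_to_slow": mean_stacked[w:],
            },
            se=last.se,
            n_events=last.n_events,
        )

    def loss_at(self, params: PgdParams) -> float:
        pred = self.model_series(params).stacked()
        ok = ~np.isnan(self._target) & ~np.isnan(pred)
        return float(np.mean((pred[ok] - self._target[ok]) ** 2))

    def fit(
        self,
        start_params: PgdParams | None = None,
        maxiter: int = 120,
        xatol: float = 0.02,
        fatol: float = 1e-3,
        initial_simplex_scale: float = 0.35,
    ) -> PGDBehaviourResults:
        """Minimize the aligned-series squared error with Nelder-Mead.

        The simplex operates on log-parameters (all four are positive); a
        non-converged optimizer yields a flagged result, not an exception.
        """
        start = start_params or PgdParams(
            tau_long=5e3, tau_context=200.0, K=1.0, nu=2.0
        )
        x0 = np.log([start.tau_long, start.tau_context, start.K, start.nu])

        def unpack(x: np.ndarray) -> PgdParams:
            tau_long, tau_context, K, nu = np.exp(x)
            return PgdParams(tau_long=tau_long, tau_context=tau_context, K=K, nu=nu)

        def objective(x: np.ndarray) -> float:
            return self.loss_at(unpack(x))

        simplex = [x0]
        for i in range(4):
            v = x0.copy()
            v[i] += initial_simplex_scale
            simplex.append(v)
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={
                "maxiter": maxiter,
                "xatol": xatol,
                "fatol": fatol,
                "initial_simplex": np.array(simplex),
            },
        )
        params = unpack(res.x)
        return PGDBehaviourResults(
            model=self,
            params=params,
            loss=float(res.fun),
            converged=bool(res.success),
            n_iter=int(res.nit),
            n_fev=int(res.nfev),
            start_params=start,
            aligned_data=self.aligned_data,
            aligned_model=self.model_series(params),
        )


def fit_pgd(
    observed_log,
    schedule: ContextSchedule,
    init: PgdParams | None = None,
    **options,
) -> PGDBehaviourResults:
    """Functional wrapper: fit PGD parameters to an observed trial log."""
    model_kwargs = {
        k: options.pop(k)
        for k in ("window", "n_reps", "seed", "t_max", "p", "t_iti", "mode")
        if k in options
    }
    model = PGDBehaviourModel(observed_log, schedule, **model_kwargs)
    return model.fit(start_params=init, **options)
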