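"""Formats, configuration and the synthetic-fixture generator.

Interchange formats are deliberately plain: CSV with mandatory headers for
trial logs, walks and schedules; JSON for configs and fit results.  All
randomness flows from a single seeded generator per run.  Times are stored
in steps; an optional clearly-labelled seconds column can be added on
export.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .agent import PgdParams, TrialLog, run_session
from .tokens.env import (
    DEFAULT_ALPHAS,
    DEFAULT_T_ITI,
    DEFAULT_T_MAX,
    STEP_SECONDS,
    ContextSchedule,
    make_schedule,
)

__all__ = [
    "TrialLogError",
    "read_trial_log",
    "write_trial_log",
    "read_walks",
    "write_walks",
    "RunConfig",
    "generate_fixture",
]

_REQUIRED_COLUMNS = ["trial", "alpha", "t_dec", "n_dec", "report", "reward", "duration"]


class TrialLogError(ValueError):
    """Malformed trial-log content, reported with the offending row."""


class ScheduleConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: str = "periodic"
    n_trials: int = 1200
    t_block: int = 300
    block_bounds: tuple[int, int] = (50, 550)
    alpha_sequence_path: str | None = None


class AgentConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: str = "pgd"  # 'pgd' or 'arrl'
    tau_long: float = 2.0e4
    tau_context: float = 1.0e3
    K: float = 1.0
    nu: float = 4.0
    mode: str = "trial_aware"
    c: float = 0.0  # AR-RL auxiliary cost rate
    offset_noise_sd: float = 0.0


class TaskSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    t_max: int = DEFAULT_T_MAX
    p: float = 0.5
    t_iti: float = DEFAULT_T_ITI
    alphas: tuple[float, float] = DEFAULT_ALPHAS
    gamma: float = 0.0  # payoff asymmetry


class RunConfig(BaseModel):
    """Schema-validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    task: TaskSection = Field(default_factory=TaskSection)
    agent: AgentConfig = Field(default_factory=AgentConfig)
    schedule: ScheduleConfig = Field(default_factory=ScheduleConfig)
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.model_dump_json(indent=2))

    def build_schedule(self, rng=None) -> ContextSchedule:
        s = self.schedule
        if s.kind == "custom":
            return ContextSchedule.from_csv(s.alpha_sequence_path)
        return make_schedule(
            s.kind,
            n_trials=s.n_trials,
            alphas=self.task.alphas,
            t_block=s.t_block,
            block_bounds_range=s.block_bounds,
            rng=rng if rng is not None else self.seed,
        )


def write_trial_log(log: TrialLog, path, seconds_column: bool = False) -> None:
    frame = log.frame.copy()
    if seconds_column:
        frame["duration_seconds"] = frame["duration"] * STEP_SECONDS
    frame.to_csv(path, index=False)


def read_trial_log(path, t_max: int = DEFAULT_T_MAX, walks_path=None) -> TrialLog:
    """Read and validate a trial-log CSV.

    Validation: header presence, decision-time bounds, n/t parity, duration
    bounds.  Extra columns are preserved as opaque metadata (tolerant-reader
    policy); malformed rows are reported with their line numbers.
    """
    frame = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise TrialLogError(f"{path}: missing required columns {missing}")
    extras = [c for c in frame.columns if c not in _REQUIRED_COLUMNS]
    for col in ("trial", "t_dec", "n_dec", "report"):
        frame[col] = frame[col].astype(int)
    bad = []
    t_dec = frame.t_dec.to_numpy()
    n_dec = frame.n_dec.to_numpy()
    dur = frame.duration.to_numpy()
    for i in range(len(frame)):
        # +2 -> 1-based line number under the header
        if not (0 <= t_dec[i] <= t_max):
            bad.append(f"line {i + 2}: t_dec={t_dec[i]} outside [0, {t_max}]")
        elif (t_dec[i] - n_dec[i]) % 2 != 0 or abs(n_dec[i]) > t_dec[i]:
            bad.append(f"line {i + 2}: n_dec={n_dec[i]} invalid at t_dec={t_dec[i]}")
        elif not dur[i] > 0:
            bad.append(f"line {i + 2}: nonpositive duration")
    if bad:
        raise TrialLogError(f"{path}: " + "; ".join(bad[:10]))
    meta = {"t_max": t_max, "extra_columns": frame[extras] if extras else None}
    walks = read_walks(walks_path) if walks_path else None
    return TrialLog(frame=frame[_REQUIRED_COLUMNS], walks=walks, meta=meta)


def write_walks(walks: np.ndarray, path) -> None:
    cols = [f"s{t + 1}" for t in range(walks.shape[1])]
    df = pd.DataFrame(np.asarray(walks), columns=cols)
    df.insert(0, "trial", np.arange(len(df)))
    df.to_csv(path, index=False)


def read_walks(path) -> np.ndarray:
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c.startswith("s")]
    walks = df[cols].to_numpy(dtype=int)
    if not np.isin(walks, (-1, 1)).all():
        raise TrialLogError(f"{path}: walk entries must be +/-1")
    return walks


def generate_fixture(
    style: str = "irregular-nhp-like",
    n_trials: int = 3000,
    params: PgdParams | None = None,
    lapse_prob: float = 0.0,
    seed: int = 0,
    t_block: int = 300,
    block_bounds: tuple[int, int] = (50, 250),
    **session_kwargs,
) -> tuple[TrialLog, ContextSchedule]:
    """Synthetic behaviour emulating an alternating-block session.

    A ground-truth PGD agent plays the schedule; optional lapse noise
    replaces each decision time with a uniform draw with probability
    ``lapse_prob`` (the report is re-read from the walk at the lapsed time).
    Ground-truth parameters are embedded in the log metadata for recovery
    experiments.
    """
    if style not in ("periodic", "irregular-nhp-like"):
        raise ValueError(f"unknown fixture style {style!r}")
    params = params or PgdParams(tau_long=5e3, tau_context=50.0, K=1.2, nu=4.0)
    rng = np.random.default_rng(seed)
    kind = "periodic" if style == "periodic" else "irregular"
    schedule = make_schedule(
        kind, n_trials=n_trials, t_block=t_block,
        block_bounds_range=block_bounds, rng=rng,
    )
    log = run_session(schedule, params, seed=rng, **session_kwargs)
    if lapse_prob > 0.0:
        t_max = log.t_max
        frame = log.frame
        partial = np.concatenate(
            [np.zeros((len(frame), 1), dtype=int), np.cumsum(log.walks, axis=1)],
            axis=1,
        )
        lapse = rng.random(len(frame)) < lapse_prob
        new_t = rng.integers(0, t_max + 1, size=len(frame))
        for i in np.flatnonzero(lapse):
            t = int(new_t[i])
            n = int(partial[i, t])
            report = int(np.sign(n)) or (1 if rng.random() < 0.5 else -1)
            final = int(partial[i, t_max])
            frame.loc[i, ["t_dec", "n_dec", "report"]] = (t, n, report)
            frame.loc[i, "reward"] = float(report * final > 0)
            frame.loc[i, "duration"] = (
                t + (1.0 - frame.loc[i, "alpha"]) * (t_max - t) + DEFAULT_T_ITI
            )
    log.meta["ground_truth"] = {
        "tau_long": params.tau_long,
        "tau_context": params.tau_context,
        "K": params.K,
        "nu": params.nu,
        "lapse_prob": lapse_prob,
        "style": style,
        "seed": seed,
    }
    return log, schedule
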