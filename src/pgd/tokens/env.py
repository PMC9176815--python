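"""Generative tokens-task environment.

Evidence walks are i.i.d. Bernoulli jump sequences; contexts are blocks of
trials sharing an incentive strength alpha, which contracts the post-decision
jump interval by a factor (1 - alpha) and so controls how much time an early
report saves.  Time is measured in token-jump steps (one step = 200 ms in the
primate experiments); durations are kept in steps throughout and converted to
seconds only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beliefs import PayoffMatrix

__all__ = [
    "WalkRealization",
    "ContextSchedule",
    "TrialRecord",
    "sample_walk",
    "trial_duration",
    "trial_outcome",
    "make_schedule",
    "DEFAULT_T_MAX",
    "DEFAULT_T_ITI",
    "DEFAULT_ALPHAS",
    "STEP_SECONDS",
]

DEFAULT_T_MAX = 15
DEFAULT_T_ITI = 7.5
DEFAULT_ALPHAS = (0.25, 0.75)  # slow, fast
STEP_SECONDS = 0.2


@dataclass(frozen=True)
class WalkRealization:
    """One trial's evidence: jump sequence and cumulative token difference."""

    jumps: np.ndarray  # shape (t_max,), entries in {-1, +1}
    partial_sums: np.ndarray  # shape (t_max + 1,), N_0 = 0

    @property
    def t_max(self) -> int:
        return len(self.jumps)

    def n_at(self, t: int) -> int:
        return int(self.partial_sums[t])

    @property
    def final_sign(self) -> int:
        return int(np.sign(self.partial_sums[-1]))


def sample_walk(
    t_max: int = DEFAULT_T_MAX,
    p: float = 0.5,
    rng: np.random.Generator | int | None = None,
) -> WalkRealization:
    """Sample an i.i.d. Bernoulli jump sequence with P(S = +1) = p."""
    if t_max % 2 == 0 or t_max < 1:
        raise ValueError(f"t_max must be odd and positive, got {t_max}")
    if not 0.5 <= p <= 1.0:
        raise ValueError(f"p must lie in [1/2, 1], got {p}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    jumps = np.where(rng.random(t_max) < p, 1, -1)
    partial = np.concatenate([[0], np.cumsum(jumps)])
    return WalkRealization(jumps=jumps, partial_sums=partial)


def trial_duration(
    t_dec: float,
    alpha: float,
    t_max: int = DEFAULT_T_MAX,
    t_iti: float = DEFAULT_T_ITI,
) -> float:
    """Trial duration in steps: t_dec + (1 - alpha)(t_max - t_dec) + T_ITI.

    The remaining jumps after the report play out at the contracted interval;
    the inter-trial interval is a fixed dead time.
    """
    if not 0 <= t_dec <= t_max:
        raise ValueError(f"t_dec={t_dec} outside [0, {t_max}]")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha={alpha} outside [0, 1]")
    return t_dec + (1.0 - alpha) * (t_max - t_dec) + t_iti


def trial_outcome(
    walk: WalkRealization, t_dec: int, report: int, payoff: PayoffMatrix | None = None
) -> float:
    """Reward for the trial: payoff entry indexed by (sign(N_tmax), report)."""
    if report not in (-1, 1):
        raise ValueError(f"report must be +1 or -1, got {report}")
    payoff = payoff or PayoffMatrix.identity()
    s_row = 0 if walk.final_sign > 0 else 1
    a_col = 0 if report > 0 else 1
    return float(payoff.array[s_row, a_col])


@dataclass
class ContextSchedule:
    """Per-trial incentive strengths with block structure."""

    alphas: np.ndarray  # shape (n_trials,)
    block_bounds: np.ndarray = field(default=None)  # trial indices where a new block starts
    t_block: float | None = None  # characteristic block length in trials

    def __post_init__(self) -> None:
        self.alphas = np.asarray(self.alphas, dtype=float)
        if len(self.alphas) == 0:
            raise ValueError("schedule must contain at least one trial")
        if self.block_bounds is None:
            switches = np.flatnonzero(np.diff(self.alphas) != 0) + 1
            self.block_bounds = np.concatenate([[0], switches])
        else:
            self.block_bounds = np.asarray(self.block_bounds, dtype=int)

    def __len__(self) -> int:
        return len(self.alphas)

    @property
    def n_blocks(self) -> int:
        return len(self.block_bounds)

    def switch_events(self) -> list[tuple[int, float, float]]:
        """(trial index, alpha before, alpha after) for each context switch."""
        out = []
        for b in self.block_bounds[1:]:
            out.append((int(b), float(self.alphas[b - 1]), float(self.alphas[b])))
        return out

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"trial": np.arange(len(self.alphas)), "alpha": self.alphas}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ContextSchedule":
        df = pd.read_csv(path)
        return cls(alphas=df["alpha"].to_numpy())


def make_schedule(
    kind: str,
    n_trials: int | None = None,
    alphas: tuple[float, float] = DEFAULT_ALPHAS,
    t_block: int = 300,
    block_bounds_range: tuple[int, int] = (50, 550),
    alpha_sequence: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
) -> ContextSchedule:
    """Build a context schedule.

    kind='periodic': alternate between the two alphas every ``t_block`` trials.
    kind='irregular': block lengths drawn uniformly from
        ``block_bounds_range`` (inclusive), emulating experimenter-driven
        irregular sessions.
    kind='custom': use ``alpha_sequence`` verbatim.
    """
    if kind == "custom":
        if alpha_sequence is None or len(alpha_sequence) == 0:
            raise ValueError("custom schedule requires a non-empty alpha_sequence")
        return ContextSchedule(alphas=np.asarray(alpha_sequence, dtype=float))
    if n_trials is None or n_trials < 1:
        raise ValueError("n_trials must be a positive integer")
    for a in alphas:
        if not 0.0 <= a <= 1.0:
            raise ValueError(f"alpha={a} outside [0, 1]")
    if kind == "periodic":
        seq = np.empty(n_trials)
        for start in range(0, n_trials, t_block):
            seq[start : start + t_block] = alphas[(start // t_block) % 2]
        return ContextSchedule(alphas=seq, t_block=float(t_block))
    if kind == "irregular":
        rng = (
            np.random.default_rng(rng)
            if not isinstance(rng, np.random.Generator)
            else rng
        )
        lo, hi = block_bounds_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid block length bounds {block_bounds_range}")
        seq, i, which = np.empty(n_trials), 0, 0
        while i < n_trials:
            length = int(rng.integers(lo, hi + 1))
            seq[i : i + length] = alphas[which % 2]
            i += length
            which += 1
        return ContextSchedule(alphas=seq, t_block=(lo + hi) / 2.0)
    raise ValueError(f"unknown schedule kind {kind!r}")


@dataclass(frozen=True)
class TrialRecord:
    """One completed trial of a session."""

    k: int
    alpha: float
    t_dec: int
    n_dec: int
    report: int
    reward: float
    duration: float
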