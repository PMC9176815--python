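"""Probabilistic machinery of the tokens task.

A trial of the tokens task presents an unbiased (or biased, ``p > 1/2``)
random walk of token jumps.  The state relevant for prediction is the token
difference ``n`` at step ``t``; the agent's belief about the final sign of the
walk is a binomial tail probability over the remaining ``t' = t_max - t``
jumps.  This module computes that success probability exactly, its sigmoid
approximation, the belief of a correct greedy report, the expected reward
under an arbitrary 2x2 payoff matrix, and the opportunity cost of committing
to a report now rather than with full information.

All quantities live on the parity lattice ``{(n, t): |n| <= t <= t_max,
n = t (mod 2)}``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BeliefTable",
    "PayoffMatrix",
    "SigmoidApprox",
    "success_probability_exact",
    "success_probability_sigmoid",
    "belief",
    "expected_reward",
    "commitment_cost",
    "validate_lattice_point",
]

# exact comb-summation is used below this remaining-step count; beyond it the
# regularized-incomplete-beta tail from scipy keeps the sum overflow-safe
_EXACT_TAIL_LIMIT = 60


class InvalidStateError(ValueError):
    """Raised for (n, t) pairs off the walk's parity lattice."""


def validate_lattice_point(n: int, t: int, t_max: int) -> None:
    if t_max % 2 == 0 or t_max < 1:
        raise InvalidStateError(f"t_max must be odd and positive, got {t_max}")
    if not (0 <= t <= t_max):
        raise InvalidStateError(f"t={t} outside [0, {t_max}]")
    if abs(n) > t:
        raise InvalidStateError(f"|n|={abs(n)} exceeds t={t}")
    if (n - t) % 2 != 0:
        raise InvalidStateError(f"(n={n}, t={t}) violates parity n = t mod 2")


def _binomial_tail(lo: int, trials: int, p: float) -> float:
    """P(Binom(trials, p) >= lo), exact for small trial counts."""
    if lo <= 0:
        return 1.0
    if lo > trials:
        return 0.0
    if trials <= _EXACT_TAIL_LIMIT:
        q = 1.0 - p
        return math.fsum(
            math.comb(trials, k) * p**k * q ** (trials - k)
            for k in range(lo, trials + 1)
        )
    return float(stats.binom.sf(lo - 1, trials, p))


def success_probability_exact(n: int, t: int, t_max: int = 15, p: float = 0.5) -> float:
    """Probability that the walk ends positive, given token difference n at step t.

    This is the binomial tail over the ``t' = t_max - t`` remaining jumps: the
    walk ends positive iff at least ``ceil((t' - n)/2)`` of them are positive.
    Equals 1 exactly when ``n >= t'`` (outcome already determined).
    """
    validate_lattice_point(n, t, t_max)
    if not 0.5 <= p <= 1.0:
        raise ValueError(f"jump probability p must lie in [1/2, 1], got {p}")
    t_rem = t_max - t
    lo = math.ceil((t_rem - n) / 2)
    return _binomial_tail(lo, t_rem, p)


@dataclass(frozen=True)
class SigmoidApprox:
    """Sigmoid approximation of the success probability.

    ``p+(n, t) ~ 1 / (1 + exp(-(a t + b) n))`` — the slope of the sigmoid in n
    grows linearly with trial time.  The default constants are the published
    fit for a 15-step horizon; they are treated as given since no fitting loss
    accompanies them.
    """

    a: float = 0.03725
    b: float = 0.3557

    def __call__(self, n: int, t: int) -> float:
        return 1.0 / (1.0 + math.exp(-(self.a * t + self.b) * n))


def success_probability_sigmoid(
    n: int, t: int, approx: SigmoidApprox | None = None
) -> float:
    approx = approx if approx is not None else SigmoidApprox()
    return approx(n, t)


def belief(n: int, t: int, t_max: int = 15, p: float = 0.5) -> float:
    """Belief of a correct greedy report: max{p+, 1 - p+} in [1/2, 1]."""
    p_plus = success_probability_exact(n, t, t_max, p)
    return max(p_plus, 1.0 - p_plus)


@dataclass(frozen=True)
class PayoffMatrix:
    """2x2 trial payoff, rows indexed by final sign s, columns by report a.

    Layout ``[[r_{+,+}, r_{+,-}], [r_{-,+}, r_{-,-}]]``.  The asymmetric
    variant scales the a=+ column by (1+gamma) and the a=- column by
    (1-gamma), biasing + reports while leaving the total attainable reward
    r_{+,+} + r_{-,-} of the base matrix unchanged in sum.
    """

    entries: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 0.0), (0.0, 1.0))
    gamma: float = 0.0

    @classmethod
    def identity(cls) -> "PayoffMatrix":
        return cls()

    @classmethod
    def asymmetric(
        cls, gamma: float, base: "PayoffMatrix | None" = None
    ) -> "PayoffMatrix":
        if not -1.0 < gamma < 1.0:
            raise ValueError(f"gamma must lie in (-1, 1), got {gamma}")
        b = (base or cls.identity()).entries
        scaled = tuple(
            (row[0] * (1.0 + gamma), row[1] * (1.0 - gamma)) for row in b
        )
        return cls(entries=scaled, gamma=gamma)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.entries, dtype=float)

    @property
    def r_max(self) -> float:
        """A-priori maximum trial reward: best entry achievable with certainty."""
        return float(self.array.max())

    @property
    def delta_r(self) -> float:
        """Spread between the best and worst outcome of the best action."""
        a = self.array
        col = int(np.argmax(a.max(axis=0)))
        return float(a[:, col].max() - a[:, col].min())


def expected_reward(
    n: int,
    t: int,
    t_max: int = 15,
    p: float = 0.5,
    payoff: PayoffMatrix | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, int, np.ndarray]:
    """Expected reward of the best report at (n, t).

    Returns ``(r_bar, a_star, per_action)`` where ``per_action`` is
    ``[p+, 1-p+] @ R`` (entries for a=+ then a=-) and ``a_star`` is +1 or -1.
    Exact ties (e.g. n = 0 under a symmetric payoff) are broken by a uniform
    draw from ``rng`` if given, else deterministically toward +.
    """
    payoff = payoff or PayoffMatrix.identity()
    p_plus = success_probability_exact(n, t, t_max, p)
    per_action = np.array([p_plus, 1.0 - p_plus]) @ payoff.array
    if per_action[0] > per_action[1]:
        a_star = +1
    elif per_action[1] > per_action[0]:
        a_star = -1
    else:
        a_star = +1 if rng is None else (1 if rng.random() < 0.5 else -1)
    return float(per_action.max()), a_star, per_action


def commitment_cost(
    n: int,
    t: int,
    t_max: int = 15,
    p: float = 0.5,
    payoff: PayoffMatrix | None = None,
) -> float:
    """Opportunity cost of committing now: r_max - r_bar_t.

    Decays to 0 at certainty; for the identity payoff and p = 1/2 it starts
    at 1/2 and reaches 0 at t_max.
    """
    payoff = payoff or PayoffMatrix.identity()
    r_bar, _, _ = expected_reward(n, t, t_max, p, payoff)
    return payoff.r_max - r_bar


@dataclass
class BeliefTable:
    """Exact success probabilities p+(n, t) over the full parity lattice.

    Stored sparsely keyed by (n, t); a dense (n-index, t) array is exposed for
    fast in-loop lookups by the agent.
    """

    t_max: int = 15
    p: float = 0.5
    values: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.values:
            for t in range(self.t_max + 1):
                for n in range(-t, t + 1, 2):
                    self.values[(n, t)] = success_probability_exact(
                        n, t, self.t_max, self.p
                    )

    def __getitem__(self, key: tuple[int, int]) -> float:
        n, t = key
        validate_lattice_point(n, t, self.t_max)
        return self.values[(n, t)]

    def dense(self) -> np.ndarray:
        """(2*t_max+1, t_max+1) array indexed [n + t_max, t]; NaN off-lattice."""
        arr = np.full((2 * self.t_max + 1, self.t_max + 1), np.nan)
        for (n, t), v in self.values.items():
            arr[n + self.t_max, t] = v
        return arr

    def commitment_cost_dense(self, payoff: PayoffMatrix | None = None) -> np.ndarray:
        """Dense C_com[n + t_max, t] table for the given payoff."""
        payoff = payoff or PayoffMatrix.identity()
        arr = np.full((2 * self.t_max + 1, self.t_max + 1), np.nan)
        r = payoff.array
        for (n, t), p_plus in self.values.items():
            per_action = np.array([p_plus, 1.0 - p_plus]) @ r
            arr[n + self.t_max, t] = payoff.r_max - per_action.max()
        return arr

    def to_csv(self, path) -> None:
        rows = [
            {"n": n, "t": t, "p_plus": v}
            for (n, t), v in sorted(self.values.items(), key=lambda kv: (kv[0][1], kv[0][0]))
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, t_max: int, p: float = 0.5) -> "BeliefTable":
        df = pd.read_csv(path)
        values = {
            (int(r.n), int(r.t)): float(r.p_plus) for r in df.itertuples(index=False)
        }
        return cls(t_max=t_max, p=p, values=values)

    def lattice_points(self, t_lt: int | None = None):
        """Iterate (n, t) lattice points, optionally restricted to t < t_lt."""
        for (n, t) in sorted(self.values, key=lambda k: (k[1], k[0])):
            if t_lt is None or t < t_lt:
                yield n, t
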