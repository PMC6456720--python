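"""Variable-foreperiod task structure.

The task manipulates temporal predictability in a blocked 2x2 factorial
design: mean foreperiod duration (Short: 1500 ms, Long: 3000 ms) crossed
with foreperiod variability (Low: 100 ms SD, High: 600 ms SD).  Foreperiods
are drawn from Gaussians truncated symmetrically around the mean (500-2500 ms
for the short distributions, 2000-4000 ms for the long ones), which preserves
the nominal mean.  Each cell carries an ordinal temporal-predictability rank
``tp_rank`` from 4 (most predictable: short, low-variability blocks) down to
1 (least predictable: long, high-variability blocks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ForeperiodCondition",
    "make_condition_grid",
    "sample_foreperiod",
    "latin_square",
    "build_session_schedule",
    "generate_training_block",
]

#: tp_rank assignment: duration dominates, then variability.  Uncertainty
#: grows with both the length and the variability of the foreperiod, and the
#: short-duration cells are treated as more predictable than the long ones.
TP_RANKS = {
    ("Short", "Low"): 4,
    ("Short", "High"): 3,
    ("Long", "Low"): 2,
    ("Long", "High"): 1,
}


@dataclass(frozen=True)
class ForeperiodCondition:
    """One cell of the 2x2 foreperiod design (times in ms)."""

    duration_level: str  # "Short" | "Long"
    variability_level: str  # "Low" | "High"
    mu: float
    sigma: float
    lower: float
    upper: float
    tp_rank: int

    def __post_init__(self) -> None:
        if not (self.lower < self.mu < self.upper):
            raise ValueError("truncation bounds must straddle the mean")
        if self.mu - self.lower != self.upper - self.mu:
            raise ValueError("truncation must be symmetric around the mean")

    @property
    def label(self) -> str:
        return f"{self.duration_level}/{self.variability_level}"


def make_condition_grid(tp_ranks: dict[tuple[str, str], int] | None = None) -> list[ForeperiodCondition]:
    """The four foreperiod conditions of the 2x2 design.

    ``tp_ranks`` overrides the default predictability-rank table (it must be a
    bijection onto {1, 2, 3, 4}).
    """
    ranks = dict(TP_RANKS if tp_ranks is None else tp_ranks)
    if sorted(ranks.values()) != [1, 2, 3, 4]:
        raise ValueError("tp_ranks must map the four cells onto {1,2,3,4}")
    cells = [
        ("Short", "Low", 1500.0, 100.0, 500.0, 2500.0),
        ("Short", "High", 1500.0, 600.0, 500.0, 2500.0),
        ("Long", "Low", 3000.0, 100.0, 2000.0, 4000.0),
        ("Long", "High", 3000.0, 600.0, 2000.0, 4000.0),
    ]
    return [
        ForeperiodCondition(d, s, mu, sd, lo, hi, ranks[(d, s)])
        for d, s, mu, sd, lo, hi in cells
    ]


def sample_foreperiod(
    condition: ForeperiodCondition, rng: np.random.Generator, size: int | None = None
):
    """Draw foreperiod(s) in ms from the condition's truncated Gaussian.

    Rejection sampling from the untruncated normal (acceptance >= 0.90 for
    every cell of the design); falls back to inverse-CDF sampling for any
    draws still unresolved after a bounded number of rounds.
    """
    n = 1 if size is None else int(size)
    out = np.empty(n)
    todo = np.arange(n)
    for _ in range(20):
        draws = rng.normal(condition.mu, condition.sigma, size=todo.size)
        ok = (draws >= condition.lower) & (draws <= condition.upper)
        out[todo[ok]] = draws[ok]
        todo = todo[~ok]
        if todo.size == 0:
            break
    if todo.size:  # inverse-CDF fallback, exact
        a = (condition.lower - condition.mu) / condition.sigma
        b = (condition.upper - condition.mu) / condition.sigma
        u = rng.uniform(size=todo.size)
        out[todo] = stats.truncnorm.ppf(u, a, b, loc=condition.mu, scale=condition.sigma)
    return float(out[0]) if size is None else out


def latin_square(n: int = 4) -> np.ndarray:
    """Cyclic n x n Latin square of condition indices (row = session order)."""
    base = np.arange(n)
    return np.array([(base + i) % n for i in range(n)])


def build_session_schedule(
    conditions: list[ForeperiodCondition],
    n_blocks: int,
    n_trials: int,
    order_index: int,
    rng: np.random.Generator,
) -> list[tuple[int, ForeperiodCondition, float, str]]:
    """One session's trial schedule: (block, condition, foreperiod_ms, stimulus).

    Each block runs a single condition throughout; block order follows row
    ``order_index`` of a Latin square; stimulus side is equiprobable
    LEFT/RIGHT, independent across trials.
    """
    if n_blocks != len(conditions):
        raise ValueError("n_blocks must equal the number of conditions")
    square = latin_square(len(conditions))
    if not 0 <= order_index < square.shape[0]:
        raise ValueError(
            f"order_index {order_index} out of range; valid values are 0..{square.shape[0] - 1}"
        )
    schedule = []
    for block, cond_idx in enumerate(square[order_index], start=1):
        cond = conditions[cond_idx]
        fps = sample_foreperiod(cond, rng, size=n_trials)
        sides = np.where(rng.uniform(size=n_trials) < 0.5, "LEFT", "RIGHT")
        for fp, side in zip(fps, sides):
            schedule.append((block, cond, float(fp), str(side)))
    return schedule


def generate_training_block(
    n_trials: int, rng: np.random.Generator, mean_ms: float = 1000.0
) -> list[dict]:
    """Training trials with exponential (non-ageing) foreperiods, mean 1000 ms.

    The flat hazard of the exponential distribution makes elapsed time
    uninformative about stimulus onset, so training induces no condition-
    specific temporal expectations.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    fps = rng.exponential(mean_ms, size=n_trials)
    sides = np.where(rng.uniform(size=n_trials) < 0.5, "LEFT", "RIGHT")
    return [
        {"trial": i + 1, "foreperiod_ms": float(fp), "stimulus": str(s), "training": True}
        for i, (fp, s) in enumerate(zip(fps, sides))
    ]
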