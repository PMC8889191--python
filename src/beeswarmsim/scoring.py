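"""Response scoring, block summaries and signal-detection indices.

The game pays +4 points for a correct judgement, -4 for an error, and a
+2 bonus for a correct judgement made exactly at the optimal array index.
Total points convert to pence one-to-one, floored at zero for payment
(analysis variables keep the raw, possibly negative, score).

Per 20-trial block the analysis variables are earnings, percent correct,
the mean array index at response, the mean absolute log likelihood ratio
and mean observed effect size at response, and the signal-detection
indices d-prime and beta computed from hit and false-alarm rates ("yes"
meaning a true-effect judgement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ScoreRule",
    "ResponseRecord",
    "SdtCounts",
    "BlockSummary",
    "score_response",
    "summarize_block",
    "dprime_beta",
    "earnings_to_payment",
]


@dataclass(frozen=True)
class ScoreRule:
    correct_points: int = 4
    error_points: int = -4
    bonus_points: int = 2
    pence_per_point: int = 1
    payment_floor: int = 0


@dataclass(frozen=True)
class ResponseRecord:
    """A single scored response.

    ``truth`` and ``choice`` are booleans (True = "true effect").  The bonus
    is granted only when the response is correct and made exactly at the
    optimal array index, so ``points`` is one of -4, +4, +6 under the
    default rule.
    """

    trial_id: int
    truth: bool
    choice: bool
    array_index: int
    llr_at_response: float
    observed_d_at_response: float
    points: int

    @property
    def correct(self) -> bool:
        return self.choice == self.truth


def score_response(
    truth: bool,
    choice: bool,
    array_index: int,
    optimal_index: int,
    rule: ScoreRule | None = None,
) -> int:
    """Points for one response: +4 correct / -4 error, +2 bonus at optimum."""
    rule = rule or ScoreRule()
    if choice != truth:
        return rule.error_points
    bonus = rule.bonus_points if array_index == optimal_index else 0
    return rule.correct_points + bonus


@dataclass(frozen=True)
class SdtCounts:
    """Signal-detection tallies over a set of trials."""

    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self) -> None:
        if min(self.hits, self.misses, self.false_alarms, self.correct_rejections) < 0:
            raise ValueError("counts must be nonnegative")

    @classmethod
    def from_records(cls, records: Iterable[ResponseRecord]) -> "SdtCounts":
        h = m = fa = cr = 0
        for r in records:
            if r.truth:
                h, m = h + r.choice, m + (not r.choice)
            else:
                fa, cr = fa + r.choice, cr + (not r.choice)
        return cls(h, m, fa, cr)


def _clip_rate(rate: float, n: int) -> float:
    # replace only the degenerate rates 0 and 1; interior rates stay exact
    if rate == 0.0:
        return 1.0 / (2 * n)
    if rate == 1.0:
        return 1.0 - 1.0 / (2 * n)
    return rate


def dprime_beta(c: SdtCounts) -> tuple[float, float]:
    """Sensitivity d' = z(HR) - z(FAR) and likelihood-ratio bias beta.

    ``beta = exp((z(FAR)^2 - z(HR)^2) / 2)``; beta is 1 when the criterion
    is symmetric (HR + FAR = 1).  Extreme rates of exactly 0 or 1 are
    replaced by ``1/(2N)`` and ``1 - 1/(2N)`` before taking quantiles.
    """
    n_signal = c.hits + c.misses
    n_noise = c.false_alarms + c.correct_rejections
    if n_signal == 0 or n_noise == 0:
        raise ValueError("need at least one signal and one noise trial")
    hr = _clip_rate(c.hits / n_signal, n_signal)
    far = _clip_rate(c.false_alarms / n_noise, n_noise)
    zh = stats.norm.ppf(hr)
    zf = stats.norm.ppf(far)
    return float(zh - zf), float(math.exp((zf * zf - zh * zh) / 2.0))


@dataclass(frozen=True)
class BlockSummary:
    """Analysis summary of one block of responses."""

    block: int
    n_trials: int
    earnings: int
    percent_correct: float
    mean_array_index: float
    mean_abs_llr: float
    mean_observed_d: float
    d_prime: float
    beta: float


def summarize_block(
    records: Sequence[ResponseRecord], block: int = 1
) -> BlockSummary:
    """Aggregate a block of responses into its analysis variables."""
    if len(records) == 0:
        raise ValueError("block must contain at least one response")
    counts = SdtCounts.from_records(records)
    if counts.hits + counts.misses and counts.false_alarms + counts.correct_rejections:
        dp, beta = dprime_beta(counts)
    else:  # a block with only one trial type has undefined SDT indices
        dp = beta = float("nan")
    correct = [r.correct for r in records]
    return BlockSummary(
        block=block,
        n_trials=len(records),
        earnings=int(sum(r.points for r in records)),
        percent_correct=100.0 * float(np.mean(correct)),
        mean_array_index=float(np.mean([r.array_index for r in records])),
        mean_abs_llr=float(np.mean([abs(r.llr_at_response) for r in records])),
        mean_observed_d=float(np.mean([r.observed_d_at_response for r in records])),
        d_prime=dp,
        beta=beta,
    )


def earnings_to_payment(total_points: int, rule: ScoreRule | None = None) -> int:
    """Convert a raw point total to pence, floored at zero."""
    rule = rule or ScoreRule()
    return max(total_points * rule.pence_per_point, rule.payment_floor)
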