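"""Cumulative two-group trial generation and per-array evidence.

The training game shows a pair of growing samples — a pink control group and
a blue experimental group — judged as coming from the same population (null)
or from populations whose means differ by ``delta`` standard-deviation units
(a true effect, ``delta = 0.3`` by default).  Observations accumulate through
six *array sizes* of 10, 20, 40, 80, 160 and 320 points per group; each
array contains the previous one as a prefix, so the display only ever adds
points.

At every array size the evidence available to the player is summarised by

* the observed standardised mean difference (Cohen's *d* with pooled
  ``n - 1`` variances), and
* the log likelihood ratio (LLR) of the two simple hypotheses about the blue
  group, ``N(delta, 1)`` versus ``N(0, 1)``.  Because the pink population is
  identical under both hypotheses its density terms cancel, leaving the
  closed form ``delta * sum(blue) - n * delta**2 / 2``.

The *optimal* array index is the first one at which the absolute LLR reaches
``ln 40`` (odds of 40:1 either way); trials that never reach it are assigned
the final index, where the display stops.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ARRAY_SIZES",
    "TrialSpec",
    "Trial",
    "EvidenceRule",
    "EvidenceTrajectory",
    "generate_trial",
    "generate_stimulus_set",
    "log_likelihood_ratio",
    "observed_effect_size",
    "optimal_array_index",
    "latency_to_array_index",
]

#: Default per-group sample sizes of the six cumulative arrays.
ARRAY_SIZES: tuple[int, ...] = (10, 20, 40, 80, 160, 320)

#: 40:1 odds expressed as an absolute natural-log likelihood ratio.
DEFAULT_THRESHOLD: float = math.log(40.0)

#: Default population mean shift of the blue group on true-effect trials.
DEFAULT_DELTA: float = 0.3


def _validate_array_sizes(sizes: Sequence[int]) -> tuple[int, ...]:
    sizes = tuple(int(n) for n in sizes)
    if len(sizes) < 1 or any(n <= 0 for n in sizes):
        raise ValueError("array_sizes must be positive integers")
    for a, b in zip(sizes, sizes[1:]):
        if b != 2 * a:
            raise ValueError(
                f"array_sizes must double at each step, got {a} -> {b}"
            )
    return sizes


@dataclass(frozen=True)
class TrialSpec:
    """Generative parameters for one trial.

    Parameters
    ----------
    delta
        Population mean of the blue group in s.d. units (0 for a null trial,
        0.3 for the study's true effect).
    array_sizes
        Ordered per-group sample sizes; must double at each step.
    seed
        Optional seed recorded for provenance (generation uses the RNG passed
        to :func:`generate_trial`).
    """

    delta: float = DEFAULT_DELTA
    array_sizes: tuple[int, ...] = ARRAY_SIZES
    seed: int | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta):
            raise ValueError("delta must be finite")
        object.__setattr__(
            self, "array_sizes", _validate_array_sizes(self.array_sizes)
        )

    @property
    def truth(self) -> bool:
        """Whether this trial carries a true effect (``delta > 0``)."""
        return self.delta > 0


@dataclass(frozen=True)
class Trial:
    """One realised trial: cumulative pink and blue samples plus its label."""

    spec: TrialSpec
    pink: np.ndarray
    blue: np.ndarray
    truth: bool
    trial_id: int = 0

    def __post_init__(self) -> None:
        total = self.spec.array_sizes[-1]
        if len(self.pink) != total or len(self.blue) != total:
            raise ValueError(
                f"samples must hold {total} observations per group"
            )

    def sample_at(self, index: int) -> tuple[np.ndarray, np.ndarray]:
        """Pink and blue samples visible at 1-based array ``index``."""
        n = self.spec.array_sizes[index - 1]
        return self.pink[:n], self.blue[:n]


@dataclass(frozen=True)
class EvidenceRule:
    """Evidence criterion: alternative shift and the 40:1 LLR threshold."""

    threshold: float = DEFAULT_THRESHOLD
    delta_alt: float = DEFAULT_DELTA

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError("threshold must be positive")


@dataclass(frozen=True)
class EvidenceTrajectory:
    """Per-array evidence summary of one trial.

    Arrays ``n``, ``observed_d`` and ``llr`` are aligned with the 1-based
    array index (entry ``k - 1`` describes the sample of ``n[k-1]`` points
    per group).
    """

    n: np.ndarray
    observed_d: np.ndarray
    llr: np.ndarray
    truth: bool = False
    trial_id: int = 0

    def __post_init__(self) -> None:
        if not (len(self.n) == len(self.observed_d) == len(self.llr)):
            raise ValueError("trajectory arrays must have equal length")
        if not (
            np.all(np.isfinite(self.observed_d))
            and np.all(np.isfinite(self.llr))
        ):
            raise ValueError("trajectory values must be finite")

    def __len__(self) -> int:
        return len(self.n)

    @classmethod
    def from_trial(cls, trial: Trial, rule: EvidenceRule | None = None) -> "EvidenceTrajectory":
        """Compute observed *d* and LLR at every array size of ``trial``."""
        rule = rule or EvidenceRule()
        sizes = trial.spec.array_sizes
        d = np.empty(len(sizes))
        llr = np.empty(len(sizes))
        for k, n in enumerate(sizes):
            pink, blue = trial.pink[:n], trial.blue[:n]
            d[k] = observed_effect_size(pink, blue)
            llr[k] = log_likelihood_ratio(blue, rule)
        return cls(
            n=np.asarray(sizes),
            observed_d=d,
            llr=llr,
            truth=trial.truth,
            trial_id=trial.trial_id,
        )


def generate_trial(
    spec: TrialSpec, rng: np.random.Generator, trial_id: int = 0
) -> Trial:
    """Draw one cumulative trial.

    Pink observations are i.i.d. standard normal; blue observations are
    i.i.d. ``N(spec.delta, 1)``.  Cumulative nesting holds by construction:
    the first ``n_k`` elements of each sequence are the array-``k`` sample.
    """
    total = spec.array_sizes[-1]
    pink = rng.standard_normal(total)
    blue = rng.standard_normal(total) + spec.delta
    return Trial(spec=spec, pink=pink, blue=blue, truth=spec.truth, trial_id=trial_id)


def generate_stimulus_set(
    n_trials: int,
    prop_true: float = 0.5,
    rng: np.random.Generator | None = None,
    delta: float = DEFAULT_DELTA,
    array_sizes: Sequence[int] = ARRAY_SIZES,
) -> list[Trial]:
    """Generate a stimulus set with an exact proportion of true-effect trials.

    Exactly ``round(n_trials * prop_true)`` trials carry the effect
    (``delta``); the rest are null.  Truth labels are shuffled once; each
    trial is generated from its own deterministic child stream of ``rng`` so
    trial ``i`` is reproducible regardless of how the rest of the set is
    consumed.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if not 0.0 <= prop_true <= 1.0:
        raise ValueError("prop_true must lie in [0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    n_true = round(n_trials * prop_true)
    truths = np.zeros(n_trials, dtype=bool)
    truths[:n_true] = True
    rng.shuffle(truths)
    streams = rng.spawn(n_trials)
    trials = []
    for i, (is_true, sub) in enumerate(zip(truths, streams)):
        spec = TrialSpec(
            delta=delta if is_true else 0.0, array_sizes=tuple(array_sizes)
        )
        trials.append(generate_trial(spec, sub, trial_id=i))
    return trials


def log_likelihood_ratio(
    blue_sample: Sequence[float], rule: EvidenceRule | None = None
) -> float:
    """Natural-log likelihood ratio of true vs. null for the blue sample.

    Both hypotheses are simple — ``N(delta_alt, 1)`` against ``N(0, 1)`` —
    and the pink group is identically distributed under both, so only the
    blue observations contribute:

    ``llr = delta_alt * sum(blue) - n * delta_alt**2 / 2``

    Positive values favour the true effect, negative values the null.
    """
    rule = rule or EvidenceRule()
    y = np.asarray(blue_sample, dtype=float)
    if y.size == 0:
        raise ValueError("blue_sample must be nonempty")
    d = rule.delta_alt
    return float(d * y.sum() - y.size * d * d / 2.0)


def observed_effect_size(pink: Sequence[float], blue: Sequence[float]) -> float:
    """Cohen's *d*: mean difference over the pooled ``n - 1`` s.d.

    Pooling weights each group's sample variance by its degrees of freedom.
    Raises if the pooled standard deviation is zero.
    """
    x = np.asarray(pink, dtype=float)
    y = np.asarray(blue, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least two values")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    pooled = ((x.size - 1) * vx + (y.size - 1) * vy) / (x.size + y.size - 2)
    if pooled == 0.0:
        raise ZeroDivisionError("pooled standard deviation is zero")
    return float((y.mean() - x.mean()) / math.sqrt(pooled))


def optimal_array_index(
    traj: EvidenceTrajectory | Sequence[float], rule: EvidenceRule | None = None
) -> int:
    """Smallest 1-based index whose absolute LLR reaches the threshold.

    If the trajectory never crosses, the final index is returned: the
    display stops at the largest array, so the bonus remains attainable on
    every trial.
    """
    rule = rule or EvidenceRule()
    llr = traj.llr if isinstance(traj, EvidenceTrajectory) else np.asarray(traj, float)
    hits = np.flatnonzero(np.abs(llr) >= rule.threshold)
    return int(hits[0]) + 1 if hits.size else len(llr)


def latency_to_array_index(
    latency: float, step: float = 2.0, n_arrays: int = len(ARRAY_SIZES)
) -> int:
    """Map a response latency to the array index on screen at that moment.

    Each array is displayed for ``step`` seconds, so latencies in
    ``[step*(k-1), step*k)`` map to index ``k`` ("under 2 s" means the first
    array; boundary values belong to the later array).  Latencies beyond the
    last transition are capped at the final index.
    """
    if latency < 0:
        raise ValueError("latency must be nonnegative")
    return min(int(latency // step) + 1, n_arrays)
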