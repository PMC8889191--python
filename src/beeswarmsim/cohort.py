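"""Latent-learner cohort simulation.

Simulated participants play the 80-trial game (four blocks of 20) and sit a
six-item sample-size quiz before and after.  Behaviour is governed by a
latent binary learner variable ``L``:

* **Non-learners** respond at an array index drawn from an empirical initial
  distribution (defaults from early-block pilot play:
  0.005, 0.022, 0.102, 0.238, 0.358, 0.275 over indices 1-6) and judge by
  the *sign* of the log likelihood ratio there, regardless of its strength.
* **Learners** (in the final block only) wait for the first array index
  whose absolute LLR reaches the 40:1 threshold and judge by its sign there.

On top of the sign rule a proportion of responses is flipped to an error —
independently across trials, with a higher rate for non-learners (defaults
0.30 vs 0.10; the rates are free parameters of the model, chosen so that
initial-block accuracy lands near 70%).

Quiz scores are binomial: ``preS ~ Bin(6, 1/3)`` for everyone and
``postS ~ Bin(6, 1/3 + L * gain_items/6)``, i.e. learners improve by one or
two items on average.

A cohort has exactly ``round(N * plearn)`` learners (deterministic count,
not Bernoulli assignment) and yields one row per participant with block-1
and block-4 earnings, their difference (the learning index ``earn_diff``)
and the two quiz scores.

For large Monte-Carlo runs the evidence trajectories are drawn directly as
per-segment blue-group sums (the sufficient statistic for the LLR), which
is distribution-identical to generating the 320 raw observations per group;
:func:`simulate_participant_session` keeps the full raw-trial path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .scoring import ResponseRecord, ScoreRule, score_response, summarize_block
from .stimulus import (
    ARRAY_SIZES,
    DEFAULT_THRESHOLD,
    EvidenceRule,
    EvidenceTrajectory,
    Trial,
    generate_stimulus_set,
    optimal_array_index,
)

__all__ = [
    "LearnerModel",
    "CohortConfig",
    "QuizModel",
    "simulate_response",
    "simulate_participant_session",
    "simulate_quiz_scores",
    "simulate_cohort",
    "evidence_matrix",
]

#: Initial array-index choice probabilities (indices 1..6) for naive play.
INITIAL_INDEX_PROBS: tuple[float, ...] = (0.005, 0.022, 0.102, 0.238, 0.358, 0.275)


@dataclass(frozen=True)
class LearnerModel:
    """Behavioural parameters of the latent-learner response model."""

    initial_index_probs: tuple[float, ...] = INITIAL_INDEX_PROBS
    threshold: float = DEFAULT_THRESHOLD
    error_rate_learner: float = 0.10
    error_rate_nonlearner: float = 0.30

    def __post_init__(self) -> None:
        p = np.asarray(self.initial_index_probs, dtype=float)
        if p.ndim != 1 or np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("initial_index_probs must be a probability vector")
        for r in (self.error_rate_learner, self.error_rate_nonlearner):
            if not 0.0 <= r < 0.5:
                raise ValueError("error rates must lie in [0, 0.5)")
        if self.error_rate_learner >= self.error_rate_nonlearner:
            raise ValueError("learner error rate must be below non-learner rate")

    @property
    def rule(self) -> EvidenceRule:
        return EvidenceRule(threshold=self.threshold)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort size, learner proportion and Monte-Carlo settings."""

    n_participants: int
    plearn: float
    n_iterations: int = 500
    alpha: float = 0.0322
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least two participants")
        if not 0.0 <= self.plearn <= 1.0:
            raise ValueError("plearn must lie in [0, 1]")
        if not 0.0 < self.alpha < 0.5:
            raise ValueError("alpha must lie in (0, 0.5)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be positive")

    @property
    def n_learners(self) -> int:
        return round(self.n_participants * self.plearn)


@dataclass(frozen=True)
class QuizModel:
    """Binomial model of sample-size quiz scores.

    Everyone answers each of ``n_items`` pre-test items correctly with
    probability ``p_pre``; learners gain ``gain_items`` items (in
    expectation) at post-test.
    """

    n_items: int = 6
    p_pre: float = 1.0 / 3.0
    gain_items: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_pre <= 1.0:
            raise ValueError("p_pre must lie in [0, 1]")
        if not 0.0 <= self.p_post(True) <= 1.0:
            raise ValueError("learner post-test probability outside [0, 1]")

    def p_post(self, learner: bool) -> float:
        return self.p_pre + (self.gain_items / self.n_items if learner else 0.0)


# ---------------------------------------------------------------------------
# single-response / single-session simulation (full-fidelity path)
# ---------------------------------------------------------------------------

def simulate_response(
    traj: EvidenceTrajectory,
    learner_behavior: bool,
    model: LearnerModel | None = None,
    rng: np.random.Generator | None = None,
    rule: ScoreRule | None = None,
) -> ResponseRecord:
    """Simulate one response to a trial's evidence trajectory.

    ``learner_behavior`` selects the strategy actually used on this trial
    (learners only adopt the waiting strategy in the final block).
    """
    model = model or LearnerModel()
    rng = np.random.default_rng() if rng is None else rng
    opt = optimal_array_index(traj, model.rule)
    if learner_behavior:
        k = opt
        err = model.error_rate_learner
    else:
        k = int(rng.choice(len(traj), p=model.initial_index_probs)) + 1
        err = model.error_rate_nonlearner
    llr_k = float(traj.llr[k - 1])
    choice = llr_k > 0
    if rng.random() < err:
        choice = not choice
    return ResponseRecord(
        trial_id=traj.trial_id,
        truth=traj.truth,
        choice=choice,
        array_index=k,
        llr_at_response=llr_k,
        observed_d_at_response=float(traj.observed_d[k - 1]),
        points=score_response(traj.truth, choice, k, opt, rule),
    )


def simulate_participant_session(
    stimuli: Sequence[Trial],
    learner: bool,
    model: LearnerModel | None = None,
    rng: np.random.Generator | None = None,
    n_blocks: int = 4,
    shuffle: bool = True,
):
    """Play a full session (``n_blocks`` blocks) and summarise each block.

    Stimuli are presented in a fresh random order per participant.  Blocks
    before the last always use non-learner behaviour; the last block uses
    learner behaviour iff ``learner`` is set (only the first and last blocks
    feed the analyses).
    """
    model = model or LearnerModel()
    rng = np.random.default_rng() if rng is None else rng
    if len(stimuli) % n_blocks:
        raise ValueError("trial count must divide evenly into blocks")
    per_block = len(stimuli) // n_blocks
    order = np.arange(len(stimuli))
    if shuffle:
        rng.shuffle(order)
    trajs = {t.trial_id: EvidenceTrajectory.from_trial(t, model.rule) for t in stimuli}
    summaries = []
    for b in range(n_blocks):
        is_last = b == n_blocks - 1
        records = [
            simulate_response(
                trajs[stimuli[i].trial_id],
                learner_behavior=learner and is_last,
                model=model,
                rng=rng,
            )
            for i in order[b * per_block : (b + 1) * per_block]
        ]
        summaries.append(summarize_block(records, block=b + 1))
    return summaries


def simulate_quiz_scores(
    learner: bool,
    quiz: QuizModel | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[int, int]:
    """Draw (pre, post) quiz scores for one participant."""
    quiz = quiz or QuizModel()
    rng = np.random.default_rng() if rng is None else rng
    pre = int(rng.binomial(quiz.n_items, quiz.p_pre))
    post = int(rng.binomial(quiz.n_items, quiz.p_post(learner)))
    return pre, post


# ---------------------------------------------------------------------------
# vectorised cohort path
# ---------------------------------------------------------------------------

def evidence_matrix(
    truth: np.ndarray,
    rng: np.random.Generator,
    delta: float = 0.3,
    rule: EvidenceRule | None = None,
    array_sizes: Sequence[int] = ARRAY_SIZES,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw LLR trajectories for many trials at once.

    Only the blue-group segment sums enter the LLR, so each trial needs just
    six normal draws (one per cumulative segment) instead of 320 raw values.
    Returns ``(llr, opt)`` where ``llr`` has shape ``(n_trials, 6)`` and
    ``opt`` holds 0-based optimal indices.
    """
    rule = rule or EvidenceRule(delta_alt=delta)
    sizes = np.asarray(array_sizes)
    seg = np.diff(np.concatenate(([0], sizes)))
    mu = np.where(np.asarray(truth, bool)[:, None], delta, 0.0) * seg
    sums = rng.normal(mu, np.sqrt(seg)).cumsum(axis=1)
    llr = rule.delta_alt * sums - sizes * rule.delta_alt**2 / 2.0
    hit = np.abs(llr) >= rule.threshold
    opt = np.where(hit.any(axis=1), hit.argmax(axis=1), llr.shape[1] - 1)
    return llr, opt


def _llr_matrix_from_trials(
    stimuli: Sequence[Trial], rule: EvidenceRule
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    trajs = [EvidenceTrajectory.from_trial(t, rule) for t in stimuli]
    llr = np.stack([tr.llr for tr in trajs])
    truth = np.array([t.truth for t in stimuli])
    hit = np.abs(llr) >= rule.threshold
    opt = np.where(hit.any(axis=1), hit.argmax(axis=1), llr.shape[1] - 1)
    return llr, truth, opt


def _block_earnings(
    tidx: np.ndarray,
    learner_rows: np.ndarray,
    llr: np.ndarray,
    truth: np.ndarray,
    opt: np.ndarray,
    model: LearnerModel,
    rng: np.random.Generator,
    rule: ScoreRule,
) -> np.ndarray:
    """Earnings per participant for one block.

    ``tidx`` is an ``(N, per_block)`` matrix of trial indices;
    ``learner_rows`` marks participants using learner behaviour this block.
    """
    n, m = tidx.shape
    k = rng.choice(llr.shape[1], size=(n, m), p=model.initial_index_probs)
    k[learner_rows] = opt[tidx[learner_rows]]
    err = np.where(learner_rows[:, None], model.error_rate_learner, model.error_rate_nonlearner)
    choice = llr[tidx, k] > 0
    flipped = rng.random((n, m)) < err
    correct = (choice == truth[tidx]) ^ flipped
    bonus = (k == opt[tidx]) * rule.bonus_points
    points = np.where(correct, rule.correct_points + bonus, rule.error_points)
    return points.sum(axis=1)


def simulate_cohort(
    cfg: CohortConfig,
    model: LearnerModel | None = None,
    quiz: QuizModel | None = None,
    stimuli: Sequence[Trial] | None = None,
    rng: np.random.Generator | None = None,
    n_trials: int = 80,
    n_blocks: int = 4,
    score_rule: ScoreRule | None = None,
) -> pd.DataFrame:
    """Simulate one cohort and return its analysis table.

    Each participant plays the same stimulus set in an independent random
    order.  If ``stimuli`` is None an 80-trial half-true set is generated
    from ``rng`` (segment-sum path); pass a frozen set of :class:`Trial`
    objects to mimic one fixed training set.

    Returns a DataFrame with one row per participant: ``participant_id``,
    ``L``, ``earn_block1``, ``earn_block4``, ``earn_diff``, ``preS``,
    ``postS``.  Exactly ``cfg.n_learners`` rows have ``L = 1``.
    """
    model = model or LearnerModel()
    quiz = quiz or QuizModel()
    score_rule = score_rule or ScoreRule()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng

    if stimuli is not None:
        llr, truth, opt = _llr_matrix_from_trials(stimuli, model.rule)
        n_trials = len(stimuli)
    else:
        truth = np.zeros(n_trials, dtype=bool)
        truth[: n_trials // 2] = True
        rng.shuffle(truth)
        llr, opt = evidence_matrix(truth, rng, rule=model.rule)

    n = cfg.n_participants
    per_block = n_trials // n_blocks
    is_learner = np.zeros(n, dtype=bool)
    is_learner[rng.choice(n, size=cfg.n_learners, replace=False)] = True

    perm = rng.permuted(np.tile(np.arange(n_trials), (n, 1)), axis=1)
    block1 = perm[:, :per_block]
    block4 = perm[:, -per_block:]
    none_learning = np.zeros(n, dtype=bool)
    earn1 = _block_earnings(block1, none_learning, llr, truth, opt, model, rng, score_rule)
    earn4 = _block_earnings(block4, is_learner, llr, truth, opt, model, rng, score_rule)

    pre = rng.binomial(quiz.n_items, quiz.p_pre, size=n)
    p_post = np.where(is_learner, quiz.p_post(True), quiz.p_post(False))
    post = rng.binomial(quiz.n_items, p_post)

    return pd.DataFrame(
        {
            "participant_id": np.arange(1, n + 1),
            "L": is_learner.astype(int),
            "earn_block1": earn1,
            "earn_block4": earn4,
            "earn_diff": earn4 - earn1,
            "preS": pre,
            "postS": post,
        }
    )
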