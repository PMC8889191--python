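"""Monte-Carlo and analytic power computations.

Three Monte-Carlo power functions estimate the probability of rejecting the
null in the study's three confirmatory analyses, by repeatedly simulating a
cohort under the latent-learner model and applying the planned test at the
planned one-tailed alpha (0.0322 by default, the pre-registered level for a
sequential design with three looks):

* :func:`power_earnings_ttest` — paired one-tailed t-test of block-4 vs.
  block-1 earnings (learning on the game),
* :func:`power_quiz_ttest` — paired t-test of post- vs. pre-test
  sample-size quiz scores (transfer, overall; two-sided p against alpha by
  default, matching the study's quiz power grid),
* :func:`power_quiz_regression` — test of the ``earn_diff`` coefficient in
  the least-squares model ``postS ~ preS + earn_diff`` (transfer predicted
  by the amount of learning; two-sided by default likewise).

Each returns a :class:`PowerResult` carrying the rejection fraction and its
Monte-Carlo standard error ``sqrt(p*(1-p)/n_iterations)``.

Also provided: the exact two-sample t-test power curve via the noncentral t
distribution (:func:`analytic_ttest_power`) and the effect-size conversion
``r = d / sqrt(d**2 + 4)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

from .cohort import CohortConfig, LearnerModel, QuizModel, simulate_cohort

__all__ = [
    "PowerResult",
    "power_earnings_ttest",
    "power_quiz_ttest",
    "power_quiz_regression",
    "analytic_ttest_power",
    "d_to_r",
]


@dataclass(frozen=True)
class PowerResult:
    """Monte-Carlo power estimate for one scenario."""

    test: str
    power: float
    n_iterations: int
    alpha: float
    scenario: dict = field(default_factory=dict)
    n_flagged: int = 0

    @property
    def mc_std_error(self) -> float:
        p = self.power
        return math.sqrt(p * (1.0 - p) / self.n_iterations)


def _resolve_rng(cfg: CohortConfig, rng: np.random.Generator | None) -> np.random.Generator:
    return np.random.default_rng(cfg.seed) if rng is None else rng


def power_earnings_ttest(
    cfg: CohortConfig,
    model: LearnerModel | None = None,
    stimuli_policy: str = "fresh",
    rng: np.random.Generator | None = None,
) -> PowerResult:
    """Power of the paired one-tailed t-test on block-4 vs. block-1 earnings.

    ``stimuli_policy`` is "fresh" (a new stimulus set per iteration, the
    default) or "frozen" (one set drawn once and reused, mimicking a single
    fixed training set).
    """
    model = model or LearnerModel()
    rng = _resolve_rng(cfg, rng)
    if stimuli_policy not in ("fresh", "frozen"):
        raise ValueError("stimuli_policy must be 'fresh' or 'frozen'")
    frozen = None
    if stimuli_policy == "frozen":
        from .stimulus import generate_stimulus_set

        frozen = generate_stimulus_set(80, 0.5, rng)
    rejections = 0
    for _ in range(cfg.n_iterations):
        cohort = simulate_cohort(cfg, model=model, stimuli=frozen, rng=rng)
        t, p = _paired_t_greater(cohort["earn_block4"].to_numpy(), cohort["earn_block1"].to_numpy())
        rejections += p < cfg.alpha
    return PowerResult(
        test="earnings_paired_t",
        power=rejections / cfg.n_iterations,
        n_iterations=cfg.n_iterations,
        alpha=cfg.alpha,
        scenario={"N": cfg.n_participants, "plearn": cfg.plearn},
    )


def _tail_p(t, df: int, alternative: str):
    """p-value(s) for a t statistic under the requested alternative."""
    if alternative == "greater":
        return stats.t.sf(t, df)
    if alternative == "two-sided":
        return 2.0 * stats.t.sf(np.abs(t), df)
    raise ValueError("alternative must be 'two-sided' or 'greater'")


def _paired_t_greater(post: np.ndarray, pre: np.ndarray) -> tuple[float, float]:
    d = post - pre
    sd = d.std(ddof=1)
    if sd == 0:
        return math.nan, 1.0
    t = d.mean() / (sd / math.sqrt(len(d)))
    return t, float(stats.t.sf(t, len(d) - 1))


def power_quiz_ttest(
    cfg: CohortConfig,
    quiz: QuizModel | None = None,
    rng: np.random.Generator | None = None,
    alternative: str = "two-sided",
) -> PowerResult:
    """Power of the paired t-test on quiz post- vs. pre-test scores.

    ``alternative`` is "two-sided" (default: the alpha level is applied to
    the ordinary two-sided p-value, which is how the study's quiz power
    grid behaves) or "greater" (upper-tail p for post > pre).  Depends only
    on the binomial quiz model, so all iterations are drawn in one
    vectorised pass.
    """
    quiz = quiz or QuizModel()
    rng = _resolve_rng(cfg, rng)
    iters, n = cfg.n_iterations, cfg.n_participants
    p_post = np.full(n, quiz.p_post(False))
    p_post[: cfg.n_learners] = quiz.p_post(True)
    pre = rng.binomial(quiz.n_items, quiz.p_pre, size=(iters, n))
    post = rng.binomial(quiz.n_items, p_post, size=(iters, n))
    diff = (post - pre).astype(float)
    sd = diff.std(axis=1, ddof=1)
    ok = sd > 0
    t = np.full(iters, -np.inf)
    t[ok] = diff[ok].mean(axis=1) / (sd[ok] / math.sqrt(n))
    pvals = _tail_p(t, n - 1, alternative)
    return PowerResult(
        test="quiz_paired_t",
        power=float(np.mean(pvals < cfg.alpha)),
        n_iterations=iters,
        alpha=cfg.alpha,
        scenario={"N": n, "plearn": cfg.plearn, "gain_items": quiz.gain_items},
        n_flagged=int(np.sum(~ok)),
    )


def power_quiz_regression(
    cfg: CohortConfig,
    model: LearnerModel | None = None,
    quiz: QuizModel | None = None,
    rng: np.random.Generator | None = None,
    alternative: str = "two-sided",
) -> PowerResult:
    """Power of the test of the ``earn_diff`` slope in
    ``postS ~ preS + earn_diff``.

    Per iteration a full cohort (game plus quiz) is simulated and the
    slope's t statistic is tested against ``t(N - 3)``; ``alternative`` is
    "two-sided" (default, matching the study's regression power grid) or
    "greater".  Iterations with a singular design are flagged and counted
    as non-rejections.
    """
    model = model or LearnerModel()
    quiz = quiz or QuizModel()
    rng = _resolve_rng(cfg, rng)
    n = cfg.n_participants
    rejections = 0
    flagged = 0
    for _ in range(cfg.n_iterations):
        cohort = simulate_cohort(cfg, model=model, quiz=quiz, rng=rng)
        x = np.column_stack(
            [
                np.ones(n),
                cohort["preS"].to_numpy(float),
                cohort["earn_diff"].to_numpy(float),
            ]
        )
        y = cohort["postS"].to_numpy(float)
        xtx = x.T @ x
        if np.linalg.matrix_rank(xtx) < 3:
            flagged += 1
            continue
        xtx_inv = np.linalg.inv(xtx)
        beta = xtx_inv @ (x.T @ y)
        resid = y - x @ beta
        df = n - 3
        s2 = resid @ resid / df
        se = math.sqrt(s2 * xtx_inv[2, 2])
        if se == 0:
            flagged += 1
            continue
        t = beta[2] / se
        if _tail_p(t, df, alternative) < cfg.alpha:
            rejections += 1
    return PowerResult(
        test="quiz_regression",
        power=rejections / cfg.n_iterations,
        n_iterations=cfg.n_iterations,
        alpha=cfg.alpha,
        scenario={"N": n, "plearn": cfg.plearn, "gain_items": quiz.gain_items},
        n_flagged=flagged,
    )


def analytic_ttest_power(
    d: float,
    n_per_group: int,
    alpha: float = 0.05,
    tail: str = "one-sided",
) -> float:
    """Exact power of the two-sample t-test via the noncentral t distribution.

    With ``n`` observations per group the noncentrality parameter is
    ``d * sqrt(n / 2)`` and the statistic has ``2n - 2`` degrees of freedom.
    ``tail`` is "one-sided" (upper) or "two-sided".
    """
    if n_per_group < 2:
        raise ValueError("need at least two observations per group")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    df = 2 * n_per_group - 2
    ncp = d * math.sqrt(n_per_group / 2.0)
    if tail == "one-sided":
        crit = stats.t.isf(alpha, df)
        return float(stats.nct.sf(crit, df, ncp))
    if tail == "two-sided":
        crit = stats.t.isf(alpha / 2.0, df)
        return float(stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp))
    raise ValueError("tail must be 'one-sided' or 'two-sided'")


def d_to_r(d: float) -> float:
    """Convert Cohen's *d* to a point-biserial correlation (equal groups)."""
    if not math.isfinite(d):
        raise ValueError("d must be finite")
    return d / math.sqrt(d * d + 4.0)
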