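"""Quiz scoring, exclusions and the confirmatory/exploratory statistics.

The judgement-and-reasoning quiz has two parallel 12-item forms; six items
per form probe general probability (P-items) and six probe how sample size
governs the reliability of estimates (S-items).  Each item offers one
correct option and three foils; for most S-items one foil (the *bias* foil)
asserts outright that sample size does not matter, so clustering of errors
on that foil is evidence of sample-size neglect.  Items S3A/S3B have no
such foil and are excluded from the error analysis.

This module scores answer sheets against a key, applies the pre-test
exclusion rule (5-6 S-items correct indicates prior mastery), and provides
the statistical toolkit of the analysis plan: the per-item foil chi-square
against a uniform null, one-tailed one-sample/paired/Welch t-tests, the
Pearson correlation, the transfer regression ``postS ~ preS + earn_diff``
with its BIC, and two Bayes factors (the BIC approximation for nested
models and the JZS default-prior t-test Bayes factor).

``PRETRAINING_FOIL_COUNTS`` ships the reference distribution of error
responses over (bias, other1, other2) foils for the ten analysable S-items
in a 100-participant pre-training administration, together with the
chi-square statistics reported for it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import integrate, stats

__all__ = [
    "QuizItem",
    "QuizKey",
    "FoilCounts",
    "PRETRAINING_FOIL_COUNTS",
    "score_quiz",
    "apply_exclusions",
    "foil_counts_from_responses",
    "foil_chisq",
    "one_sample_t_less",
    "paired_t_one_tailed",
    "welch_t",
    "pearson_r",
    "fit_regression_postS",
    "bic_bayes_factor",
    "jzs_ttest_bf",
]

#: Error-response counts (bias foil, other foil 1, other foil 2) on the ten
#: analysable pre-training S-items, pooled over both forms, in a reference
#: 100-participant administration; ``chisq`` is the statistic reported for
#: each item under the uniform-foil null.
PRETRAINING_FOIL_COUNTS: dict[str, dict] = {
    "S1A": {"counts": (28, 7, 4), "chisq": 26.31},
    "S1B": {"counts": (22, 8, 2), "chisq": 19.75},
    "S2A": {"counts": (9, 1, 34), "chisq": 40.41},
    "S2B": {"counts": (12, 4, 2), "chisq": 9.33},
    "S4A": {"counts": (12, 29, 3), "chisq": 23.77},
    "S4B": {"counts": (8, 11, 29), "chisq": 16.12},
    "S5A": {"counts": (21, 9, 6), "chisq": 10.50},
    "S5B": {"counts": (10, 15, 8), "chisq": 2.36},
    "S6A": {"counts": (14, 14, 4), "chisq": 6.25},
    "S6B": {"counts": (23, 7, 2), "chisq": 22.56},
}


@dataclass(frozen=True)
class QuizItem:
    """One multiple-choice item of the answer key."""

    item_id: str
    form: int
    item_type: str  # "P" or "S"
    correct_option: str
    bias_foil: str | None
    other_foils: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.item_type not in ("P", "S"):
            raise ValueError("item_type must be 'P' or 'S'")
        options = {self.correct_option, *self.other_foils}
        if self.bias_foil is not None:
            options.add(self.bias_foil)
        if len(options) != 1 + len(self.other_foils) + (self.bias_foil is not None):
            raise ValueError(f"options of {self.item_id} are not distinct")

    @property
    def options(self) -> set[str]:
        opts = {self.correct_option, *self.other_foils}
        if self.bias_foil is not None:
            opts.add(self.bias_foil)
        return opts


class QuizKey:
    """Answer key for both counterbalanced forms (12 items each, 6 P + 6 S)."""

    def __init__(self, items: Iterable[QuizItem]):
        self.items = {it.item_id: it for it in items}
        for form in (1, 2):
            per_form = [it for it in self.items.values() if it.form == form]
            if len(per_form) != 12:
                raise ValueError(f"form {form} must hold 12 items, got {len(per_form)}")
            for typ in ("P", "S"):
                if sum(it.item_type == typ for it in per_form) != 6:
                    raise ValueError(f"form {form} must hold 6 {typ}-items")

    def __getitem__(self, item_id: str) -> QuizItem:
        return self.items[item_id]

    @classmethod
    def from_csv(cls, path) -> "QuizKey":
        df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])
        items = []
        for _, row in df.iterrows():
            bias = row.get("bias_foil") or None
            others = [row["other1"], row["other2"]]
            # items without a bias foil carry their third foil in "other3"
            if row.get("other3"):
                others.append(row["other3"])
            items.append(
                QuizItem(
                    item_id=row["item_id"],
                    form=int(row["form"]),
                    item_type=row["type"],
                    correct_option=row["correct"],
                    bias_foil=bias,
                    other_foils=tuple(others),
                )
            )
        return cls(items)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item_id": [it.item_id for it in self.items.values()],
                "form": [it.form for it in self.items.values()],
                "type": [it.item_type for it in self.items.values()],
                "correct": [it.correct_option for it in self.items.values()],
                "bias_foil": [it.bias_foil or "" for it in self.items.values()],
                "other1": [it.other_foils[0] for it in self.items.values()],
                "other2": [it.other_foils[1] for it in self.items.values()],
                "other3": [
                    it.other_foils[2] if len(it.other_foils) > 2 else ""
                    for it in self.items.values()
                ],
            }
        )


def score_quiz(responses: pd.DataFrame, key: QuizKey) -> pd.DataFrame:
    """Count correct S- and P-items per participant and session.

    ``responses`` needs columns participant_id, session ("pre"|"post"),
    form, item_id, choice.  Unknown items or options raise a ``ValueError``
    naming the offending row.
    """
    required = {"participant_id", "session", "form", "item_id", "choice"}
    missing = required - set(responses.columns)
    if missing:
        raise ValueError(f"responses table lacks columns: {sorted(missing)}")
    rows = []
    for (pid, session), grp in responses.groupby(["participant_id", "session"], sort=True):
        s_corr = p_corr = 0
        for _, row in grp.iterrows():
            try:
                item = key[row["item_id"]]
            except KeyError:
                raise ValueError(
                    f"unknown item {row['item_id']!r} for participant {pid} ({session})"
                ) from None
            if row["choice"] not in item.options:
                raise ValueError(
                    f"unknown option {row['choice']!r} on item {item.item_id} "
                    f"for participant {pid} ({session})"
                )
            if row["choice"] == item.correct_option:
                if item.item_type == "S":
                    s_corr += 1
                else:
                    p_corr += 1
        rows.append(
            {"participant_id": pid, "session": session, "S_correct": s_corr, "P_correct": p_corr}
        )
    return pd.DataFrame(rows)


def apply_exclusions(
    pre_scores: Mapping | pd.Series, max_pre_s: int = 4
) -> tuple[list, list]:
    """Split participants into (retained, excluded) by pre-test S score.

    Participants scoring above ``max_pre_s`` (i.e. 5 or 6 of 6 by default)
    already understand sample-size effects and are removed from learning
    analyses.
    """
    series = pd.Series(pre_scores)
    excluded = sorted(series.index[series > max_pre_s])
    retained = sorted(series.index[series <= max_pre_s])
    return retained, excluded


@dataclass(frozen=True)
class FoilCounts:
    """Error tallies of one S-item over its three foils."""

    item_id: str
    bias: int
    other1: int
    other2: int

    def __post_init__(self) -> None:
        if min(self.bias, self.other1, self.other2) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.bias + self.other1 + self.other2


def foil_counts_from_responses(
    responses: pd.DataFrame, key: QuizKey, session: str = "pre"
) -> list[FoilCounts]:
    """Tally wrong answers by foil for every S-item that has a bias foil."""
    sub = responses[responses["session"] == session]
    out = []
    for item_id in sorted({i for i in sub["item_id"] if key[i].item_type == "S"}):
        item = key[item_id]
        if item.bias_foil is None:
            continue
        wrong = sub[(sub["item_id"] == item_id) & (sub["choice"] != item.correct_option)]
        c = wrong["choice"].value_counts()
        out.append(
            FoilCounts(
                item_id=item_id,
                bias=int(c.get(item.bias_foil, 0)),
                other1=int(c.get(item.other_foils[0], 0)),
                other2=int(c.get(item.other_foils[1], 0)),
            )
        )
    return out


@dataclass(frozen=True)
class ChisqResult:
    statistic: float
    df: int
    p: float


def foil_chisq(counts: FoilCounts | Sequence[int]) -> ChisqResult:
    """Pearson chi-square of the three foil counts against a uniform null."""
    obs = (
        np.array([counts.bias, counts.other1, counts.other2], float)
        if isinstance(counts, FoilCounts)
        else np.asarray(counts, dtype=float)
    )
    if obs.sum() < 1:
        raise ValueError("foil chi-square is undefined with zero errors")
    statistic, p = stats.chisquare(obs)
    return ChisqResult(statistic=float(statistic), df=len(obs) - 1, p=float(p))


# ---------------------------------------------------------------------------
# frequentist tests
# ---------------------------------------------------------------------------

def one_sample_t_less(scores: Sequence[float], mu0: float) -> tuple[float, float]:
    """One-sample t-test with lower-tail p (is the mean below ``mu0``?)."""
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two scores")
    if x.std(ddof=1) == 0:
        raise ValueError("zero variance")
    res = stats.ttest_1samp(x, mu0, alternative="less")
    return float(res.statistic), float(res.pvalue)


def paired_t_one_tailed(
    x_post: Sequence[float], x_pre: Sequence[float]
) -> tuple[float, int, float]:
    """Paired t-test with upper-tail p for post > pre; returns (t, df, p)."""
    post = np.asarray(x_post, dtype=float)
    pre = np.asarray(x_pre, dtype=float)
    if post.shape != pre.shape:
        raise ValueError("paired samples must have equal length")
    if post.size < 2:
        raise ValueError("need at least two pairs")
    if (post - pre).std(ddof=1) == 0:
        raise ValueError("zero variance of differences")
    res = stats.ttest_rel(post, pre, alternative="greater")
    return float(res.statistic), post.size - 1, float(res.pvalue)


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, fractional df, two-sided p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    if va + vb == 0:
        raise ValueError("both groups have zero variance")
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(df), float(res.pvalue)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with its t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least three pairs")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ValueError("zero variance")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# transfer regression and Bayes factors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of ``postS ~ preS + earn_diff`` (terms in that order after
    the intercept), with the BIC of the Gaussian likelihood at the MLE
    residual variance."""

    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues_one_tailed: np.ndarray
    df_resid: int
    bic: float
    model: object = field(repr=False, default=None)


def _ols_bic(y: np.ndarray, x: np.ndarray):
    fit = sm.OLS(y, x).fit()
    return fit


def fit_regression_postS(
    postS: Sequence[float], preS: Sequence[float], earn_diff: Sequence[float]
) -> RegressionFit:
    """Least-squares fit of the transfer model ``postS ~ preS + earn_diff``.

    One-tailed p-values are the upper tail of each coefficient's t statistic
    (the pre-registered direction predicts positive slopes).
    """
    y = np.asarray(postS, dtype=float)
    x = sm.add_constant(
        np.column_stack([np.asarray(preS, float), np.asarray(earn_diff, float)]),
        has_constant="add",
    )
    if y.size <= 3:
        raise ValueError("need more observations than parameters")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("design matrix is rank deficient")
    fit = _ols_bic(y, x)
    one_tailed = stats.t.sf(fit.tvalues, fit.df_resid)
    return RegressionFit(
        params=np.asarray(fit.params),
        bse=np.asarray(fit.bse),
        tvalues=np.asarray(fit.tvalues),
        pvalues_one_tailed=np.asarray(one_tailed),
        df_resid=int(fit.df_resid),
        bic=float(fit.bic),
        model=fit,
    )


def bic_bayes_factor(bic_full: float, bic_reduced: float) -> float:
    """Bayes factor for the extra term from two nested models' BICs.

    ``BF = exp((bic_reduced - bic_full) / 2)``; values below 1 favour the
    reduced (null) model.
    """
    if not (math.isfinite(bic_full) and math.isfinite(bic_reduced)):
        raise ValueError("BICs must be finite")
    return math.exp((bic_reduced - bic_full) / 2.0)


def jzs_ttest_bf(
    t: float,
    n: int,
    design: str = "paired",
    n2: int | None = None,
    scale: float = math.sqrt(2.0) / 2.0,
) -> float:
    """JZS default-prior Bayes factor (BF10) for a t statistic.

    Places a Cauchy prior with the given ``scale`` on the standardised
    effect and integrates it out numerically (equivalently, an inverse-
    chi-square mixture over the prior variance ``g``).  ``design`` is
    "paired" (or one-sample; ``n`` observations, ``n - 1`` df) or
    "two-sample" (``n`` and ``n2`` per group, ``n + n2 - 2`` df, effective
    sample size ``n*n2/(n+n2)``).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if design in ("paired", "one-sample"):
        nu = n - 1
        n_eff = float(n)
    elif design == "two-sample":
        if n2 is None or n2 < 2:
            raise ValueError("two-sample design needs n2 >= 2")
        nu = n + n2 - 2
        n_eff = n * n2 / (n + n2)
    else:
        raise ValueError("design must be 'paired', 'one-sample' or 'two-sample'")

    t2 = t * t
    log_null = -(nu + 1) / 2.0 * math.log1p(t2 / nu)

    def integrand(g: float) -> float:
        log_alt = (
            -0.5 * math.log1p(n_eff * g)
            - (nu + 1) / 2.0 * math.log1p(t2 / ((1.0 + n_eff * g) * nu))
        )
        log_prior = (
            math.log(scale)
            - 0.5 * math.log(2.0 * math.pi)
            - 1.5 * math.log(g)
            - scale * scale / (2.0 * g)
        )
        return math.exp(log_alt + log_prior - log_null)

    # quad cannot mix breakpoints with an infinite bound: integrate the body
    # (with a breakpoint at the prior mode) and the tail separately
    body, err1 = integrate.quad(
        integrand, 0.0, 2.0, points=[scale * scale], limit=200
    )
    tail, err2 = integrate.quad(integrand, 2.0, np.inf, limit=200)
    val, err = body + tail, err1 + err2
    if not math.isfinite(val) or val <= 0 or (err > 1e-6 * max(val, 1.0)):
        raise ArithmeticError(
            f"JZS integration failed: value={val!r}, abserr={err!r}"
        )
    return val
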