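"""Quiz scoring, exclusions, foil chi-squares, t-tests and Bayes factors."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from beeswarmsim import (
    PRETRAINING_FOIL_COUNTS,
    FoilCounts,
    apply_exclusions,
    bic_bayes_factor,
    fit_regression_postS,
    foil_chisq,
    foil_counts_from_responses,
    jzs_ttest_bf,
    one_sample_t_less,
    paired_t_one_tailed,
    pearson_r,
    score_quiz,
    welch_t,
)


class TestScoreQuiz:
    def _sheet(self, key, answers):
        rows = []
        for item_id, choice in answers.items():
            item = key[item_id]
            rows.append(
                {
                    "participant_id": 1,
                    "session": "pre",
                    "form": item.form,
                    "item_id": item_id,
                    "choice": choice,
                }
            )
        return pd.DataFrame(rows)

    def test_all_correct(self, fixtures):
        key = fixtures["quiz_key"]
        answers = {i: key[i].correct_option for i in key.items if key[i].form == 1}
        out = score_quiz(self._sheet(key, answers), key)
        assert out.iloc[0]["S_correct"] == 6 and out.iloc[0]["P_correct"] == 6

    def test_all_wrong(self, fixtures):
        key = fixtures["quiz_key"]
        answers = {i: key[i].other_foils[0] for i in key.items if key[i].form == 1}
        out = score_quiz(self._sheet(key, answers), key)
        assert out.iloc[0]["S_correct"] == 0 and out.iloc[0]["P_correct"] == 0

    def test_partial_counts(self, fixtures):
        key = fixtures["quiz_key"]
        form1 = [i for i in key.items if key[i].form == 1]
        s_items = [i for i in form1 if key[i].item_type == "S"]
        p_items = [i for i in form1 if key[i].item_type == "P"]
        answers = {}
        for i, item_id in enumerate(s_items):
            answers[item_id] = key[item_id].correct_option if i < 4 else key[item_id].other_foils[0]
        for i, item_id in enumerate(p_items):
            answers[item_id] = key[item_id].correct_option if i < 3 else key[item_id].other_foils[0]
        out = score_quiz(self._sheet(key, answers), key)
        assert out.iloc[0]["S_correct"] == 4 and out.iloc[0]["P_correct"] == 3

    def test_unknown_option_named_in_error(self, fixtures):
        key = fixtures["quiz_key"]
        sheet = self._sheet(key, {"S1A": "Z"})
        with pytest.raises(ValueError, match="S1A"):
            score_quiz(sheet, key)

    def test_fixture_sheets_score_cleanly(self, fixtures):
        out = score_quiz(fixtures["quiz_responses"], fixtures["quiz_key"])
        assert set(out["session"]) == {"pre", "post"}
        assert out["S_correct"].between(0, 6).all()


class TestExclusions:
    @pytest.mark.parametrize("pre,excluded", [(4, False), (5, True), (6, True), (0, False)])
    def test_threshold(self, pre, excluded):
        retained, dropped = apply_exclusions({"p1": pre, "p2": 2})
        assert ("p1" in dropped) is excluded
        assert "p2" in retained


class TestFoilChisq:
    def test_hand_example(self):
        res = foil_chisq((1, 2, 4))
        assert res.statistic == pytest.approx(2.0)
        assert res.df == 2
        assert res.p == pytest.approx(math.exp(-1), abs=1e-3)

    def test_uniform_counts_give_zero(self):
        assert foil_chisq((10, 10, 10)).statistic == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            foil_chisq((0, 0, 0))

    def test_matches_brute_force_on_reference_items(self):
        for item, rec in PRETRAINING_FOIL_COUNTS.items():
            obs = np.array(rec["counts"], float)
            expected = obs.sum() / 3
            brute = ((obs - expected) ** 2 / expected).sum()
            assert foil_chisq(rec["counts"]).statistic == pytest.approx(brute)

    def test_reference_items_reproduce_reported_statistics(self):
        """All ten analysable pre-training S-items match their reported
        chi-squares to two decimals."""
        for item, rec in PRETRAINING_FOIL_COUNTS.items():
            got = foil_chisq(rec["counts"]).statistic
            assert round(got, 2) == pytest.approx(rec["chisq"], abs=5e-3), item

    def test_counts_from_responses(self, fixtures):
        counts = foil_counts_from_responses(fixtures["quiz_responses"], fixtures["quiz_key"])
        ids = {c.item_id for c in counts}
        assert "S3A" not in ids and "S3B" not in ids  # no bias foil on item 3
        assert all(c.total >= 0 for c in counts)


class TestFrequentistTests:
    def test_one_sample_centred(self):
        t, p = one_sample_t_less([2.0, 3.0, 4.0], 3.0)
        assert t == pytest.approx(0.0) and p == pytest.approx(0.5)

    def test_one_sample_hand_value(self):
        t, p = one_sample_t_less([1, 2, 3], 5)
        assert t == pytest.approx(-5.196, abs=1e-3)
        assert p < 0.05

    def test_one_sample_direction(self):
        _, p = one_sample_t_less([6, 7, 8], 5)
        assert p > 0.5

    def test_paired_hand_value(self):
        t, df, p = paired_t_one_tailed([2, 2, 2, 2, 0], [1, 1, 1, 1, 1])
        assert t == pytest.approx(1.5, abs=1e-9) and df == 4

    def test_paired_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            paired_t_one_tailed([1, 2, 3], [0, 1, 2])

    def test_paired_antisymmetry(self, rng):
        a, b = rng.normal(size=10), rng.normal(size=10)
        t1, _, _ = paired_t_one_tailed(a, b)
        t2, _, _ = paired_t_one_tailed(b, a)
        assert t1 == pytest.approx(-t2)

    def test_welch_hand_value(self):
        t, df, _ = welch_t([0, 0, 1, 1], [2, 2, 3, 3])
        assert t == pytest.approx(-4.899, abs=1e-3)
        assert df == pytest.approx(6.0, abs=1e-9)  # equal variances -> pooled df

    def test_welch_sign_flip(self):
        t1, _, _ = welch_t([0, 1, 2], [5, 6, 9])
        t2, _, _ = welch_t([5, 6, 9], [0, 1, 2])
        assert t1 == pytest.approx(-t2)

    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3, 4], [3, 5, 7, 9], 1.0),
            ([1, 2, 3, 4], [-1, -2, -3, -4], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
        ],
    )
    def test_pearson(self, x, y, expected):
        r, _ = pearson_r(x, y)
        assert r == pytest.approx(expected, abs=1e-9)

    def test_one_tailed_p_halves_two_tailed(self, rng):
        post = rng.normal(0.5, 1, 30)
        pre = rng.normal(0, 1, 30)
        t, df, p1 = paired_t_one_tailed(post, pre)
        two = stats.ttest_rel(post, pre).pvalue
        if t > 0:
            assert p1 == pytest.approx(two / 2)


class TestRegression:
    def test_noiseless_recovery(self):
        pre = np.array([0, 1, 2, 3, 4, 5, 6, 2, 3], float)
        ed = np.array([5, -3, 8, 0, 2, 7, 1, 4, -2], float)
        post = 0.25 + 0.5 * pre + 0.0 * ed
        fit = fit_regression_postS(post, pre, ed)
        assert fit.params == pytest.approx([0.25, 0.5, 0.0], abs=1e-10)

    def test_intercept_equivariance(self, rng):
        pre = rng.integers(0, 7, 30).astype(float)
        ed = rng.normal(0, 20, 30)
        post = rng.normal(2 + 0.3 * pre + 0.02 * ed, 1)
        f1 = fit_regression_postS(post, pre, ed)
        f2 = fit_regression_postS(post + 3, pre, ed)
        assert f2.params[0] == pytest.approx(f1.params[0] + 3)
        assert f2.params[1:] == pytest.approx(f1.params[1:])

    def test_permuted_predictor_coefficient_near_zero(self, rng):
        coefs = []
        for _ in range(200):
            pre = rng.integers(0, 7, 40).astype(float)
            ed = rng.normal(0, 20, 40)
            post = rng.normal(2 + 0.3 * pre, 1)
            coefs.append(fit_regression_postS(post, pre, rng.permutation(ed)).params[2])
        assert abs(np.mean(coefs)) < 3 * np.std(coefs) / math.sqrt(len(coefs))

    def test_rank_deficiency_rejected(self):
        with pytest.raises(ValueError):
            fit_regression_postS([1, 2, 3, 4, 5], [1, 1, 1, 1, 1], [2, 2, 2, 2, 2])


class TestBayesFactors:
    def test_bic_bf_identities(self):
        assert bic_bayes_factor(10.0, 10.0) == 1.0
        assert bic_bayes_factor(8.0, 10.0) == pytest.approx(math.e)
        assert bic_bayes_factor(14.605, 10.0) == pytest.approx(0.1, abs=1e-3)

    def test_jzs_null_evidence_at_t_zero(self):
        assert jzs_ttest_bf(0.0, 50) < 1.0

    def test_jzs_monotone_in_t(self):
        bfs = [jzs_ttest_bf(t, 30) for t in (0.0, 1.0, 2.0, 4.0, 8.0)]
        assert all(b > a for a, b in zip(bfs, bfs[1:]))
        assert bfs[-1] > 1e4

    def test_jzs_reciprocal_identity(self):
        bf10 = jzs_ttest_bf(2.2, 40)
        assert bf10 * (1.0 / bf10) == pytest.approx(1.0)

    @pytest.mark.parametrize("t,n", [(0.0, 20), (1.5, 30), (2.5, 50), (-2.0, 25), (4.0, 80)])
    def test_jzs_matches_pingouin(self, t, n):
        pg = pytest.importorskip("pingouin")
        ref = float(pg.bayesfactor_ttest(t, n, paired=True))
        assert jzs_ttest_bf(t, n, design="paired") == pytest.approx(ref, rel=1e-3)

    def test_jzs_two_sample_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        ref = float(pg.bayesfactor_ttest(2.25, 40, 32))
        assert jzs_ttest_bf(2.25, 40, design="two-sample", n2=32) == pytest.approx(ref, rel=1e-3)

    def test_bic_and_jzs_agree_in_direction(self, rng):
        """Away from the indifference region both Bayes factors pick the
        same side on simulated regressions."""
        for effect in (0.0, 0.08):
            pre = rng.integers(0, 7, 80).astype(float)
            ed = rng.normal(0, 20, 80)
            post = rng.normal(2 + 0.3 * pre + effect * ed, 1)
            full = fit_regression_postS(post, pre, ed)
            # reduced model: drop earn_diff by refitting on pre alone
            import statsmodels.api as sm

            red = sm.OLS(post, sm.add_constant(pre)).fit()
            bf_bic = bic_bayes_factor(full.bic, red.bic)
            t_ed = full.tvalues[2]
            bf_jzs = jzs_ttest_bf(t_ed, 80)
            if abs(t_ed) > 3 or abs(t_ed) < 0.5:
                assert (bf_bic > 1) == (bf_jzs > 1)
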