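"""Monte-Carlo power of the planned analyses under the latent-learner model.

Simulates cohorts in which a proportion `plearn` of participants become
learners by the final block, then estimates the power of (i) the paired
one-tailed t-test on block-4 vs block-1 earnings, (ii) the paired t-test
on quiz pre/post scores and (iii) the regression of the post-test quiz
score on the pre-test score and the earnings gain, all at the
pre-registered alpha = 0.0322.
"""

import beeswarmsim as bs

ALPHA = 0.0322
print(f"{'test':<22} {'N':>4} {'plearn':>7} {'power':>7} {'mc se':>7}")

for plearn in (0.0, 0.25, 0.5):
    cfg = bs.CohortConfig(50, plearn, n_iterations=500, alpha=ALPHA, seed=11)
    r = bs.power_earnings_ttest(cfg)
    print(f"{'earnings paired t':<22} {50:>4} {plearn:>7.2f} {r.power:>7.3f} {r.mc_std_error:>7.3f}")

cfg = bs.CohortConfig(50, 0.5, n_iterations=500, alpha=ALPHA, seed=12)
r = bs.power_quiz_ttest(cfg, quiz=bs.QuizModel(gain_items=2))
print(f"{'quiz paired t':<22} {50:>4} {0.5:>7.2f} {r.power:>7.3f} {r.mc_std_error:>7.3f}")

cfg = bs.CohortConfig(100, 0.5, n_iterations=500, alpha=ALPHA, seed=13)
r = bs.power_quiz_regression(cfg, quiz=bs.QuizModel(gain_items=2))
print(f"{'transfer regression':<22} {100:>4} {0.5:>7.2f} {r.power:>7.3f} {r.mc_std_error:>7.3f}")

print(
    "\nAt plearn=0 the rejection rate sits at the alpha level (type-I"
    "\ncalibration); power climbs steeply with the proportion of learners."
    "\nThe analytic two-sample power curve explains why waiting pays:"
)
for n in (10, 20, 40, 80, 160, 320):
    p = bs.analytic_ttest_power(0.3, n, alpha=0.05)
    print(f"  d=0.3, n={n:>3}/group: one-tailed t-test power = {p:.3f}")
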