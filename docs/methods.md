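# Methods

## Generative model of a trial

A trial is a pair of cumulative samples. The pink (control) group is i.i.d.
N(0, 1); the blue (experimental) group is i.i.d. N(δ, 1) with δ = 0.3 on
true-effect trials and δ = 0 on null trials. Samples nest cumulatively
through per-group array sizes 10, 20, 40, 80, 160, 320 (each array is a
prefix of the next), so the display only ever accretes points. A stimulus
set of `n_trials` contains exactly `round(n_trials·prop_true)` true trials
(default 50%), shuffled once; each trial is generated from its own child
RNG stream, so trial *i* is reproducible independently of set traversal.

## Evidence

Two per-array summaries are computed:

* **Observed effect size** — Cohen's *d* with pooled n−1 sample variances
  (degrees-of-freedom weighting). The pooled estimator is the standard
  choice; a zero pooled s.d. raises rather than returning ±inf.
* **Log likelihood ratio** — the two hypotheses are simple (blue ~ N(0.3,1)
  vs N(0,1)) and the pink group is identically distributed under both, so
  its density terms cancel exactly, leaving `LLR = δ·Σy − n·δ²/2` on the
  blue sample alone. Natural logarithm throughout. An alternative
  formulation on the blue−pink mean difference has the same sign structure;
  the blue-only form is the one implemented and tested (it matches the
  stated generative model).

The **optimal array index** is the smallest *k* with |LLR_k| ≥ ln 40
(≈ 3.6889; 40:1 odds). We use the exact ln 40 rather than a rounded 3.68 or
3.65 — the difference never changes an index in practice. Trials that never
cross are assigned index 6: the display stops at 320 points, so the bonus
must remain attainable on every trial. Response latencies map to indices by
half-open 2-second windows, `[2(k−1), 2k) → k`, capped at 6 ("under 2 s"
is an exclusive bound, so a boundary latency belongs to the later array).

## Scoring and signal detection

+4 correct / −4 error, +2 bonus only when a correct response is made
*exactly* at the optimal index (not at-or-after). Earnings are the raw sum
including bonuses; payment is `max(points, 0)` pence while analysis
variables keep the signed score. Per block we report earnings, percent
correct, mean array index, mean |LLR| and mean observed d at response, and
the signal-detection pair d′ = z(HR) − z(FAR), β = exp((z²(FAR) − z²(HR))/2)
with "yes" = "true effect". Only degenerate hit/false-alarm rates of
exactly 0 or 1 are replaced, by 1/(2N) and 1 − 1/(2N); interior rates stay
exact. A block containing only one trial type gets NaN SDT indices rather
than an error.

## Latent-learner cohort model

Each participant carries a latent L ∈ {0, 1}; a cohort of N has exactly
`round(N·plearn)` learners (deterministic count — the tables parameterise
the *proportion*, and a fixed count removes one variance source). Everyone
plays the same 80-trial set in an independent random order, 4 blocks of 20.

* **Non-learner behaviour** (all of blocks 1–3, and block 4 when L = 0):
  the response array index is drawn from the empirical initial distribution
  (0.005, 0.022, 0.102, 0.238, 0.358, 0.275 over indices 1–6, taken from
  naive early-block play), and the choice follows the sign of the LLR at
  that index regardless of its magnitude.
* **Learner behaviour** (block 4 when L = 1): respond at the optimal index
  with the sign of the LLR there.

After the sign rule, the choice is flipped to an error independently per
trial with probability 0.30 (non-learners) or 0.10 (learners). These two
rates are free parameters — the design constraint is only that non-learners
err more — and the defaults were set so that initial-block accuracy lands
near 70%, consistent with how hard naive play is in piloting. Several
downstream power values are sensitive to them (see Limitations).

Quiz scores are binomial with no item structure: preS ~ Bin(6, 1/3);
postS ~ Bin(6, 1/3 + L·gain/6) with gain ∈ {0, 1, 2} items (default 2).
Pre and post draws are independent given L.

A deliberate property of this model: learners do *not* raise their mean
array index relative to naive play. The initial index distribution already
has mean 4.75, while the mean threshold-crossing index is ≈ 4.46, so the
learner signature is higher accuracy, d′ and earnings (the bonus), not
longer waiting.

### Fast simulation path

The LLR trajectory depends on the blue sample only through its six
cumulative segment sums, which are independent normals
(ΔS_j ~ N(m_j·δ·truth, m_j) for segment sizes m = 10, 10, 20, 40, 80, 160).
Cohort and power simulations draw these sums directly — six draws per trial
instead of 640 — which is distribution-identical to generating raw trials;
a KS-based parity test asserts agreement with the raw-data path. The
full-fidelity path (raw 320-point samples, per-response records, block
summaries) is used for single sessions and anything needing observed d.

## Power analyses

Per scenario (N, plearn, gain), cohorts are simulated `n_iterations` times
(default 500, with the Monte-Carlo standard error √(p(1−p)/iters) attached
to every estimate) and the planned test is applied at α = 0.0322 — the
printed pre-registered level for a three-look sequential design (0.1/3
would give 0.0333; the printed value is used). A fresh stimulus set is
drawn per iteration by default (an option freezes one set), removing
dependence on any single realisation.

* **Earnings test**: paired t on block-4 − block-1 earnings, *one-tailed*
  (the direction is pre-registered).
* **Quiz test**: paired t on postS − preS, compared to α via the
  **two-sided** p-value by default. This choice reproduces the study's quiz
  power grid across all 24 cells (a one-tailed comparison overshoots every
  cell); the one-tailed variant is available via `alternative="greater"`.
* **Transfer regression**: OLS `postS ~ preS + earn_diff`; the earn_diff
  slope's t against t(N−3), two-sided by default for the same reason.
  Singular designs (e.g. zero variance in earn_diff) are flagged and
  counted as non-rejections.

Analytic two-sample t-test power uses the noncentral t distribution with
noncentrality δ√(n/2) and 2n−2 df; it is cross-checked against a raw-data
Monte-Carlo oracle. `d_to_r` implements r = d/√(d²+4).

## Quiz analytics

Answer sheets are scored against a two-form key (12 items per form, 6 P +
6 S, four options each; the key travels as CSV, making the module
form-agnostic — item text is never needed). Participants scoring 5–6 of 6
on pre-test S-items are excluded from learning analyses (prior mastery).
Error responses on S-items with a designated bias foil are tallied over
(bias, other1, other2) and tested against a uniform null by Pearson
chi-square, df = 2, no continuity correction (a 2×2 concept), p-values
reported raw with no multiplicity adjustment. The packaged reference count
table reproduces all ten reported chi-squares exactly; items 3A/3B have no
bias foil and are excluded by design.

Bayes factors: (i) the BIC approximation for nested OLS models,
BF = exp((BIC_reduced − BIC_full)/2), with BIC from the Gaussian
log-likelihood at the MLE residual variance; (ii) the JZS default-prior
t-test Bayes factor, computed by one-dimensional quadrature over the
effect-size prior (Cauchy scale √2/2 by default, configurable), with the
integrand evaluated in log space and the body and tail integrated
separately for stability. The two agree in direction away from the
indifference region; an independent implementation (pingouin) serves as a
cross-check in the test suite only.

## Problem sizes and numerics

Unit and property tests run at 200–4000 replicates; power cells in the
acceptance suite use the study's 500 iterations (the vectorised quiz t-test
cell uses 4000 for a tighter estimate against a 500-iteration band). The
closed-form LLR is asserted against a pointwise log-density oracle at
1e-10; noiseless regression recovery at 1e-10; reported chi-squares to two
decimals. Monte-Carlo assertions use 3 standard-error bands.

## Limitations

* The learner/non-learner error rates (0.10/0.30) are not identified by the
  design description; power cells for the earnings test at intermediate
  plearn and for the transfer regression vary materially with them. Under
  these defaults the earnings separation between learners and non-learners
  (~61 points per block against ~25-point noise) makes the regression power
  at N = 100, plearn = 0.5, gain = 2 saturate at 1.0, slightly above the
  0.98 this scenario is reported to yield under the original (unpublished)
  settings.
* The cohort model omits P-items, reaction-time noise, fatigue, and any
  learning trajectory in blocks 2–3 (everyone is naive there; only blocks 1
  and 4 feed the analyses).
* The synthetic quiz model has no item-level difficulty or participant
  ability correlation between pre and post, so passing tests say nothing
  about item-level psychometrics of real quiz data.
* Real-participant analyses (mixed models, strategy self-reports,
  demographic comparisons) are out of scope; the statistical operations are
  validated on constructed and simulated data only.
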