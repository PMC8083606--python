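# Methods

## Scoring model

The test yields a joint outcome over three subtests.  Detection is a
3-alternative triangle task (pick the one odorized patch among two blanks).
Intensity is a visual analog rating on the integers 0–100, dichotomized at a
cutoff: **low** means at or below 20, **high** means 21 or above.  The cutoff
convention deserves a note: the rating scale's published dichotomy is
written "≤20" vs ">21", which on an integer reading leaves 21 unassigned; we
resolve it as low ⇔ intensity ≤ 20, so 21 is high.  This is the only reading
consistent with a 0–100 integer scale that also reproduces the published
chance column (below).  Identification is a 4-alternative forced choice; a
failed first attempt triggers a 3-alternative second attempt among the
remaining options, so the second outcome is *structurally* missing whenever
the first succeeds — the package treats a recorded second attempt after a
correct first attempt as a validation error, not as data.

The 12 joint outcomes are numbered in a fixed canonical order (detection
correct before incorrect; within that, first-ID correct, then second-ID
correct, then both wrong; high intensity before low).  The overall accuracy
criterion passes patterns {1, 3, 5, 7}, equivalent to
`intensity high AND (detection OR first identification)`; the test suite
proves the equivalence by enumerating the full grid.

The 9-item reference identification test is scored two ways: the official
three-category rule (anosmia ≤3, hyposmia 4–6, normosmia ≥7) and a binarized
rule (anosmia ≤4, normosmia ≥5) used when comparing pass/fail outcomes with
the rapid test.

## Chance (guessing) model

A zero-smell guesser chooses independently at each forced-choice stage
(detection 1/3, first ID 1/4, second ID 1/3) and rates intensity uniformly
over its integer support.  With support 0..100 the low-intensity mass is
21/101.  Support choice matters at the second decimal: under 0..100 pattern
11 has probability (2/3)(80/101)(3/4)(2/3) = 80/303 ≈ 0.2640, printing as
0.26, whereas a 1..100 support gives 0.267 → 0.27.  Only the 101-point
support reproduces all 12 published two-decimal values, which is why it is
the default (it is configurable).  Probabilities are exact `Fraction`s; the
rounded view uses half-up rounding, the convention of the published table.
The whole-test chance pass probability has the closed form
P(high) · (p_det + (1 − p_det) · p_id1) = 40/101.  A vectorized Monte-Carlo
guesser simulator serves as an internal oracle; the acceptance suite checks
200,000 draws against the analytic values at 3 binomial standard errors.

## Synthetic cohort

The simulator generates the three-group population the evaluation assumes —
111 anosmic, 42 other smell disorders, 154 normosmic by default — with
marginal subtest success probabilities set to the observed group rates
(detection .44/.79/.92; intensity-high .14/.71/1.00; first identification
.34/.76/.92) and demographics matched to the observed means (ages 47±13,
55±10, 47±14 truncated to 18–75; female 71/67/74%; White 90/90/83%).
Second-attempt identification is drawn only when the first attempt fails;
its conditional probability is back-solved so the *whole-group* marginal
matches observation (e.g. anosmic: (26/111)/(1 − 0.34) ≈ 0.355).

Choices the data do not pin down, made once and documented here:

* **Within-respondent dependence.** Only marginals are observed, so subtests
  are independent within a respondent by default.  A latent-ability coupling
  is available (`latent_rho`: shared standard-normal ability entering each
  subtest through a logistic link) for sensitivity analyses; it is not
  mean-preserving and defaults to 0.  Consequence: simulated joint pattern
  counts, and therefore overall pass rates, follow the independence product —
  e.g. anosmic overall ≈ 0.14·(0.44 + 0.56·0.34) ≈ 0.088, close to but not
  equal to the observed 10%.  Passing tests on this simulator certify the
  pipeline's statistical machinery, not the real joint response structure.
* **Intensity shape.** Above the cutoff: discretized truncated normal
  (location 40/50/60, scale 15/20/20 for anosmic/other/normosmic); below:
  uniform on 0..20.  Only the dichotomy is identified by the data; locations
  were chosen so the normosmic mode sits at a moderate-to-strong rating.
* **Reference-test items.** Per-group i.i.d. item success 0.25/0.55/0.90
  (anosmic at the 4-AFC chance level).  Real item difficulties vary; the
  simulator does not model item effects.
* A `pure_guesser` preset sets every stage to its chance level with uniform
  intensity, reproducing the analytic guessing model generatively.

All draws flow from one `numpy` `default_rng` seeded by the cohort spec; the
seed is echoed in output metadata and same-seed runs are byte-identical.

## Proportion statistics

Equality of k proportions uses the Pearson chi-square on the k×2 table
(p-values from the chi-square survival function; no simulation).  Yates
continuity correction is applied only for k = 2 when requested.  Degenerate
pooled margins (all successes or all failures) return statistic 0 with a
low-expected-count flag rather than an error.  The Bayesian counterpart is a
closed-form independent-binomial Bayes factor: independent Beta(a,a) rates
per group (H1) against one shared Beta(a,a) rate (H0), a = 1 by default,
computed with log-Beta functions.  This is deliberately *not* the
mixed-model Bayes factor some analyses report; only qualitative agreement
(overwhelming evidence for the detection/intensity/first-ID group
differences, none for the second attempt) should be expected, and that is
what the tests assert.

## Classification

Features are the detection and first-ID indicators, raw intensity, and
optionally age plus one-hot sex/ethnicity indicators (ethnicity is stored
pre-binarized White/non-White).  The classifier is closed-form two-class
LDA; the pooled covariance is the Gaussian MLE (within-class scatter / n),
under which the score is the exact log-posterior-odds and which matches the
scikit-learn oracle to machine precision.  Singular covariances fall back to
a ridge (λ = 1e-6·trace/d), flagged on the fitted model.  Evaluation:
stratified 80/20 holdout; repeated stratified 10-fold × 5 CV on the training
split; the decision threshold maximizes Youden's J on pooled out-of-fold
training scores; the final model is fit on all training rows and scored once
on the untouched holdout (AUC, sensitivity, specificity, PPV, NPV; the
latter two flagged when a margin is zero).  ROC curves group tied scores;
AUC equals both the trapezoid area and the tied-pair concordance.  DeLong's
variance and paired test use placement values, valid also for the 3-point
curves of single binary features.  Backward feature selection greedily drops
the feature whose removal least degrades CV AUC.  Whether demographics enter
the discriminant is exposed as a flag (`include_demographics`), since either
configuration is defensible; the analysis drivers use the full feature set
and additionally report single-subtest AUCs.

## Sequential Bayes factor design

The monitor consumes a stream of group-labeled pass/fail outcomes,
evaluating the Bayes factor (default: the independent-binomial BF above, on
the two accumulating groups) after every participant once both groups have
reached n0 = 43.  It stops at BF10 > 6 (decide H1), BF10 < 1/3 (decide H0),
or stream exhaustion (cap — the stand-in for a calendar deadline, default
200 per group).  The BF function is pluggable.  Operating characteristics
are Monte-Carlo: alternating balanced accrual of Bernoulli outcomes.  The
acceptance suite uses 500 replicates per scenario, a size at which decision
rates are stable to about ±2 points; under the null the false-H1 rate is
well under 0.10, and under a 0.10-vs-0.94 effect the design decides H1
essentially always at the minimum n.

## Concordance

Two modes on paired respondents, with no default (they answer different
questions): **flower** compares the reference test's item 9 (the same odor
family as the rapid test's single odorant) against the rapid first
identification attempt; **full** compares the reference binarized category
against the rapid overall criterion.  The primary comparison of marginal
pass rates is the (unpaired) Yates two-proportion chi-square, which depends
only on the marginals; McNemar's paired exact test on the discordant cells
is provided as a clearly secondary output.  One rounding quirk is handled
explicitly in the tests: a discordance of 17/148 is 11.49%, which reports as
12% only when first rounded to the half-percent.

## Numerical conventions and limitations

* Exact rational arithmetic for chance probabilities; half-up rounding for
  printed views.
* Non-integer intensity ratings are floored with a warning (VAS widgets may
  emit reals); out-of-range values are rejected with CSV line numbers.
* Stratified splits shuffle within class with the run's seeded generator;
  all reports are reproducible bit-for-bit given a seed.
* The simulator cannot be calibrated to the unobserved joint distribution of
  subtest failures, to real item difficulties, or to subtypes within the
  "other smell disorders" group; conclusions about those require real data.
* Simulation sizes in the test and analysis drivers (10,000 per group for
  calibration checks, 200,000 guessers, 500 sequential-design replicates)
  were chosen to make 3-SE checks sharp while keeping a full run under a few
  minutes on one core.
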