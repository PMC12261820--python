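# Methods

## The problem

In longitudinal cohort surveys, a respondent who starts but does not finish
leaves a *terminal run* of missing items — survey breakoff.  This is
missingness that depends on the unobserved responses themselves (MNAR) and
it cannot be told apart from ordinary item skipping (MAR) by a per-person
percent-missing cutoff: a respondent who quits near the end of a long
instrument can sit below any reasonable cutoff, and a respondent who skips
many scattered items can sit above it.  The package identifies breakoff at
the individual level, separates the two missingness regimes at the cohort
level, and models what predicts breakoff.

## Per-respondent threshold classification

Each respondent's row of missingness flags (1 = missing, 0 = answered) is
treated as a binary sequence over item location j = 0..n−1.  The detector:

1. fits a univariate logistic regression of the flags on j.  Rows are
   usually perfectly separated (an exact step function), under which the
   unpenalized likelihood has no finite maximizer, so an L2 (ridge)
   stabilizer of 1e-3 on the coefficients (in an index axis rescaled to
   [−1, 1]) keeps the fit finite.  The decision boundary −b₀/b₁ is recorded;
   the coefficients themselves are not quantities of record.
2. selects the integer quit index as the accuracy-maximizing step threshold
   t ∈ {0..n} — the step predicts 0 below t and 1 at/above t — with ties
   broken to the **largest** t.  The tie-break prefers the completer call,
   which minimizes false breakoff calls.  Threshold selection is O(n) via a
   cumulative-sum identity: correct(t) = (#zeros before t) + (#ones ≥ t).

Explicit threshold selection, rather than rounding the logistic boundary,
is deliberate.  On a row such as 0,1,0,0,1,1,1,1 the exact logistic MLE
boundary is 2.41, whose ceiling (3) is a strictly worse threshold
(accuracy 6/8) than the optimum t = 4 (accuracy 7/8): logistic loss is not
0–1 loss, and an isolated pre-quit skip drags the boundary left.  Selecting
the threshold by accuracy restores the intended estimand — the first item
of the terminal missing run — and makes the classifier provably agree with
the exhaustive-enumeration oracle (`brute_force_threshold`), which is kept
as an independent O(n²) implementation for cross-checking.

A respondent is a non-completer iff t < n.  Accuracy is the step
prediction's agreement with the row over all n items; each pre-quit skip
costs 1/n.  Cohort accuracy is the unweighted mean over respondents.

Edge conventions: all-zero rows are completers with t = n; all-one rows are
non-completers with t = 0; a row whose only missing item is the last one is
classified as quitting at the last item — logically indistinguishable from
a skip there, and the accuracy-maximizing reading.  Fitted slopes below
1e-9 in magnitude are reported with no boundary (NaN).

The naive comparator (`NaiveCutoffClassifier`) calls non-completer iff the
row missing fraction ≥ a cutoff (default 0.15); on cohorts with late
quitters it under-detects by construction, which is the point of the
comparison.

## MAR/MNAR decomposition

`summed_missingness_series` counts missing responses per item across the
cohort.  Under breakoff this series trends upward (quitters accumulate);
under pure skipping it fluctuates around a constant.  `adf_test` applies
the augmented Dickey-Fuller test (statsmodels `adfuller`) with a constant
deterministic term only — adding a trend term would absorb exactly the
drift being tested for — and AIC lag selection up to the Schwert
rule-of-thumb maximum.  Failing to reject the unit root at α = 0.05 is
reported as MNAR, rejecting as MAR; α, lag order, and the deterministic
specification are recorded in the result so alternatives can be replayed.

A caveat established by simulation (see `tests/test_missingness.py`): on
cohorts whose quit hazard declines over item locations, the cumulative
quitter curve saturates, and the constant-only ADF reads part of that
concavity as mean reversion.  The breakoff verdict is therefore *marginal*
rather than near-certain — MNAR in roughly two-thirds of replicates at the
default study conditions, while the underlying upward trend is present in
every replicate and skip-only cohorts read MAR essentially always.  Users
should treat the verdict as one line of evidence and inspect the
decomposition plot alongside it.

Two summary-statistic comparisons accompany the verdict and accept printed
numbers directly: a pooled-variance (Student) two-sample t-test on
per-person missingness (pooling, not Welch, because the integer
df = n₁ + n₂ − 2 is the convention being matched) and an uncorrected
Pearson χ² on non-completion rates (the uncorrected statistic is the one
reproducible from published counts).

## Section-level attribute model

Sections are the observations; the outcome is the count of respondents
whose quit index falls in the section.  A Poisson GLM with log link
regresses quit counts on standardized mean item location, mean sensitivity
code, and question count, with log(question count) entered as an exposure
offset: longer sections offer more opportunities to quit, and the offset
separates that mechanical exposure from the per-question effect of section
length.  Question count intentionally appears both as offset and as
predictor; the resulting collinearity is tolerated and visible in the
standard errors, not silently resolved.  Exponentiated coefficients are
relative risks.  Fit is summarized by McFadden's pseudo-R² = 1 − ll/ll₀
with the offset retained in the null; which pseudo-R² flavor to use was an
open choice and McFadden is the one implemented and labeled.  Predictors
are z-scored by default (`standardize=False` gives the raw-scale fit) —
the per-unit scale of reported coefficients in the motivating analysis is
unstated, and standardization makes simulated and reported magnitudes
comparable.

## Respondent-level risk model

The outcome is the per-respondent non-completer flag; predictors are
sociodemographic/military covariates, dummy coded against explicit
reference levels, with continuous fields min-max normalized (a
centre-at-minimum-only option exists because both conventions appear in
practice).  The cohort is split 75/25 (seeded, deterministic); the model
minimizes the summed negative log-likelihood plus α·Σ|β| (α = 10 by
default, intercept unpenalized; this is sklearn's saga L1 path at
C = 1/α — the α convention is recorded in the fit metadata because it is
not standardized across software).  Balanced accuracy (mean of sensitivity
and specificity at the 0.5 probability threshold) is reported on both
splits; agreement between them is the no-overfit check.  Wald CIs are not
well defined under L1, so they come from an unpenalized refit restricted to
the L1-selected support and are labeled as post-selection; L1-zeroed terms
are reported as OR 1.00 with p = 1 and no CI.

## The synthetic-cohort generator

The generator defines the study conditions the package is validated under:

- **Instrument**: 250 items in 39 contiguous sections.  Section sizes are
  drawn N(6.44, 5.62) truncated at ≥1 and adjusted to sum to the item
  count.  Each section draws one sensitivity code from {0, 1, 2} with
  p = (0.6168, 0.3264, 0.0568) — solved so the item-level mean is 0.44 and
  the across-section SD of section means is 0.60 — and its items inherit
  the code, so sensitive questions cluster by section as on real
  instruments.
- **Breakoff status**: Bernoulli from a logistic propensity on the
  covariates, with the intercept calibrated by root-finding so the marginal
  rate equals the target (default 15%).  Covariate frequencies default to a
  young, enlisted, active-duty-heavy enrollment wave (e.g. 69.2% male,
  79.8% enlisted, 85.0% active duty) and the propensity log-odds to odds
  ratios of the magnitude reported for breakoff risk factors (e.g. 1.73 for
  one race/ethnicity group, 0.15 for one marital-status group), so the risk
  model faces realistic effect sizes.
- **Quit location**: discrete-time hazard over items,
  h_j = expit(logit(8e-4) + η_j), with η_j linear in the standardized
  section attributes (−0.10 per SD location, +0.16 per SD sensitivity,
  −0.20 per SD count) plus a +1.7 log-boost on the first, consent-adjacent
  section.  These values were calibrated once so the conditional quit
  distribution has mean ≈ 101, SD ≈ 78, and mode at item 0 on the default
  instrument — the stated shape of the phenomenon being emulated.  The
  hazard tilts are deliberately *not* the section-count model's
  coefficients: a −0.64/SD location tilt at item level would force a mean
  quit location near 50, inconsistent with the emulated moments.
- **MAR skips**: each pre-quit item is skipped independently with
  probability 0.006 (≈1.5 skips per completer on 250 items); a per-item
  override map can inject high-skip items to mimic isolated problematic
  questions.  Skips never occur at or after the quit index, by
  construction.
- **Reproducibility**: one `numpy` generator seeded from the config; a
  fixed seed reproduces the cohort byte-identically, and the seed is
  written into the run metadata.

What the generator does **not** emulate: answer content, skip logic and
conditional routing, multiple breakoff-and-return episodes, paper-vs-web
mode effects, longitudinal panels, and within-section item-level
sensitivity variation.  Passing tests on this generator therefore show the
pipeline recovers a clean quit-plus-skip process at realistic scale and
noise; they do not certify behavior under routing logic or resumed
sessions, which the detector's single-threshold model cannot represent.

## Numerical choices and degenerate inputs

- Detector Newton iterations: damped (step-halving) full Newton on the
  2-parameter logistic, batched across respondents in chunks (default 4096
  rows) to bound memory; convergence at coefficient change < 1e-8, cap 100
  iterations.  Results of record (quit index, accuracy, non-completer) are
  exact integers/ratios independent of chunking; fitted coefficients agree
  across chunkings to ~1e-14.
- ADF requires ≥ 20 observations and a non-constant series; constant series
  raise a degenerate-input error rather than returning a verdict.
- χ² requires a non-degenerate 2×2 margin; the all-events / no-events case
  raises.  The zero-variance equal-means t is defined as 0.
- Poisson fit requires ≥ 5 sections and at least one nonzero quit count.
- L1 fit requires both outcome classes in the training split; the
  post-selection refit falling back to penalized coefficients (with
  `converged=False`) if the unpenalized refit fails.

## Problem sizes used in validation

The test suite and acceptance script run cohorts of 400–10,000 respondents
on the 250-item instrument, 500 replicates of the 39-section Poisson
recovery, and 200 replicates per arm of the ADF size/power check — sizes
chosen so the full suite completes in well under a minute of compute per
module while leaving Monte-Carlo error comfortably inside the asserted
bounds.

## Known limitations

- One breakoff episode per respondent; a respondent who quits and returns
  is summarized by whatever single threshold fits their row best.
- The ADF verdict's marginality on saturating breakoff curves (above).
- Post-selection CIs do not account for selection; they are a labeled
  convention, not honest coverage.
- The attribute model's location/count effects are identified across
  sections only; within-section placement is not modeled.
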