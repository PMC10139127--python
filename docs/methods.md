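# Methods

This note documents the statistical procedures the package implements,
the choices made where the design was genuinely open, and what the
synthetic cohorts used by the test suite do and do not demonstrate.

## Data model and quality control

Input is a samples × features matrix of TMM-normalized counts per million
(CPM) and a metadata table mapping each sample to one of two group
labels.  Three QC screens run before modeling:

* **Low expression.**  A feature is removed when its mean CPM across
  samples is strictly below 5, or when it has a zero in any sample.  The
  zero rule doubles as the precondition for ratio construction (no zero
  denominators).  A mean of exactly 5 is retained — the removal
  inequalities are strict throughout the package.
* **Global outliers.**  Each feature is rescaled to mean one
  (division by the feature mean, not subtraction: CPM are nonnegative and
  the resulting scores live on a positive scale, making the screen
  invariant to rescaling the whole matrix).  A sample's score is its mean
  rescaled value; samples outside mean ± 3 SD of the scores are flagged.
  The rule is two-sided: a one-sided "greater than mean − 3 SD" reading
  would flag nearly every sample.
* **Haemolysis.**  The red-blood-cell-enriched markers miR-451a,
  miR-16-5p and miR-486-5p are rescaled to mean one; a sample is flagged
  when its mean marker level exceeds the cohort mean by more than 2 SD.
  One-sided by design: haemolysis only elevates these markers.  All SDs
  are sample SDs (n − 1); flagged samples are excluded from every
  downstream stage unless explicitly retained.

  Known limitation: with several strongly contaminated samples in a small
  cohort the flagged samples inflate the score SD and mask one another;
  the mean + 2 SD rule is reliable at the low contamination rates
  (roughly one sample in twenty) it is meant for, and the test suite
  exercises it in that regime.

## Ratio features and training-set prefilters

Features entering the models are all p(p−1)/2 pairwise ratios, with the
earlier feature (input order) as numerator.  Inside every cross-validation
training set — never on the held-out sample — two screens run:

1. remove a ratio iff its coefficient of variation (sample SD / mean,
   raw ratio values) strictly exceeds 300% in **both** groups;
2. remove a surviving ratio iff its two-sided Mann–Whitney p-value
   strictly exceeds 0.2 (exact null distribution when both groups have
   ≤ 12 samples and the column has no cross-group ties, otherwise the
   tie- and continuity-corrected normal approximation; the 0.2 screen is
   loose enough that the approximation choice is rarely decisive).

**Model scale.**  The penalized and unpenalized logistic models fit
log2-transformed ratios by default (`log_ratios=True`).  Ratios of
log-normal abundances are log-normal, and on the raw scale the L1
logistic loss is dominated by the heavy right tail — in simulation the
raw-scale Lasso reliably passed over the genuinely informative ratio
(best rank-based p-value in the cohort) in favor of spuriously correlated
noise.  The prefilters above still see raw ratio values: the CV > 300%
rule is defined on that scale, and the Mann–Whitney screen is rank-based
and unaffected.  Setting `log_ratios=False` restores raw-scale modeling.

## Penalized selection

The Lasso logistic objective is parametrized glmnet-style,
(1/n)·log-loss + λ‖β‖₁ on internally standardized features, so λ is
comparable across training sets of different sizes.  The grid is
geometric from λ_max (the smallest penalty zeroing all coefficients) down
two decades when p ≥ n (four otherwise), 100 points by default.  Inner
tuning is repeated stratified k-fold CV (default 100 × 10-fold) on
binomial deviance; `lambda.min` minimizes the mean curve and the one-SE
rule takes the largest λ within one standard error (over fold-level
deviances at the minimum) of it.  Folds are stratified by class — at
n ≈ 20 unstratified folds frequently lose a class — and fold draws are
redrawn (up to 100 times) if a training part ever contains one class.
The penalized solve is scikit-learn's liblinear; the intercept is handled
with a large `intercept_scaling` so it is effectively unpenalized.

The **relaxed refit** (relaxed Lasso with φ = 0) is an unpenalized
maximum-likelihood logistic regression on exactly the selected ratios,
computed by an in-package Newton/IRLS engine.  That engine exists because
the jackknife and the step-forward scan need on the order of 10⁵ tiny
weighted refits that differ only in per-sample weights (a deleted sample
is a zero weight); they are solved as one batched Newton iteration over a
weights matrix, and the engine is validated against statsmodels GLM to
10⁻⁶ in the test suite.  Complete or quasi-complete separation — common
with selected ratios at small n — is detected (standardized coefficients
diverging past e³⁰ per SD) and stabilized by a weak ridge (10⁻⁶) rather
than raised, because subsample refits must not abort; the fit carries a
separation flag and predicted probabilities are clipped to stay strictly
inside (0, 1).

## Standard 2-stage nested cross-validation

Outer LOOCV.  Stage 1: per training set, prefilter then tune λ.  Stage 2:
the per-training-set penalties are averaged (arithmetic mean on the λ
scale; geometric by option) and a Lasso at the shared λ̄ selects ratios in
each training set, followed by a relaxed refit and a held-out prediction,
classified at 0.5 (a probability exactly at the threshold counts as
positive, everywhere in the package, including all worst-case rules).

The λ-averaging step couples the training sets: every sample contributes
to the penalties of the splits that contain it, and through λ̄ to every
split.  This is a property of the published protocol and is preserved,
not corrected.  It has a testable consequence: training-set isolation
(mutating a held-out sample never changes its own split's selection)
holds exactly at a *fixed* shared penalty, and the package exposes
`fixed_lambda` for that purpose.

A second consequence shows up under the null.  On permuted labels the
held-out balanced accuracy of this protocol is not centered at 0.5: LOOCV
with a fixed 0.5 cut-point on balanced cohorts is biased *below* chance
(removing a positive sample lowers the training prevalence, pushing
weak models to the wrong side of the threshold), while StaVarSel's global
frequency ranking can push above chance on some seeds.  The package's
null-calibration tests document this behavior rather than assume an
unbiased chance level.

## StaVarSel

Ratios selected in at least 50% of the outer training sets form the
ranked list (count, then mean absolute relaxed coefficient across
selecting splits, then lexical ID — a deterministic ordering).  The
step-forward scan evaluates k = 1 … 10: within each outer training set an
inner LOOCV fits unpenalized logistic models on the top-k ratios and
scores the inner held-out sample at 0.5; the per-training-set error is
the inner misclassification rate and the curve value its mean over
training sets; argmin wins, smallest k on ties; sizes too large for the
inner training sets are skipped.  A single global k and a single global
top-k set are used for all splits, which are then relax-refit per split
for the honest held-out predictions.

In **conservative** mode each inner held-out sample also receives a
jackknife CI from all second single-deletion refits, and a sample counts
as misclassified if *either* the point fit or the CI reaches the wrong
side of 0.5.  Including the point fit makes the conservative error
dominate the point error by construction (with CI-only rules the
dominance would hold only in typical cases, not structurally) and is
strictly more conservative.  Conservative size selection therefore never
scores a model size better than point mode does, and in simulation it
chooses the same or a smaller k on essentially every unstable cohort.

## The three uncertainty estimators

* **Naive (Wald).**  Per class, p̂ ± z·√(p̂(1−p̂)/n) on the
  correct-classification proportion, truncated to [0, 1]; degenerate
  (zero width) at p̂ ∈ {0, 1}.  This is the named default for the "naive"
  estimator; a normal interval on the mean probabilities is the obvious
  alternative reading and is not claimed to reproduce any published
  appendix values.
* **Bootstrap.**  Class-stratified resampling (default B = 2000) of the
  held-out (probability, label) pairs; percentile lower bounds at
  (1−level)/2.  Under perfect separation every resample reproduces the
  same classification and the interval collapses to zero width — the
  estimator is uninformative exactly where a conservative one is needed,
  and the package warns accordingly.
* **Conservative n−2 jackknife.**  For held-out sample i, the training
  set is the cohort minus i (size n−1); each subsample deletes one more
  training sample (size n−2).  The support therefore has at most n−1
  distinct refits per held-out sample.  For cohorts up to
  `exhaustive_max_n = 60` the support is enumerated exhaustively — exact
  and cheaper than resampling; above that, the configured number of
  Monte-Carlo draws (default 1000) samples deletions uniformly.
  Deletions that would empty a class are excluded (redrawn).  Per-sample
  CI bounds are nearest-order-statistic (inverted-CDF) empirical
  quantiles: actual order statistics of the refit probabilities, which
  makes Monte-Carlo and exhaustive bounds coincide on small supports
  (an interpolating quantile convention would not).  At these support
  sizes (n−1 ≤ 40) the 95% bounds are the support minimum and maximum.

  Worst-case classification uses all CIs simultaneously: a negative
  sample is worst-case misclassified iff its CI upper bound ≥ 0.5 or its
  mean ≥ 0.5; a positive sample iff its CI lower bound < 0.5 or its mean
  < 0.5 (the mean guard again makes dominance over the mean-based point
  summary structural).  Worst-case specificity/sensitivity are the
  complements of these rates; balanced accuracy is their mean.

  Refit scope: for StaVarSel outputs the final feature set is fixed and
  each subsample gets a relaxed refit (`final_model`); for standard-CV
  outputs the prefilter and the Lasso selection at the fixed λ̄ are
  re-run per subsample (`selection_and_fit`) — re-optimizing λ itself on
  every subsample is disproportionate to what the deleted sample can
  change and is not done.  Deletion is uniform, not class-stratified.

  The conservative lower bound is not guaranteed to lie below the
  bootstrap lower bound on every cohort — it is a different functional
  of the data, and on occasional cohorts whose jackknife refits are
  stable the bootstrap percentile dips lower; simulations here find the
  conservative bound at or below the bootstrap bound on roughly 85% of
  deliberately unstable small cohorts and far below it in aggregate.

## Synthetic cohorts

The generator draws per-feature baselines from N(4, 1.5²) in log-CPM
(typical features around 50–60 CPM, spanning a few orders of magnitude)
and per-sample values with within-feature noise SD 0.55 in log space —
calibrated so a planted ratio with log2 fold-change 2 at n = 20+20 is
detected (Mann–Whitney p < 0.01) in ≥ 95% of cohorts, while cohorts
without planted pairs stay at the nominal false-positive rate.  Members
of an informative pair share a per-sample latent log-factor (SD 1.5) that
cancels in their ratio; without it a mean-shift on one feature makes
every ratio containing that feature equally informative and "recovering
the planted ratio" would be ill-posed.  Haemolysis spiking multiplies the
marker features in chosen samples; outlier samples multiply a whole
profile.  The `unstable_design` scenario (n = 8+8, 11 features → 55
candidate ratios, one weak pair at log2 FC 0.9) produces the
selection-instability regime the conservative estimator targets.

What these cohorts do not emulate: count-level sampling noise (the
pipeline consumes already-normalized CPM), batch effects, correlated
feature blocks beyond the planted pairs, and class imbalance beyond what
a design specifies.  Passing tests demonstrate the machinery's
correctness and the direction of the method's claims under a clean
log-normal world, not clinical performance.

## Problem sizes and determinism

The test suite and the acceptance script run the full pipelines with
reduced inner cross-validation (5-fold × 2 repeats, 20–25-point penalty
grids) and 10–20 seeded replicates per study on cohorts of 16–40 samples;
the protocol structure is never reduced.  Every stochastic stage —
fold draws, bootstrap, Monte-Carlo jackknife, cohort generation — is
seeded, and serialized result bundles are byte-identical across reruns
with the same configuration and seed (timestamps live in logs, not in
artifacts).

## Known limitations

* The λ-averaging and global-ranking couplings of the published protocol
  mean held-out estimates are not fully insulated from the model-selection
  process; the conservative bounds exist precisely to absorb this.
* Wald bounds collapse at proportions of 0 or 1; bootstrap bounds
  collapse under perfect separation.
* The haemolysis screen can mask multiple contaminated samples.
* Exact Mann–Whitney p-values are used only for groups of ≤ 12 without
  ties; elsewhere the normal approximation decides a deliberately loose
  (p > 0.2) screen.
* No multi-class support, no ROC-threshold optimization, no elastic-net
  mixing, and no feature search beyond the ranked prefix.
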