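# stavarsel

Stable biomarker selection under nested cross-validation, with a
conservative jackknife estimator of prediction-error uncertainty — built
for small two-group expression studies (for example circulating serum
small-extracellular-vesicle miRNA cohorts) where candidate features vastly
outnumber samples and model selection is unstable.

## The problem

A biomarker classifier derived from a samples × features CPM matrix with
p ≫ n overfits easily, and a nested cross-validation — leave-one-out
(LOOCV) in the outer loop, penalized selection tuned in inner loops —
typically selects a *different* feature set in every training set.  Two
consequences follow:

1. the per-training-set models are unstable, so there is no single
   reportable biomarker panel; and
2. the variance of the cross-validated prediction error is badly
   underestimated by the usual estimators, because the held-out
   predictions are correlated across the overlapping training sets.

## The methods implemented

**Feature engineering and QC.**  Features are pairwise expression ratios
x_i/x_j (library-size factors cancel).  Upstream screens remove
low-abundance miRNAs (mean CPM < 5, or any zero count), flag global
outlier samples (mean-one rescaled profile outside mean ± 3 SD) and
detect haemolysed samples from red-blood-cell markers miR-451a,
miR-16-5p and miR-486-5p (marker average above mean + 2 SD).

**Standard 2-stage nested CV.**  Outer LOOCV; inside each training set the
ratios are prefiltered (coefficient of variation > 300% in *both* groups
removed; two-sided Mann–Whitney p > 0.2 removed) and the Lasso penalty λ
is tuned by repeated stratified k-fold CV (deviance loss; `lambda.min` or
the one-SE rule).  The per-training-set penalties are averaged, a Lasso
logistic model at the shared λ̄ selects ratios per training set, an
unpenalized ("relaxed", φ = 0) logistic refit on the selected ratios
predicts the held-out sample, and predictions are classified at 0.5.

**StaVarSel (3-stage stabilized nested CV).**  Ratios selected in ≥ 50% of
the outer training sets form a ranked list.  A step-forward scan then picks
the model size k: for each k, an LOOCV inside every training set fits
unpenalized logistic models on the top-k ratios and the k with the lowest
mean inner prediction error wins (smallest k on ties).  The top-k set is
relax-refit per training set to produce honest held-out predictions.

**Conservative n−2 jackknife bounds.**  For each held-out sample, its
training set (cohort minus that sample) is repeatedly subsampled by
deleting one more sample; the model is refit on every subsample of size
n−2 and the spread of refit predictions gives a per-sample nonparametric
95% CI (enumerated exhaustively for the cohort sizes this tool targets).
Using all CIs *simultaneously* gives worst-case specificity and
sensitivity: a negative sample counts as misclassified whenever its CI
upper bound reaches the 0.5 cut-point, a positive sample whenever its CI
lower bound falls below it.  Wald ("naive") and class-stratified bootstrap
bounds are provided for comparison, and the conservative error can also
drive the step-forward size selection
(`size_selection_mode="conservative"`), which favors smaller, more stable
panels.

## Worked example

```python
from stavarsel import (
    StandardNestedCV, StaVarSelCV, UncertaintyConfig,
    attach_jackknife, build_ratios, conservative_bounds, generate_worked_fixture,
)

expr, meta, truth = generate_worked_fixture()          # 24 samples x 15 miRNAs
ratios = build_ratios(expr)                            # 105 pairwise ratio features
y = (meta["group"] == "B").astype(int).to_numpy()

standard = StandardNestedCV(inner_folds=5, inner_repeats=2, n_lambda=25,
                            random_state=1).fit(ratios, y)
stable = StaVarSelCV(inner_folds=5, inner_repeats=2, n_lambda=25,
                     random_state=1).fit(ratios, y, standard=standard)

dists = attach_jackknife(stable, ratios, y, UncertaintyConfig(), seed=11)
worst = conservative_bounds(dists, stable.records_["true_label"])
```

which prints, with the summary lines shown in the example script:

```
planted ratios:        ['mir-000/mir-001', 'mir-002/mir-003']
standard nested CV:    balanced accuracy 0.917
StaVarSel:             balanced accuracy 1.000, model size 6
top of frequency table:['mir-000/mir-001', 'mir-002/mir-003']
worst-case bounds:     specificity 1.000, sensitivity 0.917
```

The fixture plants two informative ratio pairs among noise; StaVarSel
ranks exactly those two at the top of its selection-frequency table,
outperforms the standard nested CV on the held-out samples, and the
worst-case bounds show how much of that performance survives when every
per-sample jackknife CI is counted against the classifier simultaneously.

The same pipeline is available from the shell for TSV/CSV matrices:

```bash
stavarsel simulate --n-per-group 20 20 --n-features 30 --informative 0,1,1.5 --seed 1 --out cohort/
stavarsel qc        --matrix cohort/matrix.tsv --out qc/
stavarsel stavarsel --matrix qc/matrix.qc.tsv --metadata cohort/metadata.tsv \
                    --comparison A B --seed 1 --out results/
stavarsel report    --matrix qc/matrix.qc.tsv --metadata cohort/metadata.tsv \
                    --comparison A B --seed 1 --out report/
```

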