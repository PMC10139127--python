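"""Prediction-error variance estimators for LOOCV-derived probabilities.

Three estimators of classification-performance uncertainty are provided:

* **naive** — a Wald normal interval on each class's correct-classification
  proportion; biased because held-out predictions are correlated across
  overlapping training sets, and degenerate at proportions of 0 or 1;
* **bootstrap** — class-stratified resampling of the held-out
  (probability, label) pairs; uninformative under perfect separation,
  where every resample reproduces the same error-free classification;
* **conservative** — the Monte-Carlo n−2 jackknife: for each held-out
  sample, its training set (the cohort minus that sample) is repeatedly
  subsampled by deleting one more sample, the model is refit on each
  subsample of size n−2, and the spread of refit predictions gives a
  per-sample nonparametric CI.  The CI bounds of all samples are then used
  *simultaneously*: a negative-class sample counts as misclassified in the
  worst case when its upper bound reaches the threshold, a positive-class
  sample when its lower bound falls below it.  The resulting worst-case
  specificity and sensitivity can never exceed the point estimates.

Because the held-out sample is already excluded, the single-deletion
support has at most n−1 distinct subsamples; when that support is small
(the default for cohorts up to ``exhaustive_max_n``) it is enumerated
exhaustively, which is both cheaper and exact.  CI bounds are
nearest-order-statistic (inverted-CDF) empirical quantiles, so Monte-Carlo
and exhaustive modes agree on small supports.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import fit_logistic_batched, sigmoid
from .config import UncertaintyConfig
from .lasso import LassoLogistic, RelaxedLogistic, _PROB_CLIP
from .nested_cv import ClassificationSummary, StandardNestedCV, summarize_classification
from .ratios import prefilter_mask

logger = logging.getLogger(__name__)


@dataclass
class JackknifeDistribution:
    """Per-sample jackknife refit probabilities and their percentile CI."""

    sample_id: str
    probabilities: np.ndarray
    ci_low: float
    ci_high: float
    mean: float
    n_iterations: int
    mode: str = "exhaustive"

    @classmethod
    def from_probabilities(cls, sample_id, probs, ci_level, mode):
        probs = np.asarray(probs, dtype=float)
        lo = float(np.quantile(probs, (1 - ci_level) / 2, method="inverted_cdf"))
        hi = float(np.quantile(probs, (1 + ci_level) / 2, method="inverted_cdf"))
        return cls(
            sample_id=sample_id,
            probabilities=probs,
            ci_low=lo,
            ci_high=hi,
            mean=float(probs.mean()),
            n_iterations=len(probs),
            mode=mode,
        )


def _deletion_support_fixed(X_train, y_train, x_held):
    """Probability for the held-out point under each single deletion of the
    training set (fixed feature set, relaxed refits, one batched call).

    Deletions that would empty a class are excluded from the support.
    """
    n = len(y_train)
    W = np.ones((n, n))
    W[np.arange(n), np.arange(n)] = 0.0
    valid = np.array(
        [(W[r] * y_train).sum() > 0 and (W[r] * (1 - y_train)).sum() > 0 for r in range(n)]
    )
    if not valid.any():
        raise ValueError("every single deletion empties a class; training set too small")
    coef, intercept, _ = fit_logistic_batched(X_train, y_train, W[valid])
    eta = coef @ np.asarray(x_held, float) + intercept
    return np.clip(sigmoid(eta), _PROB_CLIP, 1 - _PROB_CLIP)


def _deletion_support_refit(
    X_train, y_train, x_held, *, cv_threshold, mwu_alpha_keep, lam,
    model_X_train=None, model_x_held=None,
):
    """Single-deletion support with the selection pipeline re-run per
    subsample: prefilter (on the raw ratio scale), Lasso selection at the
    fixed averaged penalty and relaxed refit (both on the model scale),
    prediction for the held-out point."""
    n = len(y_train)
    if model_X_train is None:
        model_X_train, model_x_held = X_train, x_held
    probs, valid_idx = [], []
    for m in range(n):
        keep_rows = np.arange(n) != m
        y_sub = y_train[keep_rows]
        if y_sub.sum() == 0 or y_sub.sum() == len(y_sub):
            continue
        X_sub = X_train[keep_rows]
        M_sub = model_X_train[keep_rows]
        try:
            keep = prefilter_mask(
                X_sub, y_sub, cv_threshold=cv_threshold, mwu_alpha_keep=mwu_alpha_keep
            )
        except ValueError:
            continue
        if keep.any():
            lasso = LassoLogistic(lam=lam).fit(M_sub[:, keep], y_sub)
            sel = np.flatnonzero(keep)[lasso.selected_]
        else:
            sel = np.array([], dtype=int)
        relaxed = RelaxedLogistic().fit(M_sub[:, sel], y_sub)
        p = relaxed.predict_proba(np.asarray(model_x_held, float)[None, sel])[:, 1][0]
        probs.append(float(p))
        valid_idx.append(m)
    if not probs:
        raise ValueError("no valid jackknife subsample (class lost under every deletion)")
    return np.asarray(probs), np.asarray(valid_idx)


def jackknife_prediction_distribution(
    X_train,
    y_train,
    x_held,
    *,
    sample_id: str = "",
    config: UncertaintyConfig | None = None,
    seed: int = 0,
    model_spec: dict | None = None,
) -> JackknifeDistribution:
    """Monte-Carlo n−2 jackknife distribution for one held-out sample.

    ``X_train``/``y_train`` are the LOOCV training set (cohort minus the
    held-out sample); each iteration deletes one more uniformly chosen
    training sample, refits per ``model_spec`` and records the held-out
    prediction.  ``model_spec``:

    - ``{"scope": "final_model"}`` — relaxed refit on the given columns
      (``X_train`` already restricted to the final feature set);
    - ``{"scope": "selection_and_fit", "lam": ..., "cv_threshold": ...,
      "mwu_alpha_keep": ...}`` — the prefilter + Lasso selection at the
      fixed penalty is re-run on every subsample.

    When the deletion support is small enough (``config.exhaustive_max_n``)
    the enumeration is exhaustive and exact; otherwise
    ``config.jackknife_iterations`` uniform draws (with replacement over
    deletions, i.e. subsampling without replacement within each draw) are
    taken.  Iterations whose subsample loses a class are redrawn.
    """
    config = config or UncertaintyConfig()
    model_spec = model_spec or {"scope": "final_model"}
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    if y_train.dtype != np.dtype(int):
        y_train = y_train.astype(int)
    n = len(y_train)
    if n < 6:
        raise ValueError("training set too small for jackknife (need >= 6)")
    if model_spec["scope"] == "selection_and_fit":
        support, _ = _deletion_support_refit(
            X_train,
            y_train,
            x_held,
            cv_threshold=model_spec.get("cv_threshold", 3.0),
            mwu_alpha_keep=model_spec.get("mwu_alpha_keep", 0.2),
            lam=model_spec["lam"],
            model_X_train=model_spec.get("model_X_train"),
            model_x_held=model_spec.get("model_x_held"),
        )
    else:
        support = _deletion_support_fixed(X_train, y_train.astype(float), x_held)
    if n <= config.exhaustive_max_n:
        return JackknifeDistribution.from_probabilities(
            sample_id, support, config.ci_level, mode="exhaustive"
        )
    rng = np.random.default_rng(seed)
    draws = support[rng.integers(0, len(support), size=config.jackknife_iterations)]
    return JackknifeDistribution.from_probabilities(
        sample_id, draws, config.ci_level, mode="monte_carlo"
    )


def attach_jackknife(
    cv_result,
    X,
    y,
    config: UncertaintyConfig | None = None,
    seed: int = 0,
) -> list[JackknifeDistribution]:
    """Jackknife CI for every held-out sample of a fitted CV object.

    For a fitted :class:`StaVarSelCV` the final feature set is fixed and
    refits are cheap relaxed GLMs; for a fitted :class:`StandardNestedCV`
    the selection pipeline is re-run per subsample at the fixed averaged
    penalty (``selection_and_fit`` scope).  The per-sample summaries are
    written into ``cv_result.records_`` (columns ci_low, ci_high,
    jackknife_mean, jackknife_n).
    """
    config = config or UncertaintyConfig()
    values = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    classes = cv_result.classes_
    y01 = (np.asarray(y) == classes[1]).astype(int)
    n = len(y01)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(2**31, size=n)
    dists = []
    log_ratios = bool(getattr(cv_result, "log_ratios", False))
    model_values = np.log2(values) if log_ratios else values
    if hasattr(cv_result, "final_feature_idx_"):
        idx = cv_result.final_feature_idx_
        for i in range(n):
            tr = np.arange(n) != i
            dists.append(
                jackknife_prediction_distribution(
                    model_values[tr][:, idx],
                    y01[tr],
                    model_values[i, idx],
                    sample_id=str(cv_result.records_["sample_id"].iloc[i]),
                    config=config,
                    seed=int(seeds[i]),
                    model_spec={"scope": "final_model"},
                )
            )
    elif isinstance(cv_result, StandardNestedCV):
        for i in range(n):
            tr = np.arange(n) != i
            spec = {
                "scope": "selection_and_fit",
                "lam": cv_result.lambda_average_,
                "cv_threshold": cv_result.cv_threshold,
                "mwu_alpha_keep": cv_result.mwu_alpha_keep,
                "model_X_train": model_values[tr],
                "model_x_held": model_values[i],
            }
            dists.append(
                jackknife_prediction_distribution(
                    values[tr],
                    y01[tr],
                    values[i],
                    sample_id=str(cv_result.records_["sample_id"].iloc[i]),
                    config=config,
                    seed=int(seeds[i]),
                    model_spec=spec,
                )
            )
    else:
        raise TypeError("cv_result must be a fitted StaVarSelCV or StandardNestedCV")
    rec = cv_result.records_
    rec["ci_low"] = [d.ci_low for d in dists]
    rec["ci_high"] = [d.ci_high for d in dists]
    rec["jackknife_mean"] = [d.mean for d in dists]
    rec["jackknife_n"] = [d.n_iterations for d in dists]
    return dists


# ---------------------------------------------------------------------------
# summaries


def naive_normal_bounds(
    records: pd.DataFrame, config: UncertaintyConfig | None = None
) -> ClassificationSummary:
    """Wald interval on each class's correct-classification proportion.

    At proportions of 0 or 1 the interval collapses to a point — the
    documented failure mode of this estimator.
    """
    config = config or UncertaintyConfig()
    point = summarize_classification(records, config.threshold, tag="naive")
    z = stats.norm.ppf(1 - (1 - config.ci_level) / 2)

    def lower(p, m):
        return float(np.clip(p - z * np.sqrt(p * (1 - p) / m), 0.0, 1.0))

    point.specificity_lower = lower(point.specificity, point.n_negative)
    point.sensitivity_lower = lower(point.sensitivity, point.n_positive)
    point.balanced_accuracy_lower = (point.specificity_lower + point.sensitivity_lower) / 2
    return point


def bootstrap_bounds(
    records: pd.DataFrame, config: UncertaintyConfig | None = None, seed: int = 0
) -> ClassificationSummary:
    """Class-stratified bootstrap of the held-out (probability, label) pairs."""
    config = config or UncertaintyConfig()
    t = config.threshold
    point = summarize_classification(records, t, tag="bootstrap")
    y = records["true_label"].to_numpy()
    p = records["point_probability"].to_numpy(dtype=float)
    neg, pos = p[y == 0], p[y == 1]
    rng = np.random.default_rng(seed)
    spec_b = np.empty(config.bootstrap_B)
    sens_b = np.empty(config.bootstrap_B)
    for b in range(config.bootstrap_B):
        spec_b[b] = (neg[rng.integers(0, len(neg), len(neg))] < t).mean()
        sens_b[b] = (pos[rng.integers(0, len(pos), len(pos))] >= t).mean()
    alpha = (1 - config.ci_level) / 2
    point.specificity_lower = float(np.quantile(spec_b, alpha, method="inverted_cdf"))
    point.sensitivity_lower = float(np.quantile(sens_b, alpha, method="inverted_cdf"))
    point.balanced_accuracy_lower = float(
        np.quantile((spec_b + sens_b) / 2, alpha, method="inverted_cdf")
    )
    if spec_b.std() == 0 and sens_b.std() == 0:
        warnings.warn(
            "bootstrap resamples are constant (perfect separation): the "
            "non-conservative bootstrap cannot estimate the prediction-error "
            "variance here",
            stacklevel=2,
        )
    return point


def conservative_bounds(
    dists: list[JackknifeDistribution],
    labels,
    config: UncertaintyConfig | None = None,
) -> ClassificationSummary:
    """Simultaneous worst-case specificity/sensitivity from per-sample CIs.

    A negative-class sample is worst-case misclassified iff its CI upper
    bound reaches the threshold; a positive-class sample iff its CI lower
    bound falls below it.  The worst case additionally covers the mean
    prediction itself, so the worst-case rates can never exceed the point
    rates computed from the per-sample mean probabilities, which are
    reported alongside in the main summary fields.
    """
    config = config or UncertaintyConfig()
    t = config.threshold
    labels = np.asarray(labels)
    if len(dists) != len(labels):
        raise ValueError("need exactly one jackknife distribution per sample")
    neg = labels == 0
    pos = labels == 1
    ci_low = np.array([d.ci_low for d in dists])
    ci_high = np.array([d.ci_high for d in dists])
    means = np.array([d.mean for d in dists])
    if neg.sum() == 0 or pos.sum() == 0:
        raise ValueError("both classes must be represented")
    spec_wc = float(((ci_high[neg] < t) & (means[neg] < t)).mean())
    sens_wc = float(((ci_low[pos] >= t) & (means[pos] >= t)).mean())
    spec_pt = float((means[neg] < t).mean())
    sens_pt = float((means[pos] >= t).mean())
    return ClassificationSummary(
        estimator="conservative",
        specificity=spec_pt,
        sensitivity=sens_pt,
        balanced_accuracy=(spec_pt + sens_pt) / 2,
        specificity_lower=spec_wc,
        sensitivity_lower=sens_wc,
        balanced_accuracy_lower=(spec_wc + sens_wc) / 2,
        n_negative=int(neg.sum()),
        n_positive=int(pos.sum()),
    )
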