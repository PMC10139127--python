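"""StaVarSel: 3-stage stabilized nested cross-validation.

Stage 1 is the standard nested CV (per-training-set prefilter, penalty
tuning, Lasso selection at the averaged penalty).  Stage 2 counts how
often each ratio was selected across the outer training sets and keeps
those selected in at least 50% of them, ranked by frequency.  Stage 3 is
an iterative step-forward scan: for each candidate model size k, an LOOCV
inside every outer training set fits unpenalized logistic models on the
top-k ranked ratios and scores the inner held-out sample at the 0.5
cut-point; the k minimizing the mean inner prediction error (smallest k
on ties) defines the final feature set, which is then relax-refit in each
training set to predict its held-out sample.

In ``conservative`` size-selection mode each inner held-out sample
additionally receives a jackknife confidence interval from second-level
single-deletion refits, and the per-training-set error is the worst-case
misclassification rate from the CI bounds — which penalizes unstable
model sizes and tends to choose smaller models.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._glm import fit_logistic_batched, sigmoid
from .lasso import RelaxedLogistic, _PROB_CLIP
from .nested_cv import StandardNestedCV, summarize_classification

logger = logging.getLogger(__name__)


def selection_frequency_table(
    per_split_selected,
    per_split_coefs=None,
    frequency_threshold: float = 0.5,
) -> pd.DataFrame:
    """Selection counts across outer training sets, ranked.

    Features below ``frequency_threshold`` are excluded from the returned
    (ranked) table.  Ties in fraction are broken by higher mean absolute
    relaxed coefficient across the selecting splits, then lexically by ID,
    so the ranking is deterministic across reruns.
    """
    n_splits = len(per_split_selected)
    counts: dict[str, int] = {}
    coef_sums: dict[str, float] = {}
    for s, sel in enumerate(per_split_selected):
        for name in sel:
            counts[name] = counts.get(name, 0) + 1
            if per_split_coefs is not None:
                coef_sums[name] = coef_sums.get(name, 0.0) + abs(
                    per_split_coefs[s].get(name, 0.0)
                )
    rows = []
    for name, c in counts.items():
        frac = c / n_splits
        mean_abs = coef_sums.get(name, 0.0) / c if per_split_coefs is not None else 0.0
        rows.append((name, c, frac, mean_abs))
    rows.sort(key=lambda r: (-r[2], -r[3], r[0]))
    table = pd.DataFrame(rows, columns=["ratio_id", "count", "fraction", "mean_abs_coef"])
    table = table[table["fraction"] >= frequency_threshold].reset_index(drop=True)
    if table.empty:
        raise ValueError(
            f"no feature reached selection frequency {frequency_threshold:.0%}; "
            "consider lowering the threshold"
        )
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def _loo_probabilities(Xk, y01, base_weight, members):
    """Inner-LOOCV predictions: for each j in members, fit on the weighted
    training set minus j and predict j.  One batched call."""
    W = np.repeat(base_weight[None, :], len(members), axis=0)
    W[np.arange(len(members)), members] = 0.0
    coef, intercept, _ = fit_logistic_batched(Xk, y01, W)
    eta = (coef * Xk[members]).sum(axis=1) + intercept
    return np.clip(sigmoid(eta), _PROB_CLIP, 1 - _PROB_CLIP)


def _loo_jackknife_ci(Xk, y01, base_weight, members, ci_level):
    """Per inner held-out sample j: CI over all second deletions m != j.

    All (j, m) refits run as one batch.  Deletions that would leave a
    class empty in the subsample are excluded from the support.
    """
    pairs = [(j, m) for j in members for m in members if m != j]
    W = np.repeat(base_weight[None, :], len(pairs), axis=0)
    rows = np.arange(len(pairs))
    js = np.array([p[0] for p in pairs])
    ms = np.array([p[1] for p in pairs])
    W[rows, js] = 0.0
    W[rows, ms] = 0.0
    valid = np.array([(W[r] * y01).sum() > 0 and (W[r] * (1 - y01)).sum() > 0 for r in rows])
    coef, intercept, _ = fit_logistic_batched(Xk, y01, W[valid])
    eta = (coef * Xk[js[valid]]).sum(axis=1) + intercept
    probs = np.clip(sigmoid(eta), _PROB_CLIP, 1 - _PROB_CLIP)
    lo_q, hi_q = (1 - ci_level) / 2, (1 + ci_level) / 2
    ci = {}
    jv = js[valid]
    for j in members:
        pj = probs[jv == j]
        if pj.size == 0:
            raise RuntimeError("no valid jackknife subsample for an inner sample")
        ci[j] = (
            float(np.quantile(pj, lo_q, method="inverted_cdf")),
            float(np.quantile(pj, hi_q, method="inverted_cdf")),
        )
    return ci


def step_forward_size_selection(
    X,
    y01,
    ranked_ids,
    *,
    max_model_size: int = 10,
    mode: str = "point",
    threshold: float = 0.5,
    ci_level: float = 0.95,
    feature_names=None,
) -> pd.DataFrame:
    """Step-forward scan of the number of top-ranked ratios.

    For each k the mean inner-LOOCV prediction error across all outer
    training sets is computed (worst-case error from jackknife CI bounds
    in ``conservative`` mode).  Returns the error curve with attribute
    ``chosen_k`` (argmin, smallest k on ties).  Sizes too large for the
    inner training sets are skipped.
    """
    if len(ranked_ids) == 0:
        raise ValueError("ranked feature list is empty")
    if isinstance(X, pd.DataFrame):
        feature_names = np.asarray(X.columns, dtype=object)
        values = X.to_numpy(dtype=float)
    else:
        values = np.asarray(X, dtype=float)
        feature_names = np.asarray(feature_names, dtype=object)
    name_to_idx = {n: i for i, n in enumerate(feature_names)}
    ranked_idx = np.array([name_to_idx[r] for r in ranked_ids])
    n = len(y01)
    y01 = np.asarray(y01)
    k_max = min(max_model_size, len(ranked_idx))
    rows = []
    for k in range(1, k_max + 1):
        # inner training sets have n-2 samples; need >= k+1 for the fit
        if k + 1 > n - 2:
            logger.warning("model size k=%d skipped: inner training sets too small", k)
            continue
        Xk = values[:, ranked_idx[:k]]
        errors = []
        for s in range(n):
            members = np.array([j for j in range(n) if j != s])
            base_w = np.ones(n)
            base_w[s] = 0.0
            probs = _loo_probabilities(Xk, y01, base_w, members)
            mis = (probs >= threshold) != (y01[members] == 1)
            if mode == "conservative":
                # worst case over the point fit and all subsample refits:
                # a sample already misclassified by the point fit stays
                # misclassified, so the conservative error never falls
                # below the point error
                ci = _loo_jackknife_ci(Xk, y01, base_w, members, ci_level)
                ci_mis = np.array(
                    [
                        (ci[j][1] >= threshold) if y01[j] == 0 else (ci[j][0] < threshold)
                        for j in members
                    ]
                )
                mis = mis | ci_mis
            errors.append(float(np.mean(mis)))
        rows.append((k, float(np.mean(errors))))
    if not rows:
        raise ValueError("no model size was estimable")
    curve = pd.DataFrame(rows, columns=["k", "error"])
    curve.attrs["chosen_k"] = int(curve.loc[curve["error"].idxmin(), "k"])
    return curve


class StaVarSelCV(ClassifierMixin, BaseEstimator):
    """Stabilized variable selection within nested cross-validation.

    ``fit`` runs the full 3-stage procedure and exposes:

    ``frequency_table_`` : ranked selection-frequency DataFrame
    ``step_forward_curve_`` : model-size error curve (attrs["chosen_k"])
    ``chosen_k_`` / ``final_feature_ids_`` : the selected model size and set
    ``records_`` / ``summary_`` : held-out predictions and their summary
    ``final_model_`` : relaxed fit of the final set on all samples,
        used by ``predict_proba`` / ``predict`` for new data.

    A fitted :class:`StandardNestedCV` sharing the same data and settings
    can be passed to ``fit`` to reuse its (expensive) stage-1 selections.
    """

    def __init__(
        self,
        inner_folds: int = 10,
        inner_repeats: int = 100,
        lambda_rule: str = "min",
        n_lambda: int = 100,
        cv_threshold: float = 3.0,
        mwu_alpha_keep: float = 0.2,
        classification_threshold: float = 0.5,
        frequency_threshold: float = 0.5,
        max_model_size: int = 10,
        size_selection_mode: str = "point",
        ci_level: float = 0.95,
        pos_label=None,
        random_state: int = 0,
        log_ratios: bool = True,
    ):
        self.inner_folds = inner_folds
        self.inner_repeats = inner_repeats
        self.lambda_rule = lambda_rule
        self.n_lambda = n_lambda
        self.cv_threshold = cv_threshold
        self.mwu_alpha_keep = mwu_alpha_keep
        self.classification_threshold = classification_threshold
        self.frequency_threshold = frequency_threshold
        self.max_model_size = max_model_size
        self.size_selection_mode = size_selection_mode
        self.ci_level = ci_level
        self.pos_label = pos_label
        self.random_state = random_state
        self.log_ratios = log_ratios

    def fit(self, X, y, standard: StandardNestedCV | None = None):
        if standard is None:
            standard = StandardNestedCV(
                inner_folds=self.inner_folds,
                inner_repeats=self.inner_repeats,
                lambda_rule=self.lambda_rule,
                n_lambda=self.n_lambda,
                cv_threshold=self.cv_threshold,
                mwu_alpha_keep=self.mwu_alpha_keep,
                classification_threshold=self.classification_threshold,
                pos_label=self.pos_label,
                random_state=self.random_state,
                log_ratios=self.log_ratios,
            ).fit(X, y)
        else:
            check_is_fitted(standard, "splits_")
        self.standard_cv_ = standard
        self.classes_ = standard.classes_
        y01 = (np.asarray(y) == self.classes_[1]).astype(int)

        per_split_selected = [s.selected_names for s in standard.splits_]
        per_split_coefs = [s.relaxed_coef for s in standard.splits_]
        self.frequency_table_ = selection_frequency_table(
            per_split_selected, per_split_coefs, self.frequency_threshold
        )
        ranked = list(self.frequency_table_["ratio_id"])

        values = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        names = (
            np.asarray(X.columns, dtype=object)
            if isinstance(X, pd.DataFrame)
            else np.array([f"x{i}" for i in range(values.shape[1])], dtype=object)
        )
        model_values = standard._model_space(values)
        self.step_forward_curve_ = step_forward_size_selection(
            model_values,
            y01,
            ranked,
            max_model_size=self.max_model_size,
            mode=self.size_selection_mode,
            threshold=self.classification_threshold,
            ci_level=self.ci_level,
            feature_names=names,
        )
        self.chosen_k_ = self.step_forward_curve_.attrs["chosen_k"]
        self.final_feature_ids_ = ranked[: self.chosen_k_]
        idx = [int(np.flatnonzero(names == r)[0]) for r in self.final_feature_ids_]
        n = len(y01)
        probs = np.empty(n)
        self.per_split_final_ = []
        for i in range(n):
            tr = np.arange(n) != i
            relaxed = RelaxedLogistic(threshold=self.classification_threshold).fit(
                model_values[tr][:, idx], y01[tr]
            )
            probs[i] = relaxed.predict_proba(model_values[i : i + 1, idx])[:, 1][0]
            self.per_split_final_.append(relaxed)
        t = self.classification_threshold
        self.records_ = pd.DataFrame(
            {
                "sample_id": standard.sample_ids_,
                "true_label": y01,
                "point_probability": probs,
                "predicted_label": (probs >= t).astype(int),
            }
        )
        self.summary_ = summarize_classification(self.records_, t)
        self.final_feature_idx_ = np.asarray(idx)
        self.final_model_ = RelaxedLogistic(threshold=t).fit(model_values[:, idx], y01)
        self.feature_names_in_ = names
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "final_model_")
        if isinstance(X, pd.DataFrame):
            Xf = X[self.final_feature_ids_].to_numpy(dtype=float)
        else:
            Xf = np.asarray(X, dtype=float)[:, self.final_feature_idx_]
        Xf = self.standard_cv_._model_space(Xf)
        return self.final_model_.predict_proba(Xf)

    def predict(self, X):
        p = self.predict_proba(X)[:, 1]
        return self.classes_[(p >= self.classification_threshold).astype(int)]

    @property
    def balanced_accuracy_(self) -> float:
        check_is_fitted(self, "summary_")
        return self.summary_.balanced_accuracy
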