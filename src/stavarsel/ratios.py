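"""Pairwise expression-ratio features and the per-training-set prefilters.

The feature type modeled throughout the package is the miRNA-ratio: the
quotient of two features' CPM values within one sample.  Ratios are
self-normalizing (library-size factors cancel), which is why they are the
preferred substrate for circulating-RNA biomarker models.

Two prefilters are applied inside every cross-validation training set
before penalized selection:

1. a coefficient-of-variation filter that removes a ratio only when its
   within-group CV (SD/mean) exceeds the threshold in *both* comparison
   groups (default 300%), and
2. a Mann-Whitney U screen that removes ratios whose two-sided p-value
   exceeds the keep threshold (default 0.2) -- a deliberately loose screen
   that discards only clearly uninformative ratios.

Both removals use strict inequalities: a CV of exactly 300% or a p-value of
exactly 0.2 is retained.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


def build_ratios(expr: pd.DataFrame) -> pd.DataFrame:
    """All pairwise ratio features of an expression matrix.

    Parameters
    ----------
    expr : DataFrame, samples x features, strictly positive values.

    Returns
    -------
    DataFrame, samples x p*(p-1)/2 ratios.  For each unordered pair (i, j)
    with i before j in column order, the column ``"fi/fj"`` holds
    ``expr[fi] / expr[fj]`` per sample.
    """
    values = expr.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("expression matrix contains non-finite values")
    zero_cols = expr.columns[(values <= 0).any(axis=0)]
    if len(zero_cols):
        raise ValueError(
            "ratio construction requires strictly positive values; "
            f"features with zeros/negatives: {list(zero_cols[:5])} "
            "(run the low-expression QC filter first)"
        )
    p = values.shape[1]
    iu, ju = np.triu_indices(p, k=1)
    ratio_values = values[:, iu] / values[:, ju]
    cols = [f"{expr.columns[i]}/{expr.columns[j]}" for i, j in zip(iu, ju)]
    return pd.DataFrame(ratio_values, index=expr.index, columns=cols)


class RatioFeatures(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer wrapping :func:`build_ratios`."""

    def fit(self, X, y=None):
        X = self._as_frame(X)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "feature_names_in_")
        X = self._as_frame(X)
        if list(X.columns) != list(self.feature_names_in_):
            X = X[list(self.feature_names_in_)]
        return build_ratios(X)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "feature_names_in_")
        names = self.feature_names_in_
        return np.array(
            [f"{a}/{b}" for a, b in itertools.combinations(names, 2)], dtype=object
        )

    @staticmethod
    def _as_frame(X):
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


def mann_whitney_pvalues(X: np.ndarray, y: np.ndarray, exact_max_n: int = 12) -> np.ndarray:
    """Two-sided Mann-Whitney U p-value per column of X for binary y.

    Exact null distribution when both groups have <= ``exact_max_n``
    samples and the column has no cross-group ties; otherwise the normal
    approximation with tie and continuity corrections.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    a = X[y == np.unique(y)[0]]
    b = X[y != np.unique(y)[0]]
    pvals = np.empty(X.shape[1])
    small = a.shape[0] <= exact_max_n and b.shape[0] <= exact_max_n
    if small:
        # columns with cross-group ties fall back to the tie-corrected
        # normal approximation; the rest use the exact null distribution
        sorted_cols = np.sort(np.vstack([a, b]), axis=0)
        has_ties = (np.diff(sorted_cols, axis=0) == 0).any(axis=0)
    else:
        has_ties = np.ones(X.shape[1], dtype=bool)
    exact_cols = ~has_ties
    if exact_cols.any():
        pvals[exact_cols] = stats.mannwhitneyu(
            a[:, exact_cols], b[:, exact_cols], alternative="two-sided",
            method="exact", axis=0,
        ).pvalue
    if has_ties.any():
        pvals[has_ties] = stats.mannwhitneyu(
            a[:, has_ties], b[:, has_ties], alternative="two-sided",
            method="asymptotic", axis=0,
        ).pvalue
    return pvals


def coefficient_of_variation(X: np.ndarray) -> np.ndarray:
    """Per-column SD/mean with the sample SD (ddof=1)."""
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(mean != 0, sd / mean, np.inf)


def prefilter_mask(
    X,
    y,
    *,
    cv_threshold: float = 3.0,
    mwu_alpha_keep: float = 0.2,
    return_details: bool = False,
):
    """Boolean keep-mask for ratio columns on a training set.

    Step 1 removes a column iff its within-group CV strictly exceeds
    ``cv_threshold`` in *both* groups.  Step 2 removes a surviving column
    iff its two-sided Mann-Whitney p-value strictly exceeds
    ``mwu_alpha_keep``.  Both statistics are computed on the supplied
    (training) samples only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    labels = np.unique(y)
    if labels.size != 2:
        raise ValueError(f"expected exactly two groups, got {labels!r}")
    for lab in labels:
        if (y == lab).sum() < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 training samples; CV undefined")
    cv_a = coefficient_of_variation(X[y == labels[0]])
    cv_b = coefficient_of_variation(X[y == labels[1]])
    keep_cv = ~((cv_a > cv_threshold) & (cv_b > cv_threshold))
    pvals = np.full(X.shape[1], np.nan)
    if keep_cv.any():
        pvals[keep_cv] = mann_whitney_pvalues(X[:, keep_cv], y)
    keep = keep_cv & ~(pvals > mwu_alpha_keep)
    if return_details:
        return keep, {"cv_group_a": cv_a, "cv_group_b": cv_b, "mwu_p": pvals}
    return keep


class RatioPrefilter(TransformerMixin, BaseEstimator):
    """Supervised column selector applying the CV and Mann-Whitney screens.

    Parameters
    ----------
    cv_threshold : float, default 3.0
        Within-group coefficient-of-variation threshold (3.0 = 300%).
    mwu_alpha_keep : float, default 0.2
        Columns with two-sided Mann-Whitney p > this value are removed.
    """

    def __init__(self, cv_threshold: float = 3.0, mwu_alpha_keep: float = 0.2):
        self.cv_threshold = cv_threshold
        self.mwu_alpha_keep = mwu_alpha_keep

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            self.feature_names_in_ = np.array([f"x{i}" for i in range(values.shape[1])], dtype=object)
        self.n_features_in_ = values.shape[1]
        self.support_, self.details_ = prefilter_mask(
            values,
            y,
            cv_threshold=self.cv_threshold,
            mwu_alpha_keep=self.mwu_alpha_keep,
            return_details=True,
        )
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "support_")
        return self.feature_names_in_[self.support_]
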