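"""L1-penalized logistic regression and the relaxed (unpenalized) refit.

The penalty is parametrized glmnet-style: the objective is
(1/n) * binomial log-loss + lambda * ||beta||_1 with features standardized
internally, so lambda values are comparable across training sets of
different sizes and the inner-CV "lambda.min"/"one-SE" rules carry their
usual meaning.  The actual penalized solve is delegated to scikit-learn's
liblinear coordinate-descent solver (C = 1 / (n * lambda)).

The relaxed refit ("relaxed Lasso with phi = 0") is an unpenalized
maximum-likelihood logistic regression on exactly the Lasso-selected
features; with small n it frequently meets complete or quasi-complete
separation, which is flagged and stabilized by a weak ridge rather than
raised, because jackknife subsample refits must not abort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm._base import _fit_liblinear
from sklearn.utils.validation import check_is_fitted

from ._glm import fit_logistic, logistic_deviance, sigmoid
from .config import CVConfig

_PROB_CLIP = 1e-12


def _as_array(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def lambda_grid(X, y, n_lambda: int = 100, lambda_min_ratio: float | None = None) -> np.ndarray:
    """Geometric penalty grid from the smallest all-zero lambda downwards.

    lambda_max = max_j |<x_j_std, y - ybar>| / n on standardized features:
    the smallest penalty at which every coefficient is exactly zero.  The
    default depth follows the usual convention: two decades when p >= n
    (the high-dimensional regime this pipeline lives in), four otherwise.
    """
    X = _as_array(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if lambda_min_ratio is None:
        lambda_min_ratio = 1e-2 if X.shape[1] >= n else 1e-4
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    lam_max = np.abs(Xs.T @ (y - y.mean())).max() / n
    lam_max = max(lam_max, 1e-8)
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


@dataclass
class LambdaCVResult:
    lambda_min: float
    lambda_one_se: float
    grid: np.ndarray
    mean_deviance: np.ndarray
    se_at_min: float

    def by_rule(self, rule: str) -> float:
        return self.lambda_min if rule == "min" else self.lambda_one_se


class LassoLogistic(ClassifierMixin, BaseEstimator):
    """Logistic regression with an L1 penalty at a fixed glmnet-scale lambda.

    Attributes after fit: ``coef_`` and ``intercept_`` on the original
    feature scale, ``selected_`` (indices of non-zero coefficients) and
    ``selected_feature_names_``.
    """

    def __init__(self, lam: float = 0.1, max_iter: int = 5000, tol: float = 1e-8, strict: bool = True):
        self.lam = lam
        self.max_iter = max_iter
        self.tol = tol
        self.strict = strict

    def fit(self, X, y):
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        names = (
            np.asarray(X.columns, dtype=object)
            if isinstance(X, pd.DataFrame)
            else np.array([f"x{i}" for i in range(np.shape(X)[1])], dtype=object)
        )
        X = _as_array(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("binary labels required")
        yb = (y == self.classes_[1]).astype(float)
        n = len(yb)
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Xs = (X - mu) / sd
        clf = LogisticRegression(
            l1_ratio=1.0,
            C=1.0 / (n * self.lam),
            solver="liblinear",
            intercept_scaling=100.0,
            tol=self.tol,
            max_iter=self.max_iter,
            random_state=0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(Xs, yb)
        if clf.n_iter_[0] >= self.max_iter and self.strict:
            raise RuntimeError(
                f"Lasso did not converge at lambda={self.lam:g} with {X.shape[1]} features"
            )
        coef_std = clf.coef_[0]
        self.coef_ = coef_std / sd
        self.intercept_ = float(clf.intercept_[0] - (coef_std * mu / sd).sum())
        self.selected_ = np.flatnonzero(coef_std != 0.0)
        self.feature_names_in_ = names
        self.selected_feature_names_ = names[self.selected_]
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        return _as_array(X) @ self.coef_ + self.intercept_

    def predict_proba(self, X):
        p = sigmoid(self.decision_function(X))
        p = np.clip(p, _PROB_CLIP, 1 - _PROB_CLIP)
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]


class RelaxedLogistic(ClassifierMixin, BaseEstimator):
    """Unpenalized ML logistic regression on a fixed feature set.

    With zero input columns this is the intercept-only model predicting the
    training prevalence.  ``separation_`` is True when the MLE diverged
    (complete/quasi-complete separation); the reported coefficients then
    come from a weakly ridge-stabilized fit and predicted probabilities
    stay strictly inside (0, 1).
    """

    def __init__(self, threshold: float = 0.5):
        self.threshold = threshold

    def fit(self, X, y):
        X = _as_array(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size == 1:
            # degenerate training set: constant prediction at the single class
            self.classes_ = np.array(sorted({self.classes_[0], "__other__"}, key=str))
        yb = (y == self.classes_[-1]).astype(float)
        n, k = X.shape
        if k > 0 and n < k + 1:
            raise ValueError(f"need at least {k + 1} samples for {k} features, got {n}")
        coef, intercept, sep = fit_logistic(X, yb)
        self.coef_ = coef
        self.intercept_ = float(intercept)
        self.separation_ = sep
        self.n_features_in_ = k
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = _as_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"model fitted on {self.n_features_in_} features, got {X.shape[1]}"
            )
        return X @ self.coef_ + self.intercept_

    def predict_proba(self, X):
        p = sigmoid(self.decision_function(X))
        p = np.clip(p, _PROB_CLIP, 1 - _PROB_CLIP)
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] >= self.threshold).astype(int)]

    def training_deviance(self, X, y):
        yb = (np.asarray(y) == self.classes_[-1]).astype(float)
        return float(logistic_deviance(yb, self.predict_proba(X)[:, 1]))


def _fold_path_probs(X, y, grid, tr, va):
    """Validation-fold probabilities along the penalty grid.

    Standardizes once per fold and calls the liblinear solver directly
    (the estimator wrapper's input validation would dominate the inner-CV
    cost at these problem sizes); numerically identical to fitting
    :class:`LassoLogistic` at each grid value.
    """
    X_tr, y_tr = X[tr], y[tr]
    mu = X_tr.mean(axis=0)
    sd = X_tr.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xs = (X_tr - mu) / sd
    Xv = (X[va] - mu) / sd
    n = len(y_tr)
    probs = np.empty((len(grid), len(va)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for g, lam in enumerate(grid):
            coef, intercept, _n_iter = _fit_liblinear(
            Xs, y_tr, 1.0 / (n * lam), True, 100.0, None, "l1", False, 0,
                2000, 1e-7, random_state=0,
            )
            p = sigmoid(Xv @ coef[0] + float(np.asarray(intercept).ravel()[0]))
            probs[g] = np.clip(p, _PROB_CLIP, 1 - _PROB_CLIP)
    return probs


def _fold_deviances(X, y, grid, folds):
    """Per-(fold, lambda) mean held-out binomial deviance."""
    out = np.empty((len(folds), len(grid)))
    for f, (tr, va) in enumerate(folds):
        probs = _fold_path_probs(X, y, grid, tr, va)
        yv = y[va].astype(float)
        out[f] = logistic_deviance(yv, probs) / len(va)
    return out


def _misclass_fold(X, y, grid, folds, threshold):
    out = np.empty((len(folds), len(grid)))
    for f, (tr, va) in enumerate(folds):
        probs = _fold_path_probs(X, y, grid, tr, va)
        out[f] = ((probs >= threshold) != (y[va] == 1)).mean(axis=1)
    return out


def optimize_lambda(X, y, config: CVConfig | None = None, seed: int = 0) -> LambdaCVResult:
    """Repeated stratified k-fold CV over the penalty grid.

    Deviance curves from all fold-fits are averaged; ``lambda_min``
    minimizes the mean curve and ``lambda_one_se`` is the largest grid
    value whose mean deviance is within one standard error (SE of the
    fold-level deviances at the minimum) of the minimum.
    """
    config = config or CVConfig()
    X = _as_array(X)
    y01 = _binarize(y)
    grid = lambda_grid(X, y01, config.n_lambda, config.lambda_min_ratio)
    rng = np.random.default_rng(seed)
    folds = []
    for _rep in range(config.inner_repeats):
        folds.extend(_stratified_folds(y01, config.inner_folds, rng))
    if config.inner_loss == "misclassification":
        dev = _misclass_fold(X, y01, grid, folds, config.classification_threshold)
    else:
        dev = _fold_deviances(X, y01, grid, folds)
    mean_dev = dev.mean(axis=0)
    i_min = int(np.argmin(mean_dev))
    se = float(dev[:, i_min].std(ddof=1) / np.sqrt(dev.shape[0])) if dev.shape[0] > 1 else 0.0
    within = mean_dev <= mean_dev[i_min] + se
    i_1se = int(np.flatnonzero(within)[0])  # grid is decreasing, first = largest lambda
    return LambdaCVResult(
        lambda_min=float(grid[i_min]),
        lambda_one_se=float(grid[i_1se]),
        grid=grid,
        mean_deviance=mean_dev,
        se_at_min=se,
    )


def _binarize(y):
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("binary labels required")
    return (y == classes[1]).astype(int)


def _stratified_folds(y01, k, rng, max_attempts: int = 100):
    """Stratified k-fold index pairs; redraws until every training part
    contains both classes (hard error after ``max_attempts``)."""
    for _ in range(max_attempts):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(rng.integers(2**31)))
        folds = list(skf.split(np.zeros(len(y01)), y01))
        if all(len(np.unique(y01[tr])) == 2 for tr, _ in folds):
            return folds
    raise RuntimeError("could not draw stratified folds with both classes in every training part")
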