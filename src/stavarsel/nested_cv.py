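"""Standard 2-stage nested cross-validation with a LOOCV outer loop.

Protocol: every sample is held out once; within each training set the
ratio prefilters are applied and the Lasso penalty is tuned by repeated
stratified k-fold CV; the per-training-set penalties are then averaged
(a deliberate, protocol-level coupling across training sets) and a Lasso
fit at the shared averaged penalty selects features in each training set;
an unpenalized relaxed refit on the selected features produces the
held-out sample's prediction probability, classified at the 0.5 cut-point.

Specificity is the fraction of negative-class samples with probability
below the threshold, sensitivity the fraction of positive-class samples
at or above it ("balanced accuracy" = their mean).  A probability exactly
at the threshold classifies as positive, everywhere in the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .config import CVConfig
from .lasso import LassoLogistic, RelaxedLogistic, optimize_lambda
from .ratios import prefilter_mask

logger = logging.getLogger(__name__)


@dataclass
class ClassificationSummary:
    """Specificity / sensitivity / balanced accuracy with optional bounds."""

    estimator: str
    specificity: float
    sensitivity: float
    balanced_accuracy: float
    specificity_lower: float | None = None
    sensitivity_lower: float | None = None
    balanced_accuracy_lower: float | None = None
    n_negative: int = 0
    n_positive: int = 0

    def to_dict(self) -> dict:
        return {
            "estimator": self.estimator,
            "specificity": self.specificity,
            "sensitivity": self.sensitivity,
            "balanced_accuracy": self.balanced_accuracy,
            "specificity_lower": self.specificity_lower,
            "sensitivity_lower": self.sensitivity_lower,
            "balanced_accuracy_lower": self.balanced_accuracy_lower,
            "n_negative": self.n_negative,
            "n_positive": self.n_positive,
        }


def summarize_classification(
    records: pd.DataFrame,
    threshold: float = 0.5,
    prob_column: str = "point_probability",
    tag: str = "point",
) -> ClassificationSummary:
    """Point-estimate summary from per-sample held-out probabilities.

    ``records`` needs columns ``true_label`` (0 = negative, 1 = positive)
    and ``prob_column``.
    """
    if records.empty:
        raise ValueError("no prediction records")
    y = records["true_label"].to_numpy()
    p = records[prob_column].to_numpy(dtype=float)
    n_neg = int((y == 0).sum())
    n_pos = int((y == 1).sum())
    if n_neg == 0 or n_pos == 0:
        raise ValueError("both classes must be represented in the records")
    spec = float((p[y == 0] < threshold).mean())
    sens = float((p[y == 1] >= threshold).mean())
    return ClassificationSummary(
        estimator=tag,
        specificity=spec,
        sensitivity=sens,
        balanced_accuracy=(spec + sens) / 2.0,
        n_negative=n_neg,
        n_positive=n_pos,
    )


@dataclass
class SplitResult:
    held_out: str
    prefilter_names: np.ndarray
    lambda_value: float
    selected_names: np.ndarray
    relaxed_coef: dict
    separation: bool
    probability: float


class StandardNestedCV(BaseEstimator):
    """Run the 2-stage nested CV as a fit-once evaluation estimator.

    Parameters mirror the run configuration; ``random_state`` seeds every
    stochastic stage (inner fold draws).  After ``fit``:

    ``records_`` : per-sample DataFrame (sample_id, true_label,
        point_probability, predicted_label)
    ``summary_`` : point ClassificationSummary
    ``lambda_average_`` : the shared averaged penalty
    ``splits_`` : list of SplitResult with per-split selections and fits
    """

    def __init__(
        self,
        inner_folds: int = 10,
        inner_repeats: int = 100,
        lambda_rule: str = "min",
        n_lambda: int = 100,
        lambda_min_ratio: float | None = None,
        lambda_average: str = "arithmetic",
        cv_threshold: float = 3.0,
        mwu_alpha_keep: float = 0.2,
        classification_threshold: float = 0.5,
        pos_label=None,
        random_state: int = 0,
        fixed_lambda: float | None = None,
        log_ratios: bool = True,
    ):
        self.inner_folds = inner_folds
        self.inner_repeats = inner_repeats
        self.lambda_rule = lambda_rule
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.lambda_average = lambda_average
        self.cv_threshold = cv_threshold
        self.mwu_alpha_keep = mwu_alpha_keep
        self.classification_threshold = classification_threshold
        self.pos_label = pos_label
        self.random_state = random_state
        self.fixed_lambda = fixed_lambda
        self.log_ratios = log_ratios

    # -- label handling ----------------------------------------------------
    def _encode(self, y):
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"exactly two classes required, got {classes!r}")
        if self.pos_label is not None:
            if self.pos_label not in classes:
                raise ValueError(f"pos_label {self.pos_label!r} not among {classes!r}")
            classes = np.array(
                [c for c in classes if c != self.pos_label] + [self.pos_label], dtype=classes.dtype
            )
        self.classes_ = classes
        return (y == classes[1]).astype(int)

    def _cv_config(self):
        return CVConfig(
            inner_folds=self.inner_folds,
            inner_repeats=self.inner_repeats,
            lambda_rule=self.lambda_rule,
            classification_threshold=self.classification_threshold,
            n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
            lambda_average=self.lambda_average,
        )

    def _model_space(self, values: np.ndarray) -> np.ndarray:
        """Matrix the penalized/relaxed models are fit on.

        Ratio features are quotients of log-normal abundances, so the
        models operate on the log2 scale by default; the CV and
        Mann-Whitney prefilters always see the raw ratios.
        """
        if not self.log_ratios:
            return values
        if (values <= 0).any():
            raise ValueError("log_ratios=True requires strictly positive features")
        return np.log2(values)

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            names = np.asarray(X.columns, dtype=object)
            sample_ids = np.asarray(X.index, dtype=object)
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            names = np.array([f"x{i}" for i in range(values.shape[1])], dtype=object)
            sample_ids = np.array([f"s{i}" for i in range(values.shape[0])], dtype=object)
        y01 = self._encode(y)
        n = len(y01)
        if n < 8 or (y01 == 0).sum() < 3 or (y01 == 1).sum() < 3:
            raise ValueError("need n >= 8 with at least 3 samples per class")
        self.feature_names_in_ = names
        self.sample_ids_ = sample_ids
        model_values = self._model_space(values)
        cfg = self._cv_config()
        rng = np.random.default_rng(self.random_state)
        split_seeds = rng.integers(2**31, size=n)

        # stage 1: per-training-set prefilter + lambda optimization
        masks, lambdas = [], []
        for i in range(n):
            tr = np.arange(n) != i
            keep = prefilter_mask(
                values[tr],
                y01[tr],
                cv_threshold=self.cv_threshold,
                mwu_alpha_keep=self.mwu_alpha_keep,
            )
            masks.append(keep)
            if not keep.any() or self.fixed_lambda is not None:
                lambdas.append(np.nan)
                continue
            res = optimize_lambda(model_values[tr][:, keep], y01[tr], cfg, seed=int(split_seeds[i]))
            lambdas.append(res.by_rule(self.lambda_rule))
        lam_arr = np.asarray(lambdas, dtype=float)
        if not any(m.any() for m in masks):
            raise ValueError("prefilter removed every ratio in every training set")
        if self.fixed_lambda is not None:
            # fixed shared penalty supplied by the caller: stage 1 tuning skipped
            lam_avg = float(self.fixed_lambda)
        else:
            valid = np.isfinite(lam_arr)
            if not valid.any():
                raise ValueError("no training set produced a lambda estimate")
            if self.lambda_average == "geometric":
                lam_avg = float(np.exp(np.log(lam_arr[valid]).mean()))
            else:
                lam_avg = float(lam_arr[valid].mean())
        self.lambda_average_ = lam_avg
        self.lambda_per_split_ = lam_arr
        logger.info("averaged lambda (%s rule): %.5g", self.lambda_rule, lam_avg)

        # stage 2: Lasso at the shared lambda, relaxed refit, held-out prediction
        splits = []
        probs = np.empty(n)
        for i in range(n):
            tr = np.arange(n) != i
            keep = masks[i]
            if not keep.any():
                logger.warning("split %s: empty prefilter survivor set; intercept-only model", sample_ids[i])
                relaxed = RelaxedLogistic().fit(np.empty((tr.sum(), 0)), y01[tr])
                sel_idx = np.array([], dtype=int)
            else:
                lasso = LassoLogistic(lam=lam_avg).fit(model_values[tr][:, keep], y01[tr])
                sel_local = lasso.selected_
                sel_idx = np.flatnonzero(keep)[sel_local]
                relaxed = RelaxedLogistic().fit(model_values[tr][:, sel_idx], y01[tr])
            p = float(relaxed.predict_proba(model_values[i : i + 1, sel_idx])[:, 1][0])
            probs[i] = p
            splits.append(
                SplitResult(
                    held_out=sample_ids[i],
                    prefilter_names=names[keep],
                    lambda_value=float(lam_arr[i]) if np.isfinite(lam_arr[i]) else np.nan,
                    selected_names=names[sel_idx],
                    relaxed_coef=dict(zip(names[sel_idx], np.atleast_1d(relaxed.coef_))),
                    separation=bool(relaxed.separation_),
                    probability=p,
                )
            )
        self.splits_ = splits
        t = self.classification_threshold
        self.records_ = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "true_label": y01,
                "point_probability": probs,
                "predicted_label": (probs >= t).astype(int),
            }
        )
        self.summary_ = summarize_classification(self.records_, t)
        self.per_split_selected_ = [s.selected_names for s in splits]
        return self

    @property
    def balanced_accuracy_(self) -> float:
        check_is_fitted(self, "summary_")
        return self.summary_.balanced_accuracy
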