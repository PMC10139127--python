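"""Feature- and sample-level quality control for CPM expression matrices.

Three screens are applied before any modeling:

* low-expression removal — features with average CPM < 5 across samples,
  or with a zero in any sample, are dropped (the zero rule also guarantees
  that ratio construction is well defined);
* global outlier samples — each feature is rescaled to mean 1, each
  sample's score is its mean rescaled value, and samples whose score falls
  outside mean ± 3 SD of the scores are flagged;
* molecular haemolysis — red-blood-cell-enriched markers (miR-451a,
  miR-16-5p, miR-486-5p) are rescaled to mean 1 and a sample is flagged
  as haemolysed when its mean marker level exceeds the cohort mean by more
  than 2 SD (one-sided: haemolysis only elevates these markers).

"Centered to a mean of one" is implemented as division by the feature
mean (multiplicative rescaling), which makes both sample screens invariant
to rescaling the whole matrix by a positive constant.  All SDs use the
sample convention (ddof=1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_HAEMOLYSIS_MARKERS = ("hsa-miR-451a", "hsa-miR-16-5p", "hsa-miR-486-5p")


@dataclass
class QCParams:
    """Thresholds for the three QC screens (units: CPM and SD multiples)."""

    min_avg_cpm: float = 5.0
    require_nonzero_in_all_samples: bool = True
    outlier_sd_multiplier: float = 3.0
    haemolysis_sd_multiplier: float = 2.0
    haemolysis_marker_ids: tuple[str, ...] = DEFAULT_HAEMOLYSIS_MARKERS

    def __post_init__(self):
        if self.min_avg_cpm < 0:
            raise ValueError("min_avg_cpm must be >= 0")
        if self.outlier_sd_multiplier <= 0 or self.haemolysis_sd_multiplier <= 0:
            raise ValueError("SD multipliers must be > 0")
        if not self.haemolysis_marker_ids:
            raise ValueError("haemolysis marker list must be non-empty")


@dataclass
class QCReport:
    removed_features: list[tuple[str, str]] = field(default_factory=list)
    flagged_samples: list[tuple[str, str]] = field(default_factory=list)
    sample_scores: dict[str, float] = field(default_factory=dict)

    @property
    def flagged_sample_ids(self) -> list[str]:
        return [s for s, _ in self.flagged_samples]

    @property
    def removed_feature_ids(self) -> list[str]:
        return [f for f, _ in self.removed_features]


def filter_low_expression(matrix: pd.DataFrame, params: QCParams | None = None):
    """Drop low-abundance features; returns (filtered matrix, QCReport).

    A feature is removed when its mean CPM over samples is strictly below
    ``min_avg_cpm`` (a mean of exactly the threshold is retained), or —
    when ``require_nonzero_in_all_samples`` — it has a zero count in any
    sample.
    """
    params = params or QCParams()
    if matrix.size == 0:
        raise ValueError("empty expression matrix")
    values = matrix.to_numpy(dtype=float)
    mean_cpm = values.mean(axis=0)
    low = mean_cpm < params.min_avg_cpm
    has_zero = (values <= 0).any(axis=0) if params.require_nonzero_in_all_samples else np.zeros(values.shape[1], bool)
    report = QCReport()
    for j, fid in enumerate(matrix.columns):
        if low[j]:
            report.removed_features.append((fid, f"mean CPM {mean_cpm[j]:.4g} < {params.min_avg_cpm:g}"))
        elif has_zero[j]:
            report.removed_features.append((fid, "zero count in at least one sample"))
    keep = ~(low | has_zero)
    if not keep.any():
        raise ValueError("low-expression filter removed every feature")
    return matrix.loc[:, keep], report


def _mean_one_scores(values: np.ndarray) -> np.ndarray:
    means = values.mean(axis=0)
    if np.any(means == 0):
        raise ValueError(
            "feature with mean zero; run filter_low_expression before sample QC"
        )
    return (values / means).mean(axis=1)


def detect_outlier_samples(matrix: pd.DataFrame, params: QCParams | None = None) -> QCReport:
    """Flag samples whose mean-one-rescaled profile is outside mean ± k·SD."""
    params = params or QCParams()
    if matrix.shape[0] < 3:
        raise ValueError("outlier detection needs at least 3 samples")
    scores = _mean_one_scores(matrix.to_numpy(dtype=float))
    center = scores.mean()
    sd = scores.std(ddof=1)
    lo = center - params.outlier_sd_multiplier * sd
    hi = center + params.outlier_sd_multiplier * sd
    report = QCReport(sample_scores=dict(zip(matrix.index, scores)))
    for sid, sc in zip(matrix.index, scores):
        if sc > hi:
            report.flagged_samples.append((sid, "outlier-high"))
        elif sc < lo:
            report.flagged_samples.append((sid, "outlier-low"))
    return report


def detect_haemolysis(matrix: pd.DataFrame, params: QCParams | None = None) -> QCReport:
    """Flag haemolysed samples from red-blood-cell marker elevation.

    Markers configured but absent from the matrix are skipped with a
    warning; if none are present this is a hard error.
    """
    params = params or QCParams()
    present = [m for m in params.haemolysis_marker_ids if m in matrix.columns]
    missing = [m for m in params.haemolysis_marker_ids if m not in matrix.columns]
    if not present:
        raise ValueError(
            f"no haemolysis marker found: configured {list(params.haemolysis_marker_ids)}, "
            f"available features include {list(matrix.columns[:5])}..."
        )
    if missing:
        logger.warning("haemolysis markers missing from matrix, skipped: %s", missing)
    scores = _mean_one_scores(matrix[present].to_numpy(dtype=float))
    center = scores.mean()
    sd = scores.std(ddof=1)
    threshold = center + params.haemolysis_sd_multiplier * sd
    report = QCReport(sample_scores=dict(zip(matrix.index, scores)))
    for sid, sc in zip(matrix.index, scores):
        if sc > threshold:
            report.flagged_samples.append((sid, "haemolysed"))
    return report


def apply_qc(matrix: pd.DataFrame, params: QCParams | None = None, keep_flagged: bool = False):
    """Full QC pass: low-expression filter, then outlier and haemolysis flags.

    Flagged samples are excluded from the returned matrix (all downstream
    stages) unless ``keep_flagged`` is set.  Returns
    (matrix, feature_report, outlier_report, haemolysis_report).
    """
    params = params or QCParams()
    filtered, feat_report = filter_low_expression(matrix, params)
    outlier_report = detect_outlier_samples(filtered, params)
    try:
        haemo_report = detect_haemolysis(filtered, params)
    except ValueError:
        logger.warning("haemolysis screen skipped: no configured marker present")
        haemo_report = QCReport()
    flagged = set(outlier_report.flagged_sample_ids) | set(haemo_report.flagged_sample_ids)
    if flagged and not keep_flagged:
        filtered = filtered.loc[[s for s in filtered.index if s not in flagged]]
    elif flagged:
        logger.warning("flagged samples retained by request: %s", sorted(flagged))
    return filtered, feat_report, outlier_report, haemo_report
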