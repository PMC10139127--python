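"""Seeded synthetic CPM cohorts with planted ratio signal.

The generator emulates the statistical structure the pipeline assumes:
strictly positive log-normal CPM profiles, a small number of feature pairs
whose ratio separates the two groups, optional haemolysis-marker spiking
and optional global outlier samples.  It makes every pipeline stage and
every statistical property testable without any external dataset.

The model: each feature f receives a baseline log-mean drawn once from
N(base_log_mean, base_log_sd^2); each sample's CPM for f is
exp(N(mean_f, noise_log_sd^2)).  For an informative pair (i, j), both
members additionally share a per-sample latent log-factor (SD
``pair_latent_sd``) that cancels in their ratio — mimicking the shared
biological/technical variation that motivates ratio features — and
feature i's log-mean is shifted by log(2) * log2_fc in group B, so the
pair's ratio carries a planted log2 fold-change of log2_fc with much less
noise than any ratio pairing i or j with an unrelated feature.  Haemolysis
spiking multiplies the configured marker features by the spike factor in
the chosen samples; an outlier factor multiplies a sample's entire profile.

Defaults put typical features around 50-60 CPM with a between-feature
log-SD of 1.5 and a within-feature biological noise log-SD of 0.55 —
right-skewed abundance spanning a few orders of magnitude, as in
TMM-normalized small-RNA data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qc import DEFAULT_HAEMOLYSIS_MARKERS

__all__ = ["SimulationDesign", "generate_cohort", "generate_worked_fixture", "unstable_design"]


@dataclass
class SimulationDesign:
    """Full description of one synthetic two-group cohort.

    ``informative_pairs`` is a list of ``(numerator_index, denominator_index,
    log2_fc)`` triples: the numerator feature's log-mean is shifted by
    ``log2_fc * log(2)`` in group B.  ``haemolysis`` is ``(sample_indices,
    spike_factor, marker_indices)``; marker features are renamed to the
    canonical red-blood-cell marker IDs so the QC screen can find them.
    ``outliers`` is ``(sample_indices, global_factor)``.
    """

    n_per_group: tuple[int, int] = (20, 20)
    n_features: int = 30
    informative_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    base_log_mean: float = 4.0
    base_log_sd: float = 1.5
    noise_log_sd: float = 0.55
    pair_latent_sd: float = 1.5
    haemolysis: tuple[list[int], float, list[int]] | None = None
    outliers: tuple[list[int], float] | None = None
    group_labels: tuple[str, str] = ("A", "B")
    seed: int = 0

    def __post_init__(self):
        n_total = sum(self.n_per_group)
        for i, j, fc in self.informative_pairs:
            if not (0 <= i < self.n_features and 0 <= j < self.n_features) or i == j:
                raise ValueError(f"informative pair ({i},{j}) out of range or degenerate")
            if not np.isfinite(fc):
                raise ValueError("fold-changes must be finite")
        if self.haemolysis is not None:
            idx, factor, markers = self.haemolysis
            if factor <= 0:
                raise ValueError("spike factor must be > 0")
            if any(not 0 <= s < n_total for s in idx) or any(
                not 0 <= m < self.n_features for m in markers
            ):
                raise ValueError("haemolysis indices out of range")
            informative = {k for i, j, _ in self.informative_pairs for k in (i, j)}
            if informative & set(markers):
                raise ValueError("haemolysis markers conflict with informative features")
        if self.outliers is not None:
            idx, factor = self.outliers
            if factor <= 0:
                raise ValueError("outlier factor must be > 0")
            if any(not 0 <= s < n_total for s in idx):
                raise ValueError("outlier sample indices out of range")


def generate_cohort(design: SimulationDesign):
    """Draw one cohort; returns (expression DataFrame, metadata DataFrame, truth dict).

    The truth record lists the planted informative ratio IDs (oriented with
    the lower feature index as numerator, matching ratio-matrix column IDs)
    and the spiked/outlier sample IDs, so tests can score recovery without
    inspecting pipeline internals.
    """
    rng = np.random.default_rng(design.seed)
    n_a, n_b = design.n_per_group
    n = n_a + n_b
    p = design.n_features
    feature_ids = [f"mir-{k:03d}" for k in range(p)]
    marker_map = {}
    if design.haemolysis is not None:
        _, _, marker_idx = design.haemolysis
        for m, name in zip(marker_idx, DEFAULT_HAEMOLYSIS_MARKERS):
            feature_ids[m] = name
            marker_map[name] = m
    sample_ids = [f"S{k:03d}" for k in range(n)]
    groups = np.array([design.group_labels[0]] * n_a + [design.group_labels[1]] * n_b)

    mean_f = rng.normal(design.base_log_mean, design.base_log_sd, size=p)
    log_cpm = rng.normal(0.0, design.noise_log_sd, size=(n, p)) + mean_f
    in_b = groups == design.group_labels[1]
    for i, j, fc in design.informative_pairs:
        # shared per-sample latent factor: both members move together, so
        # the pair's ratio is far less noisy than either feature alone --
        # the property that makes ratio features worth modeling
        u = rng.normal(0.0, design.pair_latent_sd, size=n)
        log_cpm[:, i] += u
        log_cpm[:, j] += u
        log_cpm[in_b, i] += fc * np.log(2.0)
    cpm = np.exp(log_cpm)

    if design.haemolysis is not None:
        spiked, factor, marker_idx = design.haemolysis
        for s in spiked:
            cpm[s, marker_idx] *= factor
    if design.outliers is not None:
        out_idx, factor = design.outliers
        for s in out_idx:
            cpm[s, :] *= factor

    expr = pd.DataFrame(cpm, index=sample_ids, columns=feature_ids)
    meta = pd.DataFrame({"sample_id": sample_ids, "group": groups}).set_index("sample_id")
    truth = {
        "informative_ratios": [
            f"{feature_ids[min(i, j)]}/{feature_ids[max(i, j)]}"
            for i, j, _ in design.informative_pairs
        ],
        "informative_pairs": [(i, j, fc) for i, j, fc in design.informative_pairs],
        "haemolysed_samples": [sample_ids[s] for s in design.haemolysis[0]]
        if design.haemolysis
        else [],
        "outlier_samples": [sample_ids[s] for s in design.outliers[0]]
        if design.outliers
        else [],
    }
    return expr, meta, truth


def generate_worked_fixture():
    """The small fixed cohort used throughout the docs and regression tests.

    n = 12 + 12 samples, 15 features, two planted informative ratios
    (log2 fold-changes 2.0 and 1.6), fixed seed.  Regenerating it always
    yields the identical matrix.
    """
    design = SimulationDesign(
        n_per_group=(12, 12),
        n_features=15,
        informative_pairs=[(0, 1, 2.0), (2, 3, 1.6)],
        seed=20230411,
    )
    return generate_cohort(design)


def unstable_design(seed: int = 0) -> SimulationDesign:
    """A deliberately unstable scenario: small cohort, weak planted signal.

    n = 8 + 8 samples and 11 features (55 candidate ratios) with one weak
    informative pair (log2 FC 0.9 against the default noise level).  Model
    selection on cohorts like this flips between training sets, which is
    the regime the conservative variance estimator is designed for.
    """
    return SimulationDesign(
        n_per_group=(8, 8),
        n_features=11,
        informative_pairs=[(0, 1, 0.9)],
        seed=seed,
    )
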