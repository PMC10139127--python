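"""Run configuration: every tunable threshold of the pipeline in one place.

Defaults reproduce the published protocol: LOOCV outer loop, 100x repeated
10-fold inner cross-validation for the Lasso penalty, lambda.min rule, a
0.5 classification cut-point, CV > 300% and Mann-Whitney p > 0.2 ratio
prefilters, >= 50% selection frequency, 2000 bootstrap resamples and
1000 Monte-Carlo n-2 jackknife iterations at a 95% confidence level.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .qc import QCParams


@dataclass
class PrefilterParams:
    cv_threshold: float = 3.0
    mwu_alpha_keep: float = 0.2

    def __post_init__(self):
        if self.cv_threshold <= 0:
            raise ValueError("cv_threshold must be > 0")
        if not 0 < self.mwu_alpha_keep < 1:
            raise ValueError("mwu_alpha_keep must be in (0, 1)")


@dataclass
class CVConfig:
    inner_folds: int = 10
    inner_repeats: int = 100
    lambda_rule: str = "min"  # "min" or "one_se"
    classification_threshold: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float | None = None
    lambda_average: str = "arithmetic"  # or "geometric"
    inner_loss: str = "deviance"  # or "misclassification"

    def __post_init__(self):
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")
        if self.inner_repeats < 1:
            raise ValueError("inner_repeats must be >= 1")
        if not 0 < self.classification_threshold < 1:
            raise ValueError("classification_threshold must be in (0, 1)")
        if self.lambda_rule not in ("min", "one_se"):
            raise ValueError("lambda_rule must be 'min' or 'one_se'")


@dataclass
class StabilityConfig:
    frequency_threshold: float = 0.5
    max_model_size: int = 10
    size_selection_mode: str = "point"  # or "conservative"

    def __post_init__(self):
        if not 0 < self.frequency_threshold <= 1:
            raise ValueError("frequency_threshold must be in (0, 1]")
        if self.max_model_size < 1:
            raise ValueError("max_model_size must be >= 1")
        if self.size_selection_mode not in ("point", "conservative"):
            raise ValueError("size_selection_mode must be 'point' or 'conservative'")


@dataclass
class UncertaintyConfig:
    bootstrap_B: int = 2000
    jackknife_iterations: int = 1000
    ci_level: float = 0.95
    threshold: float = 0.5
    refit_scope: str = "final_model"  # or "selection_and_fit"
    exhaustive_max_n: int = 60

    def __post_init__(self):
        if self.bootstrap_B < 100:
            raise ValueError("bootstrap_B must be >= 100")
        if self.jackknife_iterations < 100:
            raise ValueError("jackknife_iterations must be >= 100")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.refit_scope not in ("final_model", "selection_and_fit"):
            raise ValueError("refit_scope must be 'final_model' or 'selection_and_fit'")


@dataclass
class RunConfig:
    qc: QCParams = field(default_factory=QCParams)
    prefilter: PrefilterParams = field(default_factory=PrefilterParams)
    cv: CVConfig = field(default_factory=CVConfig)
    stability: StabilityConfig = field(default_factory=StabilityConfig)
    uncertainty: UncertaintyConfig = field(default_factory=UncertaintyConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["qc"]["haemolysis_marker_ids"] = list(d["qc"]["haemolysis_marker_ids"])
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        qc = d.get("qc", {})
        if "haemolysis_marker_ids" in qc:
            qc = dict(qc, haemolysis_marker_ids=tuple(qc["haemolysis_marker_ids"]))
        return cls(
            qc=QCParams(**qc),
            prefilter=PrefilterParams(**d.get("prefilter", {})),
            cv=CVConfig(**d.get("cv", {})),
            stability=StabilityConfig(**d.get("stability", {})),
            uncertainty=UncertaintyConfig(**d.get("uncertainty", {})),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text) or {})
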