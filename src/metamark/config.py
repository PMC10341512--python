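"""Run configuration shared by every pipeline stage.

All thresholds used by the screening rules live in one dataclass so a run
can be reproduced from a single small YAML-style file plus a seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Thresholds, cross-validation layout and seed for one analysis run.

    Parameters
    ----------
    alpha : significance level for adjusted p-values (default 0.05).
    fc_threshold : fold-change cutoff, applied symmetrically: a metabolite
        passes when FC >= fc_threshold or FC <= 1/fc_threshold (default 1.5).
    auc_threshold : oriented-AUC cutoff for marker retention (default 0.9).
    r_threshold : absolute Pearson-r cutoff for phenotype association
        (default 0.4).
    plsda_components : number of PLS components to extract (default 5).
    svm_repeats, svm_outer_folds, svm_inner_folds : repeated nested
        cross-validation layout (defaults 10 / 3 / 3).
    svm_cost : soft-margin penalty C of the linear SVM (default 1.0).
    max_feature_fraction : forward selection stops once the path reaches
        this fraction of all features (default 0.5).
    n_bootstrap : replicates for the ROC AUC percentile bootstrap (500).
    seed : master seed; every stochastic stage derives its stream from it.
    """

    alpha: float = 0.05
    fc_threshold: float = 1.5
    auc_threshold: float = 0.9
    r_threshold: float = 0.4
    plsda_components: int = 5
    svm_repeats: int = 10
    svm_outer_folds: int = 3
    svm_inner_folds: int = 3
    svm_cost: float = 1.0
    max_feature_fraction: float = 0.5
    n_bootstrap: int = 500
    seed: int = 0
    ttest_equal_var: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("alpha", "fc_threshold", "auc_threshold", "r_threshold",
                     "svm_cost", "max_feature_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must exceed 1")
        if self.svm_outer_folds < 2 or self.svm_inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if not (0 < self.max_feature_fraction <= 1):
            raise ValueError("max_feature_fraction must lie in (0, 1]")
        for name in ("plsda_components", "svm_repeats", "n_bootstrap"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        """Load key: value pairs from a YAML file; kwargs win over the file."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain key: value pairs")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Stable short hash of the configuration, logged with every stage."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
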