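"""Run configuration: one nested, serializable object for the whole pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

from .model import DEFAULT_DEPTH_GRID
from .preprocess import SNR_THRESHOLD_DB
from .synthetic import CohortSpec


@dataclass
class PreprocessConfig:
    snr_threshold_db: float = SNR_THRESHOLD_DB


@dataclass
class FeatureConfig:
    cci_divisor: str = "count"  # "count" = mean over samples; "span" = sum/(t2-t1)


@dataclass
class ModelSection:
    k_features: int = 15
    test_fraction: float = 0.20
    cv_folds: int = 5
    depth_grid: list[int] = field(default_factory=lambda: list(DEFAULT_DEPTH_GRID))
    n_trees: int = 500
    targets: list[str] = field(
        default_factory=lambda: ["womac_total", "pain", "stiffness", "function", "vas"]
    )
    family: str = "rforest"
    group_by_subject: bool = True
    include_temporospatial: bool = False


@dataclass
class ShapConfig:
    background_size: int = 25
    enumeration_bound: int = 15
    n_explain: int = 30


@dataclass
class RunConfig:
    seed: int = 0
    synthetic: dict = field(default_factory=dict)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    model: ModelSection = field(default_factory=ModelSection)
    shap: ShapConfig = field(default_factory=ShapConfig)

    def cohort_spec(self) -> CohortSpec:
        kwargs = dict(self.synthetic)
        kwargs.setdefault("n_subjects", 75)
        kwargs.setdefault("seed", self.seed)
        return CohortSpec(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        for name, sub in (
            ("preprocess", PreprocessConfig),
            ("features", FeatureConfig),
            ("model", ModelSection),
            ("shap", ShapConfig),
        ):
            if name in kwargs and isinstance(kwargs[name], dict):
                valid = {f.name for f in fields(sub)}
                unknown = set(kwargs[name]) - valid
                if unknown:
                    raise ValueError(f"unknown {name} config key(s): {sorted(unknown)}")
                kwargs[name] = sub(**kwargs[name])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def fingerprint(self) -> str:
        """Stable hash of the semantic configuration."""
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
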