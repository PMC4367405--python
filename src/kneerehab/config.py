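"""Pipeline configuration: one auditable object covering every stage.

Defaults follow the study conventions throughout: 40 Hz sampling, 3-sample
median filter, 0.5 Hz gravity low-pass, X = 10 % robust-range tails, and the
clinical error tolerances of the posture rules.  The config round-trips
through YAML without loss; unknown keys are rejected so silent typos cannot
change clinically meaningful thresholds.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .kinematics import KinematicsParams
from .preprocess import FilterConfig
from .rules import ThresholdConfig
from .features import FeatureParams
from .segmentation import SegmentationParams


@dataclasses.dataclass
class ClassifierParams:
    """knn_k: baseline neighbor count; pruning_cv_folds: internal CV folds
    used to choose the tree's pruning strength; seed: CV shuffling seed."""

    knn_k: int = 5
    pruning_cv_folds: int = 10
    seed: int = 0


@dataclasses.dataclass
class PipelineConfig:
    """All tunables of the assessment pipeline, by stage."""

    rate_hz: float = 40.0
    filters: FilterConfig = dataclasses.field(default_factory=FilterConfig)
    segmentation: SegmentationParams = dataclasses.field(default_factory=SegmentationParams)
    kinematics: KinematicsParams = dataclasses.field(default_factory=KinematicsParams)
    features: FeatureParams = dataclasses.field(default_factory=FeatureParams)
    thresholds: ThresholdConfig = dataclasses.field(default_factory=ThresholdConfig)
    classifier: ClassifierParams = dataclasses.field(default_factory=ClassifierParams)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        kwargs: dict = {}
        sections = {
            "filters": FilterConfig,
            "segmentation": SegmentationParams,
            "kinematics": KinematicsParams,
            "features": FeatureParams,
            "thresholds": ThresholdConfig,
            "classifier": ClassifierParams,
        }
        if "rate_hz" in data:
            kwargs["rate_hz"] = float(data.pop("rate_hz"))
        for name, klass in sections.items():
            if name in data:
                section = data.pop(name) or {}
                known = {f.name for f in dataclasses.fields(klass)}
                unknown = set(section) - known
                if unknown:
                    raise ValueError(
                        f"unknown key(s) in config section '{name}': {sorted(unknown)}"
                    )
                kwargs[name] = klass(**section)
        if data:
            raise ValueError(f"unknown config key(s): {sorted(data)}")
        return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline config; missing sections keep their defaults."""
    data = yaml.safe_load(Path(path).read_text())
    return PipelineConfig.from_dict(data or {})


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    """Write the full config (defaults included) as YAML."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
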