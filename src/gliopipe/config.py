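"""Single-file pipeline configuration (YAML) covering every stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from ._nn import LRNConfig
from .crnn import NetworkSpec, TrainConfig


@dataclass(frozen=True)
class PreprocessingConfig:
    window_size: int = 3
    sharpen_amount: float = 1.0


@dataclass(frozen=True)
class SegmentationConfig:
    clusters: int = 3
    fuzziness: float = 2.0
    eps: float = 1e-5
    max_iter: int = 100
    min_area_fraction: float = 0.001


@dataclass(frozen=True)
class FeatureConfig:
    levels: int = 32
    distance: int = 1
    angles: tuple[int, ...] = (0, 45, 90, 135)
    masked: bool = False


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters plus split fraction and global seed; round-trips
    losslessly through YAML."""

    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    network: NetworkSpec = field(default_factory=NetworkSpec.compact)
    training: TrainConfig = field(default_factory=TrainConfig)
    train_fraction: float = 0.8
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["features"]["angles"] = list(d["features"]["angles"])
        d["network"]["pool_after"] = list(d["network"]["pool_after"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        feat = dict(d.get("features", {}))
        if "angles" in feat:
            feat["angles"] = tuple(feat["angles"])
        net = dict(d.get("network", {}))
        if "pool_after" in net:
            net["pool_after"] = tuple(net["pool_after"])
        if "lrn" in net:
            net["lrn"] = LRNConfig(**net["lrn"])
        return cls(
            preprocessing=PreprocessingConfig(**d.get("preprocessing", {})),
            segmentation=SegmentationConfig(**d.get("segmentation", {})),
            features=FeatureConfig(**feat),
            network=NetworkSpec(**net),
            training=TrainConfig(**d.get("training", {})),
            train_fraction=d.get("train_fraction", 0.8),
            seed=d.get("seed", 0),
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
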