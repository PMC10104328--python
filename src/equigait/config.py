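"""Structured run configuration with YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .feature_table import MIN_STRIDES, VARIABILITY_METRICS
from .selection import CLASSIFIERS
from .synthetic import HIGH_INTENSITY_FRACTION, SPEED_ROM_FRACTION, FatigueEffectConfig
from .types import GAITS


@dataclass
class SimulatorConfig:
    n_horses: int = 20
    strides_per_trial: int = 33
    effects: dict = field(default_factory=lambda: dict(FatigueEffectConfig.study_default().effects))
    noise_sd_accel: float = 0.02
    noise_sd_gyro: float = 2.0
    inter_horse_cv: float = 0.08
    stride_cv: float = 0.04
    high_intensity_fraction: float = HIGH_INTENSITY_FRACTION
    gaits: tuple = GAITS

    def effect_config(self) -> FatigueEffectConfig:
        return FatigueEffectConfig(
            effects=dict(self.effects),
            noise_sd_accel=self.noise_sd_accel,
            noise_sd_gyro=self.noise_sd_gyro,
            inter_horse_cv=self.inter_horse_cv,
            stride_cv=self.stride_cv,
        )


@dataclass
class PreprocessingConfig:
    filter_order: int = 4
    cutoff_hz: float = 30.0
    theta: float = 0.15
    smooth_s: float = 0.05
    robust_window_strides: float = 2.0
    mad_threshold: float = 3.0


@dataclass
class FeatureConfig:
    rom_fraction: float = SPEED_ROM_FRACTION
    stride_length_offset: float = 0.0


@dataclass
class AggregationConfig:
    metrics: tuple = VARIABILITY_METRICS
    min_strides: int = MIN_STRIDES
    sliding_window: int | None = None


@dataclass
class SelectionConfig:
    lam: float | None = None   # None -> 1/n
    max_iter: int = 200
    max_features: int | None = None
    force_include: bool = False


@dataclass
class ClassifierConfig:
    menu: tuple = CLASSIFIERS
    hyperparams: dict = field(default_factory=dict)


@dataclass
class DatasetConfig:
    la_cutoff: float = 4.0


@dataclass
class PipelineConfig:
    seed: int = 0
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    aggregation: AggregationConfig = field(default_factory=AggregationConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    classifiers: ClassifierConfig = field(default_factory=ClassifierConfig)
    datasets: DatasetConfig = field(default_factory=DatasetConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs: dict = {}
        sections = {f.name: f.type for f in fields(cls)}
        for name, value in (data or {}).items():
            if name not in sections:
                raise ValueError(f"unknown config section {name!r}")
            if name == "seed":
                kwargs["seed"] = int(value)
                continue
            section_cls = {
                "simulator": SimulatorConfig, "preprocessing": PreprocessingConfig,
                "features": FeatureConfig, "aggregation": AggregationConfig,
                "selection": SelectionConfig, "classifiers": ClassifierConfig,
                "datasets": DatasetConfig,
            }[name]
            valid = {f.name for f in fields(section_cls)}
            unknown = set(value) - valid
            if unknown:
                raise ValueError(f"unknown keys in {name!r}: {sorted(unknown)}")
            kwargs[name] = section_cls(**value)
        cfg = cls(**kwargs)
        cfg.simulator.gaits = tuple(cfg.simulator.gaits)
        cfg.aggregation.metrics = tuple(cfg.aggregation.metrics)
        cfg.classifiers.menu = tuple(cfg.classifiers.menu)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for key in ("gaits",):
            data["simulator"][key] = list(data["simulator"][key])
        data["aggregation"]["metrics"] = list(data["aggregation"]["metrics"])
        data["classifiers"]["menu"] = list(data["classifiers"]["menu"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
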