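"""Pipeline configuration: a nested YAML schema with strict key validation.

Unknown keys anywhere in the document are rejected before any stage runs.
All stage randomness derives from the single global ``seed``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ..errors import InvalidConfigError
from ..synth_data import SynthConfig
from ..train_eval.training import RobustnessConfig, TrainConfig

__all__ = ["PipelineConfig", "FeatureConfig", "SelectionConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class FeatureConfig:
    frame_length: int = 2048
    hop: int = 512
    denoise: bool = False
    segment_seconds: float = 0.0  # 0 = keep whole clips


@dataclass(frozen=True)
class SelectionConfig:
    k: int = 21


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    out_dir: str = "runs"
    synth: SynthConfig = field(default_factory=SynthConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    robustness: RobustnessConfig = field(default_factory=RobustnessConfig)


_BLOCKS = {
    "synth": SynthConfig,
    "features": FeatureConfig,
    "selection": SelectionConfig,
    "training": TrainConfig,
    "robustness": RobustnessConfig,
}


def _build(cls, payload: dict, where: str):
    if not isinstance(payload, dict):
        raise InvalidConfigError(f"config block {where!r} must be a mapping")
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(payload) - allowed)
    if unknown:
        raise InvalidConfigError(f"unknown config key {where}.{unknown[0]}")
    try:
        return cls(**payload)
    except TypeError as exc:
        raise InvalidConfigError(f"invalid config block {where!r}: {exc}") from exc


def load_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a pipeline YAML file."""
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh) or {}
    if not isinstance(payload, dict):
        raise InvalidConfigError(f"config {path} must be a YAML mapping")
    allowed = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(payload) - allowed)
    if unknown:
        raise InvalidConfigError(f"unknown config key {unknown[0]}")
    kwargs: dict = {}
    for key, value in payload.items():
        if key in _BLOCKS:
            kwargs[key] = _build(_BLOCKS[key], value, key)
        else:
            kwargs[key] = value
    config = PipelineConfig(**kwargs)
    # a single global seed flows to every stage unless a block overrides it
    if "synth" not in payload or "seed" not in payload.get("synth", {}):
        config = dataclasses.replace(
            config, synth=dataclasses.replace(config.synth, seed=config.seed)
        )
    if "training" not in payload or "seed" not in payload.get("training", {}):
        config = dataclasses.replace(
            config, training=dataclasses.replace(config.training, seed=config.seed)
        )
    if "robustness" not in payload or "seed" not in payload.get("robustness", {}):
        config = dataclasses.replace(
            config, robustness=dataclasses.replace(config.robustness, seed=config.seed)
        )
    return config


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
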