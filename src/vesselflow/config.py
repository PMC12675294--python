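"""Run configuration: strict, nested, YAML round-trippable."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .attachment import SinkhornConfig
from .network import NetConfig
from .trainer import TrainConfig

__all__ = ["PreprocessConfig", "GenerationConfig", "RunConfig", "load_config", "save_config"]


@dataclass
class PreprocessConfig:
    margin: float = 0.05
    cpd: bool = True
    cpd_max_iter: int = 100
    cpd_outlier_weight: float = 0.1


@dataclass
class GenerationConfig:
    n_samples: int = 10
    interpolation_mode: str = "slerp"
    snr_fractions: tuple = (0.01, 0.02, 0.05, 0.1)


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/default"
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    net: NetConfig = field(default_factory=NetConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    generation: GenerationConfig = field(default_factory=GenerationConfig)


_SECTIONS = {
    "preprocessing": PreprocessConfig,
    "net": NetConfig,
    "training": TrainConfig,
    "generation": GenerationConfig,
}


def _build(cls, data: dict, path: str):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config key(s) at {path}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if cls is TrainConfig and key == "sinkhorn" and isinstance(value, dict):
            value = _build(SinkhornConfig, value, f"{path}.{key}")
        if key == "snr_fractions" and isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping: {path}")
    top = {k: v for k, v in data.items() if k not in _SECTIONS}
    unknown = set(top) - {"seed", "out_dir"}
    if unknown:
        raise ValueError(f"unknown config key(s) at top level: {sorted(unknown)}")
    cfg = RunConfig(**top)
    for name, cls in _SECTIONS.items():
        if name in data:
            setattr(cfg, name, _build(cls, data[name] or {}, name))
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    data = asdict(cfg)
    data["generation"]["snr_fractions"] = list(cfg.generation.snr_fractions)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
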