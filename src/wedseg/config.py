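"""Run configuration: one YAML file with nested per-stage sections.

Unknown keys are rejected so typos fail loudly instead of silently falling
back to defaults.  Every field has a default, so an empty file is a valid
(if small) run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .augment import AugmentationPolicy
from .synthetic import SyntheticConfig
from .train import TrainConfig
from .watershed import WatershedConfig

__all__ = ["RunConfig", "EvaluationConfig", "ModelConfig", "load_run_config"]


def _build(cls, section: dict, name: str):
    if section is None:
        section = {}
    if not isinstance(section, dict):
        raise ValueError(f"section {name!r} must be a mapping")
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown keys in section {name!r}: {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v
        for k, v in section.items()
    }
    return cls(**coerced)


@dataclass(frozen=True)
class ModelConfig:
    """Estimator-facing architecture knobs (bottleneck width is derived)."""

    base_width: int = 8
    depth: int = 4
    num_classes: int = 3
    dropout_rates: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4)
    use_batch_norm: bool = False


@dataclass(frozen=True)
class EvaluationConfig:
    threshold: float = 0.35

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must be in (0,1), got {self.threshold}")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    n_source_pairs: int = 32
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    augmentation: AugmentationPolicy = field(default_factory=AugmentationPolicy)
    watershed: WatershedConfig = field(default_factory=WatershedConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)


_SECTIONS = {
    "synthetic": SyntheticConfig,
    "augmentation": AugmentationPolicy,
    "watershed": WatershedConfig,
    "model": ModelConfig,
    "training": TrainConfig,
    "evaluation": EvaluationConfig,
}


def load_run_config(path: str | Path | None = None,
                    overrides: dict | None = None) -> RunConfig:
    """Parse a YAML run configuration, applying flat top-level overrides."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("run config must be a YAML mapping")
    if overrides:
        raw.update(overrides)
    top_allowed = {"seed", "n_source_pairs", *_SECTIONS}
    unknown = set(raw) - top_allowed
    if unknown:
        raise ValueError(f"unknown top-level keys: {sorted(unknown)}")
    kwargs: dict = {}
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "n_source_pairs" in raw:
        kwargs["n_source_pairs"] = int(raw["n_source_pairs"])
    for name, cls in _SECTIONS.items():
        kwargs[name] = _build(cls, raw.get(name), name)
    return RunConfig(**kwargs)
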