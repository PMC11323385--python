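"""YAML configuration: schema, strict validation, defaults and round-trip.

Unknown keys are rejected rather than ignored so that a typo in a liability
vocabulary or a reward parameter surfaces immediately.  Every block has
documented defaults; a minimal config file can be empty.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .model import ClassifierSpec
from .persona import Persona
from .reward import RewardConfig, SizeWindow


class ConfigError(ValueError):
    """Configuration file is malformed, has unknown keys or invalid values."""


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SizeWindowBlock(_StrictModel):
    low: float = 10.0
    high: float = 60.0
    low_slope: float = Field(default=1.0, gt=0)
    high_slope: float = Field(default=1.0, gt=0)
    alpha: float = Field(default=0.25, gt=0, le=1)

    @field_validator("high")
    @classmethod
    def _ordered(cls, v, info):
        if "low" in info.data and v <= info.data["low"]:
            raise ValueError("size window requires low < high")
        return v

    def to_window(self) -> SizeWindow:
        return SizeWindow(
            low_center=self.low,
            high_center=self.high,
            low_slope=self.low_slope,
            high_slope=self.high_slope,
            alpha=self.alpha,
        )


class RewardBlock(_StrictModel):
    similarity_cutoff: float = Field(default=0.5, ge=0, lt=1)
    sort_of_weight: float = 0.5
    prefactor: float = 1.0 / 6.0
    count_cap: int = Field(default=1, ge=1)
    size_window: SizeWindowBlock = SizeWindowBlock()

    def to_reward_config(self) -> RewardConfig:
        return RewardConfig(
            similarity_cutoff=self.similarity_cutoff,
            sort_of_weight=self.sort_of_weight,
            prefactor=self.prefactor,
            count_cap=self.count_cap,
        )


class ModelBlock(_StrictModel):
    use_model: bool = True
    n_estimators: int = Field(default=100, ge=1)
    radius: int = Field(default=2, ge=1)
    n_bits: int = Field(default=2048, ge=64)
    feedback_weight: float = Field(default=1.0, ge=1)
    sort_of_policy: str = "half"
    prior_data: Optional[str] = None

    @field_validator("sort_of_policy")
    @classmethod
    def _policy(cls, v):
        if v not in ("half", "drop"):
            raise ValueError("sort_of_policy must be 'half' or 'drop'")
        return v

    def to_classifier_spec(self) -> ClassifierSpec:
        return ClassifierSpec(
            n_estimators=self.n_estimators, radius=self.radius, n_bits=self.n_bits
        )


class LoopBlock(_StrictModel):
    k: int = Field(default=10, ge=1)
    strategy: str = "maxmin"
    temperature: float = Field(default=0.1, gt=0)
    n_iterations: int = Field(default=3, ge=0)
    n_generate: int = Field(default=30, ge=1)
    seed: int = 0

    @field_validator("strategy")
    @classmethod
    def _strategy(cls, v):
        if v not in ("random", "maxmin"):
            raise ValueError("strategy must be 'random' or 'maxmin'")
        return v


class PersonaBlock(_StrictModel):
    disliked_smarts: list[str] = []
    liked_smarts: list[str] = []
    size_range: tuple[int, int] = (5, 50)
    noise_rate: float = Field(default=0.0, ge=0, lt=1)

    def to_persona(self) -> Persona:
        return Persona(
            disliked_smarts=tuple(self.disliked_smarts),
            liked_smarts=tuple(self.liked_smarts),
            size_range=self.size_range,
            noise_rate=self.noise_rate,
        )


class PathsBlock(_StrictModel):
    molecules: Optional[str] = None
    prior_qsar: Optional[str] = None
    run_dir: str = "runs/run"


class Config(_StrictModel):
    """Top-level configuration; every field has a usable default."""

    liability_labels: list[str] = [
        "toxicophore",
        "unstable",
        "synthesis_concern",
        "liked_feature",
    ]
    global_properties: list[str] = ["size", "synthetic_accessibility", "permeability"]
    reward: RewardBlock = RewardBlock()
    model: ModelBlock = ModelBlock()
    loop: LoopBlock = LoopBlock()
    persona: Optional[PersonaBlock] = None
    paths: PathsBlock = PathsBlock()


def load_config(path: str | Path, base_dir: str | Path | None = None) -> Config:
    """Load and strictly validate a YAML config file.

    Referenced input paths (molecules, prior QSAR data) are resolved
    relative to *base_dir* (default: the config file's directory) and must
    exist at validation time.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse YAML {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        config = Config.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(f"{path}: {exc}") from exc

    base = Path(base_dir) if base_dir is not None else path.parent
    for name, ref in (
        ("paths.molecules", config.paths.molecules),
        ("paths.prior_qsar", config.paths.prior_qsar),
        ("model.prior_data", config.model.prior_data),
    ):
        if ref is not None and not (base / ref).exists() and not Path(ref).exists():
            raise ConfigError(f"{path}: {name} references missing file {ref!r}")
    return config


def dump_config(config: Config) -> str:
    """Serialize a Config back to YAML (load/dump/load is the identity)."""
    return yaml.safe_dump(config.model_dump(), sort_keys=True)


def config_from_yaml_text(text: str) -> Config:
    raw = yaml.safe_load(text) or {}
    try:
        return Config.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
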