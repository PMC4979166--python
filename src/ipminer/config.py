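"""Structured pipeline configuration loaded from YAML with CLI overrides."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or inconsistent configuration (reported before any compute)."""


@dataclass
class PipelineConfig:
    """All tunables of the five-phase pipeline, with mode-aware defaults.

    ``mode`` selects the autoencoder topology: "sep" (default) trains two
    separate sub-networks of hidden sizes 256-128-64 whose top layers are
    concatenated; "con" trains a single 256-128-128 stack on the
    concatenated 599-dim input.
    """

    mode: str = "sep"
    architecture: list[int] | None = None
    noise_prob: float = 0.5
    pretrain_epochs: int = 100
    finetune_epochs: int = 100
    batch_size: int = 100
    pretrain_lr: float = 1e-3
    finetune_lr: float = 0.01
    momentum: float = 0.9
    n_trees: int = 100
    stack_folds: int = 5
    cv_folds: int = 5
    seed: int | None = None

    def validate(self) -> None:
        if self.mode not in ("sep", "con"):
            raise ConfigError(f"mode must be 'sep' or 'con', got {self.mode!r}")
        if self.architecture is not None and (
            not self.architecture or any(int(h) <= 0 for h in self.architecture)
        ):
            raise ConfigError("architecture entries must be positive")
        if not 0.0 <= self.noise_prob < 1.0:
            raise ConfigError("noise_prob must be in [0, 1)")
        for name in ("pretrain_epochs", "finetune_epochs", "batch_size",
                     "n_trees", "stack_folds", "cv_folds"):
            if int(getattr(self, name)) <= 0:
                raise ConfigError(f"{name} must be positive")

    def classifier_params(self) -> dict:
        """Keyword arguments for IPMinerClassifier."""
        return {
            "mode": self.mode,
            "architecture": tuple(self.architecture) if self.architecture else None,
            "noise_prob": self.noise_prob,
            "pretrain_epochs": self.pretrain_epochs,
            "finetune_epochs": self.finetune_epochs,
            "batch_size": self.batch_size,
            "pretrain_lr": self.pretrain_lr,
            "finetune_lr": self.finetune_lr,
            "momentum": self.momentum,
            "n_trees": self.n_trees,
            "stack_folds": self.stack_folds,
            "random_state": self.seed,
        }

    def as_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config (optional) and apply keyword overrides.

    Unknown keys are a ConfigError, so typos fail fast.
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded:
            data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    valid = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg
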