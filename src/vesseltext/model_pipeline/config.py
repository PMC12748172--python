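"""Model and training configuration."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from ..errors import ConfigError
from ..gated_transformer import PATCH

SE_PLACEMENTS = ("none", "down", "up", "all")

__all__ = ["ModelConfig", "TrainConfig", "SE_PLACEMENTS", "load_yaml_config"]


@dataclass
class ModelConfig:
    se_placement: str = "down"
    gating_enabled: bool = True
    base_channels: int = 8
    depth: int = 3
    vit_dim: int = 32
    heads: int = 4
    vit_depth: int = 1              # gated layers per U-level (down and up each)
    gate_granularity: int = 1
    se_reduction: int = 16
    text_embedder: str = "stub"
    text_dim: int = 768
    text_max_tokens: int = 32
    input_size: tuple[int, int] = (64, 64)

    def __post_init__(self):
        if self.se_placement not in SE_PLACEMENTS:
            raise ConfigError(f"se_placement must be one of {SE_PLACEMENTS}")
        if self.depth < 2:
            raise ConfigError("depth must be at least 2")
        if self.vit_dim % self.heads:
            raise ConfigError(f"heads ({self.heads}) must divide vit_dim ({self.vit_dim})")
        if self.text_embedder not in ("stub", "pretrained"):
            raise ConfigError(f"unknown text embedder {self.text_embedder!r}")
        h, w = self.input_size
        factor = self.downsampling_factor
        if h % factor or w % factor:
            raise ConfigError(
                f"input size {self.input_size} must be divisible by {factor} "
                f"(patch {PATCH} x 2^(depth-1))")
        if self.gate_granularity not in (1, self.vit_dim):
            raise ConfigError("gate_granularity must be 1 or vit_dim")

    @property
    def downsampling_factor(self) -> int:
        return PATCH * 2 ** (self.depth - 1)

    @property
    def encoder_channels(self) -> list[int]:
        return [self.base_channels * 2**i for i in range(self.depth)]

    def as_dict(self) -> dict:
        d = asdict(self)
        d["input_size"] = list(self.input_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "input_size" in d:
            d["input_size"] = tuple(d["input_size"])
        return cls(**d)


@dataclass
class TrainConfig:
    epochs: int = 300
    batch_size: int = 2
    optimizer: str = "adam"
    learning_rate: float = 0.001
    seed: int = 0
    loss: str = "bce_dice"
    device: str = "cpu"

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs and batch_size must be positive")
        if self.learning_rate < 0:
            raise ConfigError("learning_rate must be nonnegative")
        if self.optimizer not in ("adam", "sgd"):
            raise ConfigError(f"unknown optimizer {self.optimizer!r}")
        if self.loss not in ("bce_dice", "bce", "dice"):
            raise ConfigError(f"unknown loss {self.loss!r}")

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


def load_yaml_config(path: str | Path) -> tuple[ModelConfig, TrainConfig, dict]:
    """Read one YAML file with optional `model:`, `train:`, `synth:` blocks."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    model = ModelConfig.from_dict(raw.get("model", {}))
    train = TrainConfig.from_dict(raw.get("train", {}))
    return model, train, raw.get("synth", {})
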