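"""YAML run configuration with strict schema validation.

Unknown keys are rejected by name (no silent typos); omitted keys fall back
to explicit defaults, so a minimal config is valid.  ``load_config`` /
``save_config`` round-trip exactly.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .network import (EncoderConfig, NetworkConfig, SEIBConfig,
                      REFERENCE_TAP_DEPTHS, TINY_TAP_DEPTHS)
from .training import TrainConfig

__all__ = ["RunConfig", "SceneSection", "NetworkSection", "TrainSection",
           "EvalSection", "load_config", "save_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SceneSection(_Strict):
    n: int = 8
    image_height: int = 256
    image_width: int = 512
    overlap_fraction: float = 0.25
    missing_tooth_prob: float = 0.05
    noise_sigma: float = 0.02
    artifact_count: int = 3
    arch_curvature: float = 0.6


class NetworkSection(_Strict):
    backbone: str = "inceptionv3"
    tap_depths: list[int] | None = None     # default by backbone
    branch_width: int = 64
    fib_depth: int = 128
    head_width: int = 128
    activation: str = "sigmoid"
    upsample: str = "nearest"
    threshold: float = 0.5

    def build(self) -> NetworkConfig:
        depths = self.tap_depths
        if depths is None:
            depths = (TINY_TAP_DEPTHS if self.backbone == "tiny"
                      else REFERENCE_TAP_DEPTHS)
        return NetworkConfig(
            encoder=EncoderConfig(backbone=self.backbone,
                                  tap_depths=tuple(depths)),
            seib=SEIBConfig(branch_width=self.branch_width),
            fib_depth=self.fib_depth, head_width=self.head_width,
            activation=self.activation, upsample=self.upsample,
            threshold=self.threshold,
        )


class TrainSection(_Strict):
    split_fraction: float = 0.8
    batch_size: int = 2
    epochs: int = 200
    learning_rate: float = 3e-3
    optimizer: str = "adam"
    hflip_with_fdi_remap: bool = False
    rotation_deg: float = 0.0
    brightness_jitter: float = 0.0
    loss: str = "bce_per_channel"

    def build(self, seed: int) -> TrainConfig:
        return TrainConfig(seed=seed, **self.model_dump())


class EvalSection(_Strict):
    threshold: float = 0.5


class RunConfig(_Strict):
    """Top-level config: per-subcommand blocks plus the global seed."""

    seed: int = 0
    verbosity: int = 1
    scene: SceneSection = Field(default_factory=SceneSection)
    network: NetworkSection = Field(default_factory=NetworkSection)
    train: TrainSection = Field(default_factory=TrainSection)
    eval: EvalSection = Field(default_factory=EvalSection)


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    return RunConfig.model_validate(raw)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
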