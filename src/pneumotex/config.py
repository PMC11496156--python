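"""Configuration objects for the model, training loop, losses and the
synthetic generator, with YAML round-tripping for the CLI."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = ["ModelConfig", "TrainConfig", "LossConfig", "SyntheticParams",
           "load_config", "dump_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised for inconsistent or out-of-range configuration values."""


@dataclass
class ModelConfig:
    """Architecture knobs.

    ``backbone`` is either ``"resnet18"`` (standard widths 64..512, reduced
    to 256 channels, 256-pixel inputs) or ``"small"`` (halved widths 32..256,
    reduced to 128 channels) for desk-scale experiments on 64-pixel tiles.
    """

    input_size: int = 256
    backbone: str = "resnet18"
    reduced_channels: int = 256
    codewords: int = 8
    suppression: float = 0.2       # lambda; 1.0 disables suppression
    classes: int = 4
    seed: int = 0

    def validate(self) -> "ModelConfig":
        if self.input_size % 32 != 0:
            raise ConfigError(f"input_size must be divisible by 32 (backbone stride), got {self.input_size}")
        if self.backbone not in ("resnet18", "small"):
            raise ConfigError(f"unknown backbone {self.backbone!r}")
        if self.codewords < 1:
            raise ConfigError("codewords must be >= 1")
        if not 0.0 < self.suppression <= 1.0:
            raise ConfigError(f"suppression factor must be in (0, 1], got {self.suppression}")
        if self.classes < 2:
            raise ConfigError("need at least 2 classes")
        return self


@dataclass
class TrainConfig:
    """Optimization protocol; defaults follow the full-scale training recipe
    (Adam, lr 1e-4, batch 16, 300 epochs, flip + 10-degree rotation
    augmentation, five-fold cross-validation)."""

    learning_rate: float = 1e-4
    batch_size: int = 16
    epochs: int = 300
    augment_flip: bool = True
    augment_rotation: float = 10.0
    folds: int = 5
    seed: int = 0

    def validate(self) -> "TrainConfig":
        if self.learning_rate <= 0 or self.batch_size < 2 or self.epochs < 1:
            raise ConfigError("learning_rate, batch_size and epochs must be positive (batch >= 2)")
        if self.augment_rotation < 0:
            raise ConfigError("rotation degrees must be >= 0")
        return self


@dataclass
class LossConfig:
    """Loss weights: total = alpha * contrastive + beta * reweighted KL."""

    alpha: float = 0.5
    beta: float = 0.5
    tau: float = 0.1
    supcon_variant: str = "in"

    def validate(self) -> "LossConfig":
        if self.alpha < 0 or self.beta < 0 or self.alpha + self.beta <= 0:
            raise ConfigError("need alpha, beta >= 0 with alpha + beta > 0")
        if self.tau <= 0:
            raise ConfigError("temperature tau must be positive")
        if self.supcon_variant not in ("in", "out"):
            raise ConfigError(f"unknown supcon variant {self.supcon_variant!r}")
        return self


# default opacity counts per profusion level for 256-pixel tiles; adjacent
# ranges are separated so levels are confusable but separable
_DEFAULT_COUNTS = ((0, 2), (8, 16), (24, 48), (64, 128))


@dataclass
class SyntheticParams:
    """Knobs of the synthetic subregion generator (see pneumotex.synthetic)."""

    tile_size: int = 256
    opacity_count_ranges: tuple = _DEFAULT_COUNTS
    opacity_radius_range: tuple = (2.0, 6.0)
    opacity_intensity_range: tuple = (0.15, 0.40)
    rib_band_count: int = 4
    rib_band_width: float = 10.0
    rib_band_intensity_range: tuple = (0.08, 0.20)
    background_smoothing: float = 8.0
    background_noise: float = 0.06

    def validate(self) -> "SyntheticParams":
        if self.tile_size < 16:
            raise ConfigError("tile_size must be >= 16")
        ranges = [tuple(r) for r in self.opacity_count_ranges]
        for lo, hi in ranges:
            if lo < 0 or hi < lo:
                raise ConfigError(f"invalid opacity count range ({lo}, {hi})")
        for a, b in zip(ranges, ranges[1:]):
            if b[0] <= a[1]:
                raise ConfigError("opacity count ranges must be strictly increasing across levels")
        if self.opacity_radius_range[0] <= 0:
            raise ConfigError("opacity radius must be positive")
        if self.rib_band_count < 0:
            raise ConfigError("rib_band_count must be >= 0")
        return self

    def scaled(self, tile_size: int) -> "SyntheticParams":
        """Rescale the generator for a different tile size.

        Counts scale with the linear factor f and radii with sqrt(f), so
        blobs shrink less than the tile and stay resolvable while the
        per-level count ordering (and confusability of adjacent levels) is
        preserved.  For 64-pixel tiles the default 256-pixel ranges become
        (0,1), (2,4), (6,12), (16,32) with radii (1, 3).
        """
        f = tile_size / self.tile_size
        if f == 1.0:
            return self
        rf = np.sqrt(f) if f < 1 else f
        counts = []
        prev_hi = -1
        for lo, hi in self.opacity_count_ranges:
            lo2 = max(int(np.floor(lo * f)), prev_hi + 1)
            hi2 = max(int(np.ceil(hi * f)), lo2)
            counts.append((lo2, hi2))
            prev_hi = hi2
        return SyntheticParams(
            tile_size=tile_size,
            opacity_count_ranges=tuple(counts),
            opacity_radius_range=(max(1.0, self.opacity_radius_range[0] * rf),
                                  max(1.5, self.opacity_radius_range[1] * rf)),
            opacity_intensity_range=self.opacity_intensity_range,
            rib_band_count=self.rib_band_count,
            rib_band_width=max(2.0, self.rib_band_width * rf),
            rib_band_intensity_range=self.rib_band_intensity_range,
            background_smoothing=max(1.0, self.background_smoothing * rf),
            background_noise=self.background_noise,
        ).validate()


_SECTIONS = {"model": ModelConfig, "train": TrainConfig, "loss": LossConfig,
             "synthetic": SyntheticParams}


def load_config(path) -> dict:
    """Read a YAML config with optional model/train/loss/synthetic sections."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out = {}
    for key, cls in _SECTIONS.items():
        section = raw.get(key, {}) or {}
        unknown = set(section) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ConfigError(f"unknown keys in [{key}]: {sorted(unknown)}")
        obj = cls(**section)
        # tuples survive YAML as lists; normalize
        if key == "synthetic":
            obj.opacity_count_ranges = tuple(tuple(r) for r in obj.opacity_count_ranges)
        out[key] = obj.validate()
    return out


def dump_config(configs: dict, path) -> None:
    payload = {k: asdict(v) for k, v in configs.items()}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
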