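"""One structured (YAML) run configuration driving every pipeline stage.

Missing fields fall back to the study defaults: HU window [-29, +150],
6:2:2 patient split, x5 augmentation, Adam at lr 1e-4 with batch 4, up to
1000 epochs with patience 100 for both early stopping and LR decay.
Cross-field invariants (ratio sum, input side vs network depth, seeds
present) are checked up front, and violations name the offending field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .phantoms import PhantomSpec, MUSCLE_HU_WINDOW
from .training import TrainConfig
from .unet import UNetConfig

__all__ = ["RunConfig", "ConfigError", "validate_config", "load_config"]


class ConfigError(ValueError):
    """A run configuration field violates an invariant."""


@dataclass
class RunConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    unet: UNetConfig = field(default_factory=UNetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    hu_window: tuple[float, float] = MUSCLE_HU_WINDOW
    split_ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    split_seed: int = 0
    augment_factor: int = 5
    augment_seed: int = 0
    cv_rounds: int = 3
    cv_seeds: tuple[int, ...] = (1, 2, 3)
    out_dir: str = "run"

    def validate(self) -> "RunConfig":
        if abs(sum(self.split_ratios) - 1.0) > 1e-9:
            raise ConfigError(
                f"split_ratios: {self.split_ratios} must sum to 1")
        if self.augment_factor < 1:
            raise ConfigError("augment_factor: must be >= 1")
        f = self.unet.pool_factor
        if self.phantom.image_size % f:
            raise ConfigError(
                f"phantom.image_size: {self.phantom.image_size} not divisible "
                f"by 2^(depth-1) = {f} required by unet.depth = {self.unet.depth}")
        lo, hi = self.hu_window
        if lo > hi:
            raise ConfigError(f"hu_window: lower bound {lo} exceeds upper {hi}")
        if len(set(self.cv_seeds)) < self.cv_rounds:
            raise ConfigError(
                f"cv_seeds: need {self.cv_rounds} distinct seeds, got {self.cv_seeds}")
        return self


def _build(section_cls, data, name):
    try:
        return section_cls(**(data or {}))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{name}: {exc}") from exc


def load_config(data: dict) -> RunConfig:
    """Build and validate a RunConfig from a plain dict (parsed YAML)."""
    data = dict(data or {})
    kwargs = {}
    if "phantom" in data:
        ph = dict(data.pop("phantom"))
        if "body_axes" in ph and ph["body_axes"] is not None:
            ph["body_axes"] = tuple(ph["body_axes"])
        kwargs["phantom"] = _build(PhantomSpec, ph, "phantom")
    if "unet" in data:
        kwargs["unet"] = _build(UNetConfig, data.pop("unet"), "unet")
    if "train" in data:
        kwargs["train"] = _build(TrainConfig, data.pop("train"), "train")
    for key in ("hu_window", "split_ratios", "cv_seeds"):
        if key in data:
            kwargs[key] = tuple(data.pop(key))
    for key in ("split_seed", "augment_factor", "augment_seed", "cv_rounds",
                "out_dir"):
        if key in data:
            kwargs[key] = data.pop(key)
    if data:
        raise ConfigError(f"unknown config fields: {sorted(data)}")
    return RunConfig(**kwargs).validate()


def validate_config(path) -> RunConfig:
    """Parse a YAML config file, fill defaults, check invariants."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return load_config(raw)


def dump_config(cfg: RunConfig, path) -> None:
    data = {
        "phantom": asdict(cfg.phantom),
        "unet": asdict(cfg.unet),
        "train": asdict(cfg.train),
        "hu_window": list(cfg.hu_window),
        "split_ratios": list(cfg.split_ratios),
        "split_seed": cfg.split_seed,
        "augment_factor": cfg.augment_factor,
        "augment_seed": cfg.augment_seed,
        "cv_rounds": cfg.cv_rounds,
        "cv_seeds": list(cfg.cv_seeds),
        "out_dir": cfg.out_dir,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
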