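"""Augmentation and training configuration.

Defaults follow the herbarium training recipe: horizontal flip at
probability 0.5; rotation (max 10 degrees), zoom (max factor 1.1),
lighting adjustment (max factor 0.2) and perspective warp (max factor
0.2), each applied independently with probability 0.75; 256 x 256 inputs;
an 80/20 train/validation split; 22 epochs under the one-cycle learning
rate policy.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass


@dataclass(frozen=True)
class AugmentConfig:
    hflip_prob: float = 0.5
    transform_prob: float = 0.75   # applied independently to rotate/zoom/light/warp
    rot_max_deg: float = 10.0
    zoom_max: float = 1.1
    light_max: float = 0.2
    warp_max: float = 0.2

    def validate(self) -> "AugmentConfig":
        for name in ("hflip_prob", "transform_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.rot_max_deg < 0:
            raise ValueError("rot_max_deg must be >= 0")
        if self.zoom_max < 1.0:
            raise ValueError("zoom_max must be >= 1")
        return self

    @staticmethod
    def identity() -> "AugmentConfig":
        """All probabilities zero: augmentation becomes the identity."""
        return AugmentConfig(hflip_prob=0.0, transform_prob=0.0)


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of a training run.

    ``lr_max`` and ``batch_size`` are not dictated by the recipe and carry
    package defaults; ``warmup_fraction`` / ``div_factor`` /
    ``final_div_factor`` parameterize the one-cycle schedule.  One root
    ``seed`` drives the split, the parameter init and the augmentation
    stream through derived sub-seeds.
    """

    image_size: int = 256
    val_fraction: float = 0.2
    epochs: int = 22
    lr_max: float = 1e-2
    warmup_fraction: float = 0.3
    div_factor: float = 25.0
    final_div_factor: float = 2.5e4
    batch_size: int = 4
    encoder_depth: int = 4
    base_channels: int = 16
    loss: str = "bce"              # "bce" or "dice"
    seed: int = 0

    def validate(self) -> "TrainConfig":
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.image_size % (2 ** self.encoder_depth) != 0:
            raise ValueError(
                f"image_size {self.image_size} must be divisible by 2^encoder_depth "
                f"= {2 ** self.encoder_depth}"
            )
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss not in ("bce", "dice"):
            raise ValueError(f"loss must be 'bce' or 'dice', got {self.loss!r}")
        if self.lr_max <= 0 or self.batch_size < 1:
            raise ValueError("lr_max must be positive and batch_size >= 1")
        if not 0.0 < self.warmup_fraction < 1.0:
            raise ValueError("warmup_fraction must be in (0, 1)")
        return self


def configs_to_json(train_cfg: TrainConfig, aug_cfg: AugmentConfig) -> str:
    return json.dumps({"train": asdict(train_cfg), "augment": asdict(aug_cfg)}, indent=2)


def configs_from_json(text: str) -> tuple[TrainConfig, AugmentConfig]:
    raw = json.loads(text)
    return TrainConfig(**raw["train"]).validate(), AugmentConfig(**raw["augment"]).validate()
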