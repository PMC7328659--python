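"""Training loop: augmented mini-batches, one-cycle schedule, Adam.

The loss is mean per-pixel binary cross-entropy on sigmoid scores against
the {0, 1} mask (a soft-Dice loss is available as a config option).  One
root seed drives the train/validation split, parameter initialization and
the augmentation stream through derived sub-streams, so a run is fully
deterministic up to floating-point reduction order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..evaluate import dice
from ..imaging import PLANT
from .config import AugmentConfig, TrainConfig
from .data import augment_pair, prepare_sample, split_dataset
from .layers import Adam
from .model import UNet, to_input
from .schedule import one_cycle_lr


@dataclass
class TrainHistory:
    """Per-epoch losses and validation Dice, plus the per-step LR trace."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    lr_trace: list[float] = field(default_factory=list)


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Numerically stable mean BCE and its gradient w.r.t. the logits."""
    z = logits.astype(np.float64)
    loss = np.mean(np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z))))
    p = 1.0 / (1.0 + np.exp(-z))
    grad = ((p - y) / z.size).astype(np.float32)
    return float(loss), grad


def soft_dice_loss(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """1 - soft Dice over the batch, with gradient w.r.t. the logits."""
    z = logits.astype(np.float64)
    p = 1.0 / (1.0 + np.exp(-z))
    inter = np.sum(p * y)
    denom = np.sum(p) + np.sum(y)
    eps = 1.0
    loss = 1.0 - (2.0 * inter + eps) / (denom + eps)
    # d(loss)/dp, then chain through the sigmoid
    dldp = -(2.0 * y * (denom + eps) - (2.0 * inter + eps)) / (denom + eps) ** 2
    grad = (dldp * p * (1.0 - p)).astype(np.float32)
    return float(loss), grad


def _loss_fn(name: str):
    return {"bce": bce_with_logits, "dice": soft_dice_loss}[name]


def _evaluate_epoch(model: UNet, xs: np.ndarray, ys: np.ndarray, masks: list[np.ndarray],
                    batch_size: int, loss_name: str) -> tuple[float, float]:
    losses, dices = [], []
    fn = _loss_fn(loss_name)
    for b0 in range(0, len(xs), batch_size):
        xb = xs[b0:b0 + batch_size]
        yb = ys[b0:b0 + batch_size]
        logits = model.forward(xb)[:, 0]
        loss, _ = fn(logits, yb)
        losses.append(loss * len(xb))
        for j in range(len(xb)):
            pred = np.where(logits[j] > 0.0, PLANT, 0).astype(np.uint8)
            dices.append(dice(pred, masks[b0 + j]))
    return float(np.sum(losses) / len(xs)), float(np.mean(dices))


def train(model: UNet, images: list[np.ndarray], masks: list[np.ndarray],
          cfg: TrainConfig, aug_cfg: AugmentConfig | None = None,
          ) -> tuple[UNet, TrainHistory]:
    """Train in place on (image, mask) pairs; returns the model and history.

    Inputs may be any size: every pair passes through the center-crop /
    resize geometry first.  Augmentation is redrawn per sample per epoch
    on the training partition only; validation images are scored
    unaugmented, with per-epoch mean Dice recorded in the history.
    """
    cfg = cfg.validate()
    aug_cfg = (aug_cfg or AugmentConfig()).validate()
    if len(images) != len(masks) or not images:
        raise ValueError("need equally many images and masks, at least one pair")

    train_idx, val_idx = split_dataset(len(images), cfg.val_fraction, cfg.seed)
    size = cfg.image_size
    prepared = [prepare_sample(img, m, size) for img, m in zip(images, masks)]

    val_masks = [prepared[i][1] for i in val_idx]
    val_x = np.stack([to_input(prepared[i][0]) for i in val_idx])
    val_y = np.stack([prepared[i][1].astype(np.float32) / PLANT for i in val_idx])

    aug_rng = np.random.default_rng([cfg.seed, 0xA06])
    order_rng = np.random.default_rng([cfg.seed, 0x0D8])
    opt = Adam(model.parameters())
    loss_fn = _loss_fn(cfg.loss)

    steps_per_epoch = math.ceil(len(train_idx) / cfg.batch_size)
    total_steps = cfg.epochs * steps_per_epoch
    history = TrainHistory()
    step = 0
    for _epoch in range(cfg.epochs):
        order = order_rng.permutation(train_idx)
        epoch_losses = []
        for b0 in range(0, len(order), cfg.batch_size):
            batch_ids = order[b0:b0 + cfg.batch_size]
            xs, ys = [], []
            for i in batch_ids:
                img_a, mask_a = augment_pair(prepared[i][0], prepared[i][1], aug_cfg, aug_rng)
                xs.append(to_input(img_a))
                ys.append(mask_a.astype(np.float32) / PLANT)
            xb = np.stack(xs)
            yb = np.stack(ys)
            logits = model.forward(xb)[:, 0]
            loss, glogits = loss_fn(logits, yb)
            model.backward(glogits[:, None])
            lr = one_cycle_lr(step, total_steps, cfg)
            opt.step(lr)
            history.lr_trace.append(lr)
            epoch_losses.append(loss * len(batch_ids))
            step += 1
        history.train_loss.append(float(np.sum(epoch_losses) / len(train_idx)))
        val_loss, val_dice = _evaluate_epoch(model, val_x, val_y, val_masks,
                                             cfg.batch_size, cfg.loss)
        history.val_loss.append(val_loss)
        history.val_dice.append(val_dice)
    return model, history
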