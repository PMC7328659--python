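"""Compact U-Net-style encoder-decoder on numpy.

The network follows the classic segmentation layout: ``encoder_depth``
downsampling stages of two 3x3 conv + ReLU layers followed by 2x2 max
pooling, a two-conv bottleneck, and a mirrored decoder of nearest 2x
upsampling, skip concatenation with the matching encoder resolution, and
two 3x3 conv + ReLU layers, ending in a 1x1 conv producing one logit per
pixel.  Channel widths double per stage from ``base_channels``.

Initialization is seeded (He normal) and fully determined by the training
config, so two builds from the same config are bit-identical.  Loading
externally pretrained encoder weights is possible through
``load_checkpoint`` but never required.
"""

from __future__ import annotations

import json
import os

import numpy as np

from ..imaging import PLANT, validate_rgb
from .config import AugmentConfig, TrainConfig, configs_from_json, configs_to_json
from .data import prepare_image
from .layers import Adam, Conv2d, MaxPool2, Param, ReLU, Upsample2


class _ConvBlock:
    """Two 3x3 conv + ReLU layers."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv1 = Conv2d(cin, cout, 3, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, rng)
        self.relu2 = ReLU()

    def parameters(self) -> list[Param]:
        return self.conv1.parameters() + self.conv2.parameters()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.relu2.forward(self.conv2.forward(self.relu1.forward(self.conv1.forward(x))))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return self.conv1.backward(self.relu1.backward(
            self.conv2.backward(self.relu2.backward(gy))))


class UNet:
    def __init__(self, cfg: TrainConfig):
        cfg = cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng([cfg.seed, 0x5E61])
        d, c = cfg.encoder_depth, cfg.base_channels
        self.chans = [c * 2 ** i for i in range(d + 1)]
        self.enc = []
        self.pools = []
        cin = 3
        for i in range(d):
            self.enc.append(_ConvBlock(cin, self.chans[i], rng))
            self.pools.append(MaxPool2())
            cin = self.chans[i]
        self.bottleneck = _ConvBlock(self.chans[d - 1], self.chans[d], rng)
        self.ups = [Upsample2() for _ in range(d)]
        self.dec = [_ConvBlock(self.chans[i + 1] + self.chans[i], self.chans[i], rng)
                    for i in range(d)]
        self.head = Conv2d(self.chans[0], 1, 1, rng)

    def parameters(self) -> list[Param]:
        params: list[Param] = []
        for blk in self.enc:
            params += blk.parameters()
        params += self.bottleneck.parameters()
        for blk in self.dec:
            params += blk.parameters()
        params += self.head.parameters()
        return params

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, 3, S, S) float32 -> (N, 1, S, S) logits."""
        d = self.cfg.encoder_depth
        h = x
        skips = []
        for i in range(d):
            h = self.enc[i].forward(h)
            skips.append(h)
            h = self.pools[i].forward(h)
        h = self.bottleneck.forward(h)
        self._skip_chans = [s.shape[1] for s in skips]
        for i in range(d - 1, -1, -1):
            h = self.ups[i].forward(h)
            h = np.concatenate([h, skips[i]], axis=1)
            h = self.dec[i].forward(h)
        return self.head.forward(h)

    def backward(self, glogits: np.ndarray) -> np.ndarray:
        d = self.cfg.encoder_depth
        g = self.head.backward(glogits)
        skip_grads: list[np.ndarray | None] = [None] * d
        for i in range(d):                       # reverse of decoding order
            g = self.dec[i].backward(g)
            split = self.chans[i + 1]
            skip_grads[i] = g[:, split:]
            g = self.ups[i].backward(np.ascontiguousarray(g[:, :split]))
        g = self.bottleneck.backward(g)
        for i in range(d - 1, -1, -1):
            g = self.pools[i].backward(g)
            g = g + skip_grads[i]
            g = self.enc[i].backward(g)
        return g


def build_model(cfg: TrainConfig) -> UNet:
    """Build a seeded network; parameter count is deterministic per config."""
    return UNet(cfg)


def to_input(img: np.ndarray) -> np.ndarray:
    """uint8 RGB (S, S, 3) -> normalized float32 (3, S, S)."""
    return (img.astype(np.float32) / 255.0 - 0.5).transpose(2, 0, 1)


def predict_logits(model: UNet, batch: np.ndarray) -> np.ndarray:
    """Forward a normalized (N, 3, S, S) batch to (N, S, S) logits."""
    return model.forward(batch.astype(np.float32))[:, 0]


def predict_mask(model: UNet, img: np.ndarray) -> np.ndarray:
    """Predict a binary mask at model resolution for an image of any size.

    The input goes through the same center-crop / resize geometry as
    training samples; per-pixel scores above probability 0.5 (logit > 0)
    map to 255.  Deterministic: same model and image give the same mask.
    """
    img = validate_rgb(img)
    size = model.cfg.image_size
    prepared = prepare_image(img, size)
    logits = predict_logits(model, to_input(prepared)[None])
    return np.where(logits[0] > 0.0, PLANT, 0).astype(np.uint8)


def save_checkpoint(model: UNet, aug_cfg: AugmentConfig, path: str | os.PathLike) -> str:
    """Serialize parameters (.npz) plus a JSON sidecar with both configs,
    so a checkpoint is self-describing."""
    path = os.fspath(path)
    arrays = {f"param_{i:03d}": p.value for i, p in enumerate(model.parameters())}
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)
    with open(path + ".json", "w") as fh:
        fh.write(configs_to_json(model.cfg, aug_cfg))
    return path


def load_checkpoint(path: str | os.PathLike) -> tuple[UNet, AugmentConfig]:
    path = os.fspath(path)
    with open(path + ".json") as fh:
        cfg, aug_cfg = configs_from_json(fh.read())
    model = UNet(cfg)
    with np.load(path) as data:
        params = model.parameters()
        if len(data.files) != len(params):
            raise ValueError(
                f"checkpoint {path!r} has {len(data.files)} tensors but the config "
                f"describes a model with {len(params)}"
            )
        for i, p in enumerate(params):
            stored = data[f"param_{i:03d}"]
            if stored.shape != p.value.shape:
                raise ValueError(
                    f"checkpoint tensor {i} shape {stored.shape} does not match "
                    f"model shape {p.value.shape}; config/checkpoint mismatch"
                )
            p.value[...] = stored
    return model, aug_cfg
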