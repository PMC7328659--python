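"""Data handling for segmentation training: split, geometry, augmentation.

Rectangular sheets are center-cropped to a square on the shorter side and
resized to the model resolution; images are resampled bilinearly, masks by
nearest neighbor so they stay strictly binary.  Augmentation draws one
geometric chain per sample (horizontal flip; small rotation; zoom;
4-corner perspective warp) and applies it identically to image and mask;
a lighting adjustment touches the image only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import transform as sktransform

from ..imaging import PLANT, validate_mask, validate_rgb
from ..maskpost import rebinarize
from .config import AugmentConfig


def split_dataset(n: int, val_fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded shuffle split into disjoint, exhaustive train/val index sets.

    Validation size is ``round(n * val_fraction)``; a split that would
    leave either side empty raises.
    """
    if n < 2:
        raise ValueError("need at least 2 items to split")
    n_val = int(round(n * val_fraction))
    if n_val == 0 or n_val == n:
        raise ValueError(
            f"val_fraction {val_fraction} gives a validation set of size {n_val} for n={n}"
        )
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[n_val:]), np.sort(perm[:n_val])


def _center_square(arr: np.ndarray) -> np.ndarray:
    h, w = arr.shape[:2]
    side = min(h, w)
    r0 = (h - side) // 2
    c0 = (w - side) // 2
    return arr[r0:r0 + side, c0:c0 + side]


def prepare_image(img: np.ndarray, size: int) -> np.ndarray:
    """Center square crop then bilinear resize to ``size x size`` RGB."""
    img = validate_rgb(img)
    crop = _center_square(img)
    out = sktransform.resize(crop.astype(np.float64), (size, size),
                             order=1, anti_aliasing=True, preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def prepare_mask(mask: np.ndarray, size: int) -> np.ndarray:
    """Center square crop then nearest-neighbor resize; output stays binary."""
    mask = validate_mask(mask)
    crop = _center_square(mask)
    out = sktransform.resize(crop, (size, size), order=0,
                             anti_aliasing=False, preserve_range=True)
    return out.astype(np.uint8)


def prepare_sample(img: np.ndarray, mask: np.ndarray, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Apply the identical crop/resize geometry to an image/mask pair."""
    img = validate_rgb(img)
    mask = validate_mask(mask)
    if img.shape[:2] != mask.shape:
        raise ValueError(f"image {img.shape[:2]} and mask {mask.shape} dimensions differ")
    return prepare_image(img, size), prepare_mask(mask, size)


@dataclass(frozen=True)
class AugmentParams:
    """One concrete draw of the augmentation chain."""

    hflip: bool = False
    angle_deg: float = 0.0
    zoom: float = 1.0
    corner_shift: np.ndarray | None = None   # (4, 2) fractional corner offsets
    light: float = 0.0                        # multiplicative brightness delta

    @property
    def is_geometric_identity(self) -> bool:
        return (not self.hflip and self.angle_deg == 0.0 and self.zoom == 1.0
                and self.corner_shift is None)


def sample_augment(cfg: AugmentConfig, rng: np.random.Generator) -> AugmentParams:
    """Draw one augmentation: flip at ``hflip_prob``; each other transform
    independently at ``transform_prob`` with magnitude uniform up to its max."""
    cfg = cfg.validate()
    hflip = bool(rng.random() < cfg.hflip_prob)
    angle = float(rng.uniform(-cfg.rot_max_deg, cfg.rot_max_deg)) \
        if rng.random() < cfg.transform_prob else 0.0
    zoom = float(rng.uniform(1.0, cfg.zoom_max)) \
        if rng.random() < cfg.transform_prob else 1.0
    corner_shift = None
    if rng.random() < cfg.transform_prob and cfg.warp_max > 0:
        # corners displaced up to warp_max/2 of the side, the usual
        # realization of a "warp by factor w" perspective jitter
        corner_shift = rng.uniform(-cfg.warp_max / 2, cfg.warp_max / 2, size=(4, 2))
    light = float(rng.uniform(-cfg.light_max, cfg.light_max)) \
        if rng.random() < cfg.transform_prob else 0.0
    return AugmentParams(hflip=hflip, angle_deg=angle, zoom=zoom,
                         corner_shift=corner_shift, light=light)


def _geometric_matrix(params: AugmentParams, side: int) -> np.ndarray:
    """Forward homography (input -> output) in (x, y) homogeneous coords."""
    c = (side - 1) / 2.0
    to_center = np.array([[1, 0, -c], [0, 1, -c], [0, 0, 1]], dtype=np.float64)
    from_center = np.array([[1, 0, c], [0, 1, c], [0, 0, 1]], dtype=np.float64)
    m = np.eye(3)
    if params.hflip:
        m = np.array([[-1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]]) @ m
    if params.angle_deg != 0.0:
        a = np.deg2rad(params.angle_deg)
        m = np.array([[np.cos(a), -np.sin(a), 0],
                      [np.sin(a), np.cos(a), 0], [0, 0, 1.0]]) @ m
    if params.zoom != 1.0:
        m = np.diag([params.zoom, params.zoom, 1.0]) @ m
    m = from_center @ m @ to_center
    if params.corner_shift is not None:
        corners = np.array([[0, 0], [side - 1, 0], [side - 1, side - 1], [0, side - 1]],
                           dtype=np.float64)
        shifted = corners + params.corner_shift * side
        tform = sktransform.ProjectiveTransform.from_estimate(corners, shifted)
        if not tform:
            raise RuntimeError("degenerate perspective warp")
        m = tform.params @ m
    return m


def apply_geometric(arr: np.ndarray, params: AugmentParams, *, is_mask: bool) -> np.ndarray:
    """Apply the sampled geometric chain to a square raster.

    Images interpolate bilinearly; masks use nearest neighbor and are
    re-binarized, so binarity survives the warp.
    """
    side = arr.shape[0]
    if arr.shape[1] != side:
        raise ValueError("augmentation expects square inputs")
    if params.is_geometric_identity:
        return arr.copy()
    m = _geometric_matrix(params, side)
    tform = sktransform.ProjectiveTransform(matrix=m)
    warped = sktransform.warp(arr.astype(np.float64), tform.inverse,
                              order=0 if is_mask else 1,
                              mode="reflect", preserve_range=True)
    out = np.clip(np.rint(warped), 0, 255).astype(np.uint8)
    if is_mask:
        out = rebinarize(out, 127)
    return out


def apply_photometric(img: np.ndarray, params: AugmentParams) -> np.ndarray:
    """Multiplicative brightness adjustment; image pathway only."""
    if params.light == 0.0:
        return img.copy()
    out = img.astype(np.float64) * (1.0 + params.light)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def augment_pair(img: np.ndarray, mask: np.ndarray, cfg: AugmentConfig,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One augmentation draw applied consistently to an image/mask pair.

    The geometric chain is shared; the lighting adjustment touches the
    image only, so the mask's labels stay aligned with the warped pixels.
    """
    if img.shape[:2] != mask.shape:
        raise ValueError("image and mask dimensions differ")
    params = sample_augment(cfg, rng)
    img_out = apply_photometric(apply_geometric(img, params, is_mask=False), params)
    mask_out = apply_geometric(mask, params, is_mask=True)
    return img_out, mask_out
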