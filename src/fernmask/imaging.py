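"""Core raster types, color conversion, and lossless mask I/O.

Images are plain numpy arrays throughout the package:

* RGB image  -- ``(H, W, 3)`` uint8, channel order red-green-blue
* gray image -- ``(H, W)`` uint8
* binary mask -- ``(H, W)`` uint8 with values in ``{0, 255}``;
  255 (white) labels plant tissue, 0 (black) labels background.

Masks are always written as lossless 8-bit grayscale PNG: a lossy codec
would introduce intermediate gray values and destroy binarity.
"""

from __future__ import annotations

import os

import numpy as np
from PIL import Image, UnidentifiedImageError

#: Pixel value labelling plant tissue in a binary mask.
PLANT: int = 255
#: Pixel value labelling background in a binary mask.
BACKGROUND: int = 0

# ITU-R BT.601 luma weights (the conversion dialect of the classic
# imaging libraries' default RGB->gray routine).
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


class ImageDecodeError(ValueError):
    """Raised when a file cannot be read as an image."""


def validate_rgb(img: np.ndarray) -> np.ndarray:
    """Check that ``img`` is a valid ``(H, W, 3)`` uint8 RGB raster."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB raster, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("image must have at least one row and one column")
    if img.dtype != np.uint8:
        if np.issubdtype(img.dtype, np.integer) and img.min() >= 0 and img.max() <= 255:
            img = img.astype(np.uint8)
        else:
            raise ValueError(f"RGB raster must be 8-bit integer in [0, 255], got dtype {img.dtype}")
    return img


def validate_gray(img: np.ndarray) -> np.ndarray:
    """Check that ``img`` is a valid ``(H, W)`` uint8 grayscale raster."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected (H, W) gray raster, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("image must have at least one row and one column")
    if img.dtype != np.uint8:
        if np.issubdtype(img.dtype, np.integer) and img.min() >= 0 and img.max() <= 255:
            img = img.astype(np.uint8)
        else:
            raise ValueError(f"gray raster must be 8-bit integer in [0, 255], got dtype {img.dtype}")
    return img


def validate_mask(mask: np.ndarray) -> np.ndarray:
    """Check that ``mask`` is a binary ``{0, 255}`` uint8 raster."""
    mask = validate_gray(mask)
    bad = (mask != BACKGROUND) & (mask != PLANT)
    if bad.any():
        values = np.unique(mask[bad])[:8]
        raise ValueError(f"mask is not binary: contains values {values.tolist()} (expected only 0 and 255)")
    return mask


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a JPEG or PNG file as an ``(H, W, 3)`` uint8 RGB raster.

    16-bit inputs are rescaled to 8 bits; grayscale and paletted inputs
    are expanded to three channels.
    """
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode in ("I", "I;16", "I;16B", "I;16L"):
                arr = np.asarray(im, dtype=np.float64)
                arr = np.clip(np.rint(arr / 257.0), 0, 255).astype(np.uint8)
                im = Image.fromarray(arr, mode="L")
            rgb = im.convert("RGB")
            return np.asarray(rgb, dtype=np.uint8)
    except (UnidentifiedImageError, OSError, SyntaxError) as exc:
        raise ImageDecodeError(f"could not decode image file {os.fspath(path)!r}: {exc}") from exc


def read_gray(path: str | os.PathLike) -> np.ndarray:
    """Read an image file as a single-channel uint8 raster (BT.601 luma)."""
    return to_grayscale(read_image(path))


def read_mask(path: str | os.PathLike, strict: bool = True) -> np.ndarray:
    """Read a binary mask PNG.

    With ``strict`` (default) any non-{0,255} value raises; masks edited by
    hand may contain intermediate grays and should be read with
    ``strict=False`` and passed through :func:`fernmask.maskpost.rebinarize`.
    """
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"), dtype=np.uint8)
    except (UnidentifiedImageError, OSError, SyntaxError) as exc:
        raise ImageDecodeError(f"could not decode mask file {os.fspath(path)!r}: {exc}") from exc
    if strict:
        return validate_mask(arr)
    return arr


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> str:
    """Write a binary mask as 8-bit grayscale PNG and return the path.

    Round-trips bit-exactly: ``read_mask(write_mask(m)) == m``. Non-binary
    input raises before anything is written.
    """
    mask = validate_mask(mask)
    Image.fromarray(mask, mode="L").save(os.fspath(path), format="PNG")
    return os.fspath(path)


def write_image(img: np.ndarray, path: str | os.PathLike) -> str:
    """Write an RGB raster as PNG (or JPEG if the suffix says so)."""
    img = validate_rgb(img)
    Image.fromarray(img, mode="RGB").save(os.fspath(path))
    return os.fspath(path)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert RGB to grayscale with BT.601 luma weights.

    Per-pixel ``0.299 R + 0.587 G + 0.114 B``, rounded to the nearest
    integer and clamped to [0, 255].
    """
    img = validate_rgb(img)
    luma = img.astype(np.float64) @ _LUMA_WEIGHTS
    return np.clip(np.rint(luma), 0, 255).astype(np.uint8)
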