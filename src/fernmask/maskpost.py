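"""Mask post-processing: re-binarization and despeckling.

Automatically generated (or hand-edited) foreground masks carry two kinds
of defects: intermediate gray values introduced by editing tools along
brushed edges, and small isolated specks where dust or stains on the sheet
fell on the dark side of the threshold.  ``rebinarize`` restores strict
{0, 255} binarity; ``despeckle`` removes the specks with a median filter
over a square pixel neighborhood (an edge-preserving smoother, unlike a
Gaussian blur which would erode the fine frond margins that make these
masks valuable).

The filter's neighborhood size trades speck removal against loss of thin
structures, and the right setting depends on the specimen's condition, so
``blur_sweep`` runs a small set of kernel sizes and returns *all*
candidates; picking the best one is deliberately left to the user.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .imaging import PLANT, validate_gray, validate_mask

#: Default despeckle kernel sweep: small / medium / large neighborhoods.
DEFAULT_KERNELS: tuple[int, ...] = (5, 11, 21)


@dataclass(frozen=True)
class BlurSweep:
    """Despeckled candidates, one per kernel size, for visual inspection."""

    kernel_sizes: tuple[int, ...]
    candidates: tuple[np.ndarray, ...]

    def pick(self, index: int | None = None) -> np.ndarray:
        """Return one candidate; defaults to the middle kernel."""
        if index is None:
            index = len(self.candidates) // 2
        return self.candidates[index]


def rebinarize(img: np.ndarray, cutoff: int = 127) -> np.ndarray:
    """Map every pixel strictly above ``cutoff`` to 255, the rest to 0.

    Idempotent on already-binary masks (0 stays 0, 255 stays 255 for any
    cutoff in [0, 254]).
    """
    if not 0 <= int(cutoff) <= 254:
        raise ValueError(f"cutoff must be in [0, 254], got {cutoff}")
    img = validate_gray(img)
    return np.where(img > cutoff, PLANT, 0).astype(np.uint8)


def despeckle(mask: np.ndarray, kernel: int) -> np.ndarray:
    """Median-filter a binary mask over a kernel x kernel neighborhood.

    Edges are handled by reflection so that plant tissue touching the
    sheet border is not spuriously eroded.  The result is re-binarized at
    127, so the output is always a valid binary mask; isolated specks
    smaller than the neighborhood majority disappear.
    """
    mask = validate_mask(mask)
    kernel = int(kernel)
    if kernel % 2 == 0 or kernel < 3:
        raise ValueError(f"kernel must be an odd integer >= 3, got {kernel}")
    if kernel > min(mask.shape):
        raise ValueError(f"kernel {kernel} exceeds the smaller mask dimension {min(mask.shape)}")
    filtered = ndimage.median_filter(mask, size=kernel, mode="reflect")
    return rebinarize(filtered, 127)


def blur_sweep(mask: np.ndarray, kernel_sizes: Sequence[int] = DEFAULT_KERNELS) -> BlurSweep:
    """Despeckle with each kernel size; no automatic 'best' selection."""
    sizes = tuple(int(k) for k in kernel_sizes)
    if not sizes:
        raise ValueError("kernel_sizes must not be empty")
    candidates = tuple(despeckle(mask, k) for k in sizes)
    return BlurSweep(kernel_sizes=sizes, candidates=candidates)
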