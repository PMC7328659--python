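"""Automatic preliminary mask generation with Otsu's method.

Given a grayscale sheet photograph, Otsu's method picks the threshold on
the 256-bin intensity histogram that maximizes the between-class variance

    sigma_b^2(t) = w0(t) * w1(t) * (mu0(t) - mu1(t))^2

where class 0 holds the pixels with value <= t and class 1 the rest; this
is equivalent to minimizing the weighted intraclass variance.  On a
herbarium sheet the plant tissue is dark against an off-white mounting
sheet, so the below-threshold (dark) class is the plant: the *foreground*
mask paints those pixels white (255), and the *background* mask is its
pixelwise complement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import PLANT, to_grayscale, validate_gray, validate_rgb


@dataclass(frozen=True)
class GrayHistogram:
    """Exact 256-bin intensity histogram of a grayscale image."""

    counts: np.ndarray  # shape (256,), non-negative integers
    total: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (256,):
            raise ValueError(f"histogram needs exactly 256 bins, got shape {counts.shape}")
        if (counts < 0).any():
            raise ValueError("histogram counts must be non-negative")
        if int(counts.sum()) != self.total:
            raise ValueError("histogram total does not match the sum of counts")
        object.__setattr__(self, "counts", counts)


@dataclass(frozen=True)
class OtsuResult:
    """Selected threshold with its between-class variance.

    ``degenerate`` is set when the histogram has a single nonzero bin
    (e.g. an empty sheet); the threshold is then that bin's value and the
    variance is zero.  Degenerate inputs do not raise so that batch runs
    over curated-but-imperfect collections keep going.
    """

    threshold: int
    between_class_variance: float
    degenerate: bool


@dataclass(frozen=True)
class MaskPair:
    """Complementary foreground/background binary masks.

    The foreground holds the dark (below-threshold) class as white
    pixels — the plant on a light mounting sheet; the background image is
    its exact pixelwise inverse.
    """

    foreground: np.ndarray
    background: np.ndarray


def histogram(img: np.ndarray) -> GrayHistogram:
    """Exact integer intensity histogram of a grayscale image."""
    img = validate_gray(img)
    counts = np.bincount(img.ravel(), minlength=256).astype(np.int64)
    return GrayHistogram(counts=counts, total=int(img.size))


def otsu_threshold(hist: GrayHistogram) -> OtsuResult:
    """Threshold maximizing between-class variance; ties break low.

    Computed in one pass from cumulative moments.  For every candidate
    ``t`` in [0, 255], class 0 is ``value <= t`` and class 1 is
    ``value > t``; thresholds whose classes are empty score zero.
    """
    if hist.total < 1:
        raise ValueError("cannot threshold an empty histogram (total = 0)")
    counts = hist.counts
    nonzero = np.flatnonzero(counts)
    if nonzero.size == 1:
        return OtsuResult(threshold=int(nonzero[0]), between_class_variance=0.0, degenerate=True)

    p = counts.astype(np.float64) / hist.total
    values = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(p)                      # P(value <= t)
    m0 = np.cumsum(p * values)             # first moment of class 0
    mu = m0[-1]                            # global mean
    w1 = 1.0 - w0
    # sigma_b^2 = (mu*w0 - m0)^2 / (w0*w1); guard empty classes.
    num = (mu * w0 - m0) ** 2
    den = w0 * w1
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = np.where(den > 0, num / den, 0.0)
    t = int(np.argmax(sigma_b))            # argmax returns the lowest tie
    return OtsuResult(threshold=t, between_class_variance=float(sigma_b[t]), degenerate=False)


def threshold_to_pair(img: np.ndarray, t: int) -> MaskPair:
    """Binarize at ``t``: foreground white where ``pixel <= t``."""
    img = validate_gray(img)
    if not 0 <= int(t) <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {t}")
    fg = np.where(img <= t, PLANT, 0).astype(np.uint8)
    bg = (PLANT - fg).astype(np.uint8)
    return MaskPair(foreground=fg, background=bg)


def auto_mask(img: np.ndarray) -> tuple[MaskPair, OtsuResult]:
    """Full automatic pass: grayscale, Otsu threshold, mask pair."""
    img = validate_rgb(img)
    gray = to_grayscale(img)
    result = otsu_threshold(histogram(gray))
    return threshold_to_pair(gray, result.threshold), result
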