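"""Segmentation metrics and per-family evaluation reports.

The headline metric is the Sørensen–Dice coefficient over foreground
pixel sets, ``2 |A ∩ B| / (|A| + |B|)``; pixel accuracy (fraction of
pixels with identical labels) is reported alongside because the two only
agree when the classes are balanced — on plant-sparse sheets they can
differ noticeably, so both are computed for every image.

Scoring happens at model resolution: the ground-truth mask passes through
the same center-crop / resize geometry as the prediction, so each image
contributes exactly ``size^2`` pixel predictions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging import read_image, read_mask, validate_mask


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Sørensen–Dice coefficient over foreground pixels, in [0, 1].

    Defined as 1.0 when both masks are empty: a correctly empty
    prediction is not penalized.
    """
    pred = validate_mask(pred)
    truth = validate_mask(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"mask dimensions differ: {pred.shape} vs {truth.shape}")
    a = pred != 0
    b = truth != 0
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def pixel_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of pixels whose labels agree."""
    pred = validate_mask(pred)
    truth = validate_mask(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"mask dimensions differ: {pred.shape} vs {truth.shape}")
    return float(np.mean(pred == truth))


def count_pixel_predictions(n_images: int, size: int) -> int:
    """Total per-pixel predictions for ``n_images`` masks of ``size x size``."""
    if n_images < 0:
        raise ValueError("n_images must be >= 0")
    return int(n_images) * int(size) ** 2


@dataclass(frozen=True)
class EvalReport:
    """Per-image scores, per-family means, and the overall summary."""

    per_image: pd.DataFrame   # catalog_number, family, dice, pixel_accuracy
    per_family: pd.DataFrame  # family, n_images, mean_dice, mean_pixel_accuracy
    overall: dict[str, float]
    errors: tuple[str, ...] = ()


def summarize(per_image: pd.DataFrame, size: int) -> EvalReport:
    """Aggregate per-image scores into the per-family and overall sections.

    Per-family means are unweighted over that family's images; the overall
    mean is the unweighted mean over all images.
    """
    if per_image.empty:
        raise ValueError("no images were scored")
    grouped = (per_image.groupby("family", sort=True)
               .agg(n_images=("dice", "size"), mean_dice=("dice", "mean"),
                    mean_pixel_accuracy=("pixel_accuracy", "mean"))
               .reset_index())
    n = len(per_image)
    overall = {
        "n_images": float(n),
        "mean_dice": float(per_image["dice"].mean()),
        "mean_pixel_accuracy": float(per_image["pixel_accuracy"].mean()),
        "total_pixel_predictions": float(count_pixel_predictions(n, size)),
    }
    return EvalReport(per_image=per_image.reset_index(drop=True),
                      per_family=grouped, overall=overall)


def evaluate_model(model, manifest: pd.DataFrame | str | os.PathLike,
                   base_dir: str | os.PathLike | None = None) -> EvalReport:
    """Score a trained model against every record of a manifest.

    ``manifest`` needs columns ``catalog_number, family, image, mask``
    (the dialect the synthetic generator writes); relative paths resolve
    against ``base_dir`` (default: the manifest's directory, or cwd).
    Rows whose files cannot be read are collected into ``report.errors``
    and the run continues.
    """
    from .segnet.model import predict_mask
    from .segnet.data import prepare_mask

    if not isinstance(manifest, pd.DataFrame):
        path = os.fspath(manifest)
        if base_dir is None:
            base_dir = os.path.dirname(path)
        manifest = pd.read_csv(path)
    if manifest.empty:
        raise ValueError("manifest has no records")
    base_dir = os.fspath(base_dir) if base_dir else "."

    size = model.cfg.image_size
    rows, errors = [], []
    for rec in manifest.itertuples(index=False):
        try:
            img = read_image(os.path.join(base_dir, rec.image))
            truth = read_mask(os.path.join(base_dir, rec.mask))
            pred = predict_mask(model, img)
            truth_s = prepare_mask(truth, size)
            rows.append({
                "catalog_number": rec.catalog_number,
                "family": rec.family,
                "dice": dice(pred, truth_s),
                "pixel_accuracy": pixel_accuracy(pred, truth_s),
            })
        except (OSError, ValueError) as exc:
            errors.append(f"{rec.catalog_number}: {exc}")
    if not rows:
        raise ValueError(f"no manifest row could be scored; first error: {errors[0]}")
    report = summarize(pd.DataFrame(rows), size)
    return EvalReport(per_image=report.per_image, per_family=report.per_family,
                      overall=report.overall, errors=tuple(errors))


def write_report(report: EvalReport, stem: str | os.PathLike) -> list[str]:
    """Write ``<stem>_per_image.csv``, ``<stem>_per_family.csv`` and
    ``<stem>_overall.csv``; returns the paths."""
    stem = os.fspath(stem)
    paths = [f"{stem}_per_image.csv", f"{stem}_per_family.csv", f"{stem}_overall.csv"]
    report.per_image.to_csv(paths[0], index=False)
    report.per_family.to_csv(paths[1], index=False)
    pd.DataFrame([report.overall]).to_csv(paths[2], index=False)
    return paths


def format_report(report: EvalReport) -> str:
    """Human-readable per-family table plus the overall line."""
    lines = ["Family                         n    Dice   PixelAcc"]
    for rec in report.per_family.itertuples(index=False):
        lines.append(f"{rec.family:<28} {rec.n_images:>4}   {rec.mean_dice:.3f}   "
                     f"{rec.mean_pixel_accuracy:.3f}")
    o = report.overall
    lines.append(f"overall: n={int(o['n_images'])}  mean Dice={o['mean_dice']:.3f}  "
                 f"mean pixel accuracy={o['mean_pixel_accuracy']:.3f}  "
                 f"pixel predictions={int(o['total_pixel_predictions'])}")
    return "\n".join(lines)
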