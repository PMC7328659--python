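"""Seeded generator of synthetic digitized herbarium sheets.

Real herbarium sheet photographs mix the biologically relevant signal (a
pressed, dried plant — here a fern-like silhouette with complex, finely
divided margins) with systematic visual noise: an institutional label,
a color calibration bar, a ruler, a barcode, stamp marks, and accumulated
debris on an aging, slightly yellowed mounting sheet.  This module draws
such scenes procedurally with a pixel-perfect ground-truth mask, so the
whole pipeline (thresholding, post-processing, network training and
evaluation) is testable end to end without downloading any collection.

Design points that matter downstream:

* The plant is dark (greens/browns) and the sheet is off-white, with a
  guaranteed luma gap between them, so Otsu thresholding is well posed on
  clean scenes by construction.
* The truth raster is captured from the plant painting step only.  Opaque
  sheet furniture (label, bar, ruler, barcode, stamp) is drawn in reserved
  margins and additionally clears any truth beneath it, so element pixels
  are never labelled plant.  Debris is painted *after* truth capture and
  only off-plant: it pollutes the image but never the truth — exactly the
  disparity the despeckle step exists to remove.
* Taxonomy is an in-code fake (invented families/genera/species), so the
  per-family evaluation report can be exercised without implying real data.

Default geometry is a 910 x 680 sheet — one tenth of a typical digitized
sheet on each side, preserving the portrait aspect ratio so that the
square-crop path of the training pipeline is exercised.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .imaging import PLANT, _LUMA_WEIGHTS, write_image, write_mask

# Invented taxonomy: 8 fake "fern" families with genera and epithets.
# Names are deliberately fictitious so synthetic manifests cannot be
# mistaken for records of real specimens.
FAKE_TAXA: dict[str, dict[str, tuple[str, ...]]] = {
    "Spiralopteridaceae": {"Spiralopteris": ("helicoides", "nana"), "Gyrophyllum": ("tortile",)},
    "Umbraphyllaceae": {"Umbraphyllum": ("tenebrosum", "latum"), "Nyctopteris": ("vulgaris",)},
    "Velutifrondaceae": {"Velutifrons": ("mollis", "aspera")},
    "Chartopteridaceae": {"Chartopteris": ("fragilis",), "Papyrella": ("plana", "minor")},
    "Crenulariaceae": {"Crenularia": ("dentata", "serrulata")},
    "Aeripinnaceae": {"Aeripinna": ("levis", "pendula"), "Zephyrofrons": ("volans",)},
    "Limbofoliaceae": {"Limbofolium": ("angustum", "robustum")},
    "Pseudonervataceae": {"Pseudonervia": ("reticulata",), "Falsinervus": ("simplex", "duplex")},
}


@dataclass(frozen=True)
class SheetConfig:
    """Parameters of one synthetic sheet.

    ``plant_color_low/high`` bound the per-frond RGB base color; together
    with ``sheet_color`` and ``sheet_noise`` they must keep plant and sheet
    separated by at least ``luma_margin`` gray levels, which guarantees
    that clean scenes are Otsu-separable.
    """

    height: int = 910
    width: int = 680
    sheet_color: tuple[int, int, int] = (245, 242, 228)
    sheet_noise: float = 4.0          # std-dev of per-pixel gaussian paper texture
    yellowing: float = 0.15           # 0-1 strength of a vertical aging tint
    plant_color_low: tuple[int, int, int] = (30, 52, 20)
    plant_color_high: tuple[int, int, int] = (92, 112, 62)
    luma_margin: float = 40.0         # required sheet-minus-plant luma gap
    frond_count: int = 3
    pinna_pairs: int = 14
    branch_depth: int = 2             # >= 2 adds second-order pinnules
    label: bool = True
    color_bar: bool = True
    ruler: bool = True
    barcode: bool = True
    stamp: bool = True
    debris: bool = True
    debris_density: float = 250.0     # specks per megapixel
    seed: int = 0

    def validate(self) -> "SheetConfig":
        if self.height < 64 or self.width < 64:
            raise ValueError("sheet dimensions must be at least 64 x 64")
        plant_max_luma = float(np.dot(self.plant_color_high, _LUMA_WEIGHTS))
        # worst-case sheet darkening: yellowing tint plus 3 sigma of texture noise
        sheet_min_luma = (
            float(np.dot(self.sheet_color, _LUMA_WEIGHTS))
            - 40.0 * self.yellowing
            - 3.0 * self.sheet_noise
        )
        gap = sheet_min_luma - plant_max_luma
        if gap < self.luma_margin:
            raise ValueError(
                f"plant/sheet luma gap {gap:.1f} below required margin {self.luma_margin:.1f}; "
                "adjust plant or sheet colors"
            )
        return self

    def without_elements(self) -> "SheetConfig":
        """Copy with all non-plant elements and debris disabled."""
        return replace(self, label=False, color_bar=False, ruler=False,
                       barcode=False, stamp=False, debris=False)


@dataclass(frozen=True)
class SyntheticSpecimen:
    """One generated sheet: photograph, ground truth, metadata.

    ``elements`` is the boolean map of pixels painted by sheet furniture
    and debris; it is disjoint from the truth by construction.
    """

    image: np.ndarray            # (H, W, 3) uint8
    truth: np.ndarray            # (H, W) uint8 binary, 255 = plant
    record: dict[str, str]
    elements: np.ndarray = field(repr=False, default=None)  # (H, W) bool


# ---------------------------------------------------------------------------
# low-level painters

_DISK_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _disk_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    if radius not in _DISK_CACHE:
        r = np.arange(-radius, radius + 1)
        dy, dx = np.meshgrid(r, r, indexing="ij")
        keep = dy * dy + dx * dx <= radius * radius + radius * 0.25
        _DISK_CACHE[radius] = (dy[keep], dx[keep])
    return _DISK_CACHE[radius]


def _stamp_segment(canvas: np.ndarray, p0: np.ndarray, p1: np.ndarray,
                   w0: float, w1: float, bounds: tuple[int, int, int, int]) -> None:
    """Paint a tapered thick segment as a run of disks, clipped to bounds."""
    length = float(np.hypot(*(p1 - p0)))
    n = max(int(length), 1)
    ts = np.linspace(0.0, 1.0, n + 1)
    r0, r1, c0, c1 = bounds
    for t in ts:
        center = p0 + t * (p1 - p0)
        radius = max(int(round(w0 + t * (w1 - w0))), 0)
        dy, dx = _disk_offsets(radius)
        yy = np.rint(center[0] + dy).astype(np.intp)
        xx = np.rint(center[1] + dx).astype(np.intp)
        keep = (yy >= r0) & (yy < r1) & (xx >= c0) & (xx < c1)
        canvas[yy[keep], xx[keep]] = True


def _draw_frond(canvas: np.ndarray, rng: np.random.Generator,
                bounds: tuple[int, int, int, int], cfg: SheetConfig) -> None:
    """One fern-like frond: a stipe carrying a solid lanceolate blade with
    a deeply serrated (pinnate) margin, plus thin pinna tips protruding
    past the blade edge when ``branch_depth >= 2``.

    Pressed fronds photographed at sheet scale read as broad blades with
    complex margins rather than isolated hairlines, so the blade is filled
    as a polygon; its serration frequency follows ``pinna_pairs``.
    """
    from skimage.draw import polygon as draw_polygon

    r0, r1, c0, c1 = bounds
    region_h = r1 - r0
    base = np.array([
        rng.uniform(r0 + 0.55 * region_h, r1 - 4),
        rng.uniform(c0 + 0.2 * (c1 - c0), c1 - 0.2 * (c1 - c0)),
    ])
    angle = np.deg2rad(rng.uniform(-30.0, 30.0))          # from vertical, tip upward
    length = rng.uniform(0.50, 0.75) * region_h
    bend = rng.uniform(-0.22, 0.22)                       # quadratic curvature

    # curved rachis centerline, finely sampled so the serration is smooth
    n_pts = 120
    ss = np.linspace(0.0, 1.0, n_pts)
    direction = np.array([-np.cos(angle), np.sin(angle)])
    normal = np.array([-direction[1], direction[0]])
    pts = base + np.outer(ss * length, direction) + np.outer(bend * length * ss**2, normal)
    # local normals follow the curvature
    tangents = direction + 2.0 * bend * np.outer(ss, normal)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)

    # stipe below the blade
    stipe_w = rng.uniform(0.004, 0.006) * cfg.height
    stipe_len = rng.uniform(0.10, 0.18) * length
    _stamp_segment(canvas, base + stipe_len * np.array([np.cos(angle), -np.sin(angle)]),
                   base, stipe_w, stipe_w, bounds)

    # lanceolate half-width profile with deep sinusoidal serration;
    # phase differs per side so left/right notches alternate
    hw_max = rng.uniform(0.09, 0.14) * length
    profile = np.sin(np.pi * np.clip(ss * 1.08, 0.0, 1.0)) ** 0.8
    freq = max(int(cfg.pinna_pairs), 1)
    depth = rng.uniform(0.30, 0.45)
    sides = []
    for sign, phase in ((1.0, rng.uniform(0, 2 * np.pi)), (-1.0, rng.uniform(0, 2 * np.pi))):
        serr = 1.0 + depth * np.sin(2 * np.pi * freq * ss + phase)
        hw = np.maximum(hw_max * profile * serr, 0.0)
        sides.append(pts + sign * hw[:, None] * normals)
    boundary = np.vstack([sides[0], sides[1][::-1]])
    rr, cc = draw_polygon(boundary[:, 0], boundary[:, 1], shape=canvas.shape)
    keep = (rr >= r0) & (rr < r1) & (cc >= c0) & (cc < c1)
    canvas[rr[keep], cc[keep]] = True

    if cfg.branch_depth >= 2:
        # thin pinna tips protruding past the blade margin
        tip_w = rng.uniform(0.0022, 0.0032) * cfg.height
        for k in range(cfg.pinna_pairs):
            for sign in (1.0, -1.0):
                s = 0.1 + 0.8 * (k + rng.uniform(0.0, 0.6)) / cfg.pinna_pairs
                i = min(int(s * (n_pts - 1)), n_pts - 1)
                hw_here = hw_max * profile[i]
                origin = pts[i] + sign * 0.7 * hw_here * normals[i]
                pdir = sign * normals[i] + rng.uniform(-0.3, 0.3) * tangents[i]
                pdir /= np.linalg.norm(pdir)
                plen = rng.uniform(0.4, 0.8) * hw_here
                _stamp_segment(canvas, origin, origin + plen * pdir,
                               tip_w, 0.4 * tip_w, bounds)


def _paint_rect(img: np.ndarray, emap: np.ndarray, r0: int, r1: int, c0: int, c1: int,
                color: tuple[int, int, int]) -> None:
    img[r0:r1, c0:c1] = color
    emap[r0:r1, c0:c1] = True


def _draw_label(img, emap, rng, H, W):
    h = int(rng.uniform(0.10, 0.14) * H)
    w = int(rng.uniform(0.24, 0.30) * W)
    r1, c1 = H - int(0.02 * H), W - int(0.02 * W)
    r0, c0 = r1 - h, c1 - w
    _paint_rect(img, emap, r0, r1, c0, c1, (252, 250, 242))
    img[r0:r0 + 2, c0:c1] = img[r1 - 2:r1, c0:c1] = (40, 40, 45)
    img[r0:r1, c0:c0 + 2] = img[r0:r1, c1 - 2:c1] = (40, 40, 45)
    # fake text lines
    y = r0 + int(0.22 * h)
    while y < r1 - 4:
        line_w = int(rng.uniform(0.5, 0.9) * (w - 12))
        img[y:y + 2, c0 + 6:c0 + 6 + line_w] = (30, 30, 35)
        y += max(int(0.16 * h), 4)


def _draw_color_bar(img, emap, rng, H, W):
    sw = max(int(0.03 * W), 8)                      # swatch size
    n = 6
    r0 = int(rng.uniform(0.05, 0.35) * H)
    c0 = W - sw - int(0.015 * W)
    colors = [(230, 40, 40), (40, 180, 60), (50, 70, 220), (235, 220, 40),
              (30, 30, 30), (250, 250, 250)]
    for i in range(n):
        _paint_rect(img, emap, r0 + i * sw, r0 + (i + 1) * sw, c0, c0 + sw, colors[i])


def _draw_ruler(img, emap, rng, H, W):
    w = max(int(0.022 * W), 7)
    c0 = int(0.008 * W)
    _paint_rect(img, emap, int(0.05 * H), int(0.95 * H), c0, c0 + w, (210, 208, 200))
    step = max(int(0.012 * H), 4)
    for i, y in enumerate(range(int(0.05 * H), int(0.95 * H), step)):
        tick = w if i % 5 == 0 else w // 2
        img[y, c0:c0 + tick] = (25, 25, 25)


def _draw_barcode(img, emap, rng, H, W):
    h = int(0.045 * H)
    w = int(0.18 * W)
    r0 = int(0.015 * H)
    c0 = W - w - int(0.03 * W)
    _paint_rect(img, emap, r0, r0 + h, c0, c0 + w, (250, 250, 250))
    x = c0 + 3
    while x < c0 + w - 3:
        bw = int(rng.integers(1, 4))
        if rng.random() < 0.55:
            img[r0 + 2:r0 + h - 2, x:x + bw] = (10, 10, 10)
        x += bw + int(rng.integers(1, 3))


def _draw_stamp(img, emap, rng, H, W):
    radius = int(rng.uniform(0.03, 0.045) * H)
    cy = int(rng.uniform(0.88, 0.94) * H)
    cx = int(rng.uniform(0.06, 0.14) * W)
    yy, xx = np.mgrid[cy - radius:cy + radius + 1, cx - radius:cx + radius + 1]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    ring = (d2 <= radius**2) & (d2 >= (radius - 2) ** 2)
    inner = np.abs(yy - cy) <= 1
    inner &= d2 <= (radius - 5) ** 2
    sel = ring | inner
    keep = (yy >= 0) & (yy < H) & (xx >= 0) & (xx < W) & sel
    img[yy[keep], xx[keep]] = (168, 40, 48)
    emap[yy[keep], xx[keep]] = True


# ---------------------------------------------------------------------------
# public API

def generate_sheet(cfg: SheetConfig) -> SyntheticSpecimen:
    """Generate one synthetic sheet; bit-identical for a fixed seed."""
    cfg = cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.height, cfg.width

    # aging mounting sheet: base color, paper-texture noise, vertical yellow tint
    img = np.empty((H, W, 3), dtype=np.float64)
    img[:] = cfg.sheet_color
    grad = np.linspace(0.0, 1.0, H)[:, None]
    img[..., 2] -= 40.0 * cfg.yellowing * grad            # blue drops -> yellow cast
    img[..., 0] -= 10.0 * cfg.yellowing * grad
    img += rng.normal(0.0, cfg.sheet_noise, size=(H, W, 3))

    # plant silhouette, constrained to leave margins free for sheet furniture
    bounds = (int(0.04 * H), int(0.84 * H), int(0.07 * W), int(0.78 * W))
    plant = np.zeros((H, W), dtype=bool)
    low = np.asarray(cfg.plant_color_low, dtype=np.float64)
    high = np.asarray(cfg.plant_color_high, dtype=np.float64)
    for _ in range(cfg.frond_count):
        frond = np.zeros((H, W), dtype=bool)
        _draw_frond(frond, rng, bounds, cfg)
        base_color = low + rng.random(3) * (high - low)
        jitter = rng.normal(0.0, 5.0, size=(int(frond.sum()), 3))
        img[frond] = base_color + jitter
        plant |= frond

    emap = np.zeros((H, W), dtype=bool)
    if cfg.ruler:
        _draw_ruler(img, emap, rng, H, W)
    if cfg.color_bar:
        _draw_color_bar(img, emap, rng, H, W)
    if cfg.barcode:
        _draw_barcode(img, emap, rng, H, W)
    if cfg.label:
        _draw_label(img, emap, rng, H, W)
    if cfg.stamp:
        _draw_stamp(img, emap, rng, H, W)

    # ground truth: plant pixels not covered by opaque sheet furniture
    truth_bool = plant & ~emap

    if cfg.debris:
        n_specks = rng.poisson(cfg.debris_density * H * W / 1e6)
        ys = rng.integers(0, H, size=n_specks)
        xs = rng.integers(0, W, size=n_specks)
        radii = rng.integers(0, 2, size=n_specks)         # 1-px dots and small blots
        shade = rng.uniform(35.0, 90.0, size=n_specks)
        for y, x, r, s in zip(ys, xs, radii, shade):
            dy, dx = _disk_offsets(int(r))
            yy = np.clip(y + dy, 0, H - 1)
            xx = np.clip(x + dx, 0, W - 1)
            keep = ~truth_bool[yy, xx]                    # debris never on plant
            img[yy[keep], xx[keep]] = (s, s * 0.92, s * 0.8)
            emap[yy[keep], xx[keep]] = True

    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    truth = np.where(truth_bool, PLANT, 0).astype(np.uint8)

    family = str(rng.choice(sorted(FAKE_TAXA)))
    genus = str(rng.choice(sorted(FAKE_TAXA[family])))
    species = str(rng.choice(sorted(FAKE_TAXA[family][genus])))
    record = {
        "catalog_number": f"SYN{cfg.seed % 10**8:08d}",
        "family": family,
        "genus": genus,
        "species": species,
    }
    return SyntheticSpecimen(image=image, truth=truth, record=record, elements=emap)


def generate_dataset(n: int, cfg: SheetConfig, out_dir: str | os.PathLike) -> pd.DataFrame:
    """Write ``n`` sheets (image + truth PNGs) plus a manifest CSV.

    Per-item seeds derive from ``cfg.seed + index`` so any item can be
    regenerated in isolation.  The manifest has columns
    ``catalog_number,family,genus,species,image,mask`` with paths relative
    to ``out_dir``; two runs with the same config produce identical trees.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i in range(n):
        spec = generate_sheet(replace(cfg, seed=cfg.seed + i))
        catalog = f"SYN{(cfg.seed + i) % 10**8:08d}"
        image_name = f"{catalog}_image.png"
        mask_name = f"{catalog}_mask.png"
        write_image(spec.image, os.path.join(out_dir, image_name))
        write_mask(spec.truth, os.path.join(out_dir, mask_name))
        rows.append({
            "catalog_number": catalog,
            "family": spec.record["family"],
            "genus": spec.record["genus"],
            "species": spec.record["species"],
            "image": image_name,
            "mask": mask_name,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
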