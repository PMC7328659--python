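# Methods

This note documents the models and procedures implemented in `fernmask`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic test bed does and does not show.

## Automatic thresholding

Otsu's method selects the threshold `t ∈ [0, 255]` on the 256-bin
intensity histogram that maximizes the between-class variance
`σ_b²(t) = ω₀(t) ω₁(t) (μ₀(t) − μ₁(t))²`, with class 0 = pixels ≤ t and
class 1 = pixels > t; this is equivalent to minimizing the weighted
intraclass variance. The implementation uses one pass of cumulative
moments; its contract is exact agreement with the brute-force scan over
all 256 candidates, which the test suite enforces on seeded random
images. Ties are broken toward the lowest maximizing threshold
(deterministic, and the common library convention). Single-valued
histograms (blank sheets) do not raise: they return the bin value with a
`degenerate` flag so batch runs survive imperfectly curated folders.

Grayscale conversion uses ITU-R BT.601 luma (0.299 R + 0.587 G +
0.114 B), the default dialect of the classic imaging libraries; the
choice only shifts the histogram slightly and Otsu adapts per image.
Because fern tissue is darker than the mounting sheet, the *below*-
threshold class is painted white into the foreground mask (white =
plant, repo-wide), and the background mask is its exact complement.
Thresholding runs at full input resolution.

## Mask post-processing

Edited masks re-enter the pipeline through `rebinarize` (pixel > cutoff
→ 255, default cutoff 127), which restores strict {0, 255} binarity
after brush tools leave intermediate grays, and is idempotent.

"Despeckling" is realized as a median filter over a `k × k`
neighborhood followed by re-binarization. A median was chosen over a
Gaussian blur deliberately: the goal is removing isolated debris specks
while *preserving* the frond margins that make the masks valuable, and a
rank filter keeps edges where a linear blur erodes them. Edges are
handled by reflection (edge-repeating), so tissue touching the sheet
border is not eroded. The neighborhood size trades speck removal against
loss of thin structures and depends on specimen condition, so
`blur_sweep` evaluates a small/medium/large set (default {5, 11, 21})
and writes *all* candidates; the final pick is explicitly a human
decision (`--pick` on the CLI, defaulting to the middle kernel).
Connected-component filtering and morphological pipelines are out of
scope by design.

## Synthetic sheets

The generator emulates the visual structure of a digitized herbarium
sheet at 1/10 scale (910 × 680 px default, preserving the portrait
aspect ratio so the square-crop path is exercised): an off-white,
slightly yellowed paper texture; one to several fern-like fronds —
a curved rachis carrying a solid lanceolate blade with a deeply
serrated, pinnate margin and protruding pinna tips — painted in dark
greens/browns; and optional sheet furniture (label box with fake text,
six-swatch color bar, ruler, barcode, stamp ring, debris specks).
Fronds are drawn as filled polygons rather than line art so the
silhouette survives the ~5× downscale to model resolution the way real
pressed blades do.

Contracts that the rest of the package builds on:

* **Separability.** Plant and sheet colors must differ by ≥ 40 luma
  levels (validated at config time, including worst-case yellowing and
  3σ paper noise), so clean scenes are Otsu-separable by construction.
* **Truth discipline.** The ground truth is captured from the plant
  painting step. Opaque furniture is drawn in reserved margins and
  clears any truth beneath it, so element pixels are never labelled
  plant; debris is painted *after* truth capture and only off-plant —
  it pollutes the image but never the truth, which is exactly the
  disparity the despeckle stage exists to remove.
* **Determinism.** One seed fixes everything; dataset items derive
  their seeds as `seed + index`, so any sheet can be regenerated alone.
* **Fake taxonomy.** Eight invented families with invented genera and
  epithets ship in code, so per-family reports can be exercised without
  implying real specimens.

What the generator does **not** emulate: photographic lighting gradients
and vignetting, real frond texture (venation, sori), translucent or
overlapping tissue, handwriting, mercuric-chloride staining, or
specimens stored in envelopes. Tests passing on synthetic scenes
therefore demonstrate the pipeline's mechanics and the network's
trainability, not field performance on any real collection.

## Segmentation network

The network is the classic U-Net layout: `encoder_depth` stages of
(two 3×3 conv + ReLU) followed by 2×2 max pooling, a two-conv
bottleneck, and a mirrored decoder of nearest-neighbor 2× upsampling,
skip concatenation at matching resolution, and two 3×3 conv + ReLU,
ending in a 1×1 conv that emits one logit per pixel. Channel widths
double per stage from `base_channels`. It is implemented directly on
numpy: convolutions are im2col GEMMs (so the heavy work lands in BLAS)
with hand-derived backward passes, verified in the test suite against
float64 finite differences at 1e-4 relative tolerance. There is no
framework dependency; training is practical at desk scale (seconds to
minutes for the configurations used in the tests).

The encoder is randomly initialized (seeded He normal). Loading
externally pretrained classification weights as an encoder is possible
through the checkpoint mechanism but is never required; the
architecture and training recipe, not any particular weight file, are
the reproducible content of the package.

**Data handling.** Rectangular inputs are center-cropped to a square on
the shorter side and resized to `image_size` (default 256): images
bilinearly with anti-aliasing, masks by nearest neighbor so they stay
strictly binary. Center is the least biased crop anchor. Prediction
applies the identical geometry, so predicted masks are always
`image_size × image_size` regardless of the input, and evaluation maps
the ground truth through the same geometry (each image contributes
exactly `size²` pixel decisions).

**Augmentation.** Per training sample, one geometric chain is drawn —
horizontal flip (p = 0.5), rotation up to ±10°, zoom up to 1.1×, and a
4-corner perspective warp, the latter three independently at p = 0.75 —
and applied *identically* to image and mask (mask path nearest-neighbor
plus re-binarization). The "warp ≤ 0.2" magnitude is realized as corner
displacements up to 0.1 of the side (i.e. ±warp_max/2), matching the
usual symmetric-warp parameterization of augmentation libraries. A
multiplicative lighting adjustment of up to ±0.2 (p = 0.75) touches the
image only; labels must not change when the lighting does. The test
suite checks pair alignment exactly (Dice 1 between the emitted mask
and the sampled chain re-applied to a mask copy).

**Optimization.** Mean per-pixel binary cross-entropy on sigmoid scores
(a soft-Dice loss is available via `loss="dice"`); Adam; one-cycle
learning rate — cosine warmup from `lr_max/25` to `lr_max` over the
first 30% of steps, cosine anneal to `lr_max/2.5e4` — with defaults
`lr_max = 1e-2`, `batch_size = 4`. The schedule's shape constants
follow the policy's common parameterization; `lr_max` was chosen as a
robust default for this architecture on the synthetic task. One root
seed drives split, initialization, and augmentation through derived
sub-streams, so runs are deterministic up to floating-point reduction
order.

## Evaluation

Sørensen–Dice is computed over foreground pixel sets; the both-empty
case is defined as 1.0 so a correctly empty prediction is not
penalized. Pixel accuracy is reported alongside because the two metrics
are sometimes conflated yet only agree when classes are balanced: on
plant-sparse sheets accuracy exceeds Dice by up to the shared-background
fraction (`accuracy − dice ≤ TN/N`, since `dice ≥ TP/N`), a bound the
test suite checks empirically. Per-family rows are unweighted means over
that family's images (grouping on the `family` column verbatim); the
overall mean is unweighted over images. Rows whose files cannot be read
are collected as errors without aborting the run.

## Scaled-down benchmark

The repository's quantitative benchmark (also recomputed by
`scripts/acceptance.py`) trains the depth-3 network with 8 base
channels at 128 × 128 on 160 synthetic sheets (default generator
configuration) for 10 epochs with the full augmentation recipe, and
scores the 40 held-out sheets. These sizes keep the whole run at a few
minutes on one CPU while leaving the data-handling, augmentation and
scheduling recipe intact. Under these conditions the mean held-out Dice
is ≈ 0.98 (pixel accuracy slightly higher), comfortably above the 0.95
level reported for full-scale herbarium training — as expected, since
the synthetic scenes are cleaner and more stereotyped than a real
collection. The nearest-neighbor mask resampling places an intrinsic
ceiling of ≈ 0.985–0.99 on achievable Dice at 128 × 128 (boundary
pixels are sampled, not averaged), so scores in that range indicate the
network has learned essentially everything the target exposes.

## Numerical and degenerate-input choices

* Masks are validated to {0, 255} at every module boundary; any
  interpolation that could produce grays is followed by re-binarization
  at 127 (`> cutoff` → 255).
* Mask files are always lossless PNG; 16-bit reads are rescaled by
  1/257 and rounded.
* Otsu on an empty histogram raises; on a single-bin histogram returns
  the flagged degenerate result.
* `split_dataset` rejects splits that would leave either partition
  empty; validation size is `round(n · val_fraction)`.
* Max-pool gradients route to the argmax (first element on ties);
  upsample gradients sum the 2×2 block.
* The one-cycle schedule is continuous with a single interior maximum;
  step 0, the warmup end, and the final step hit their nominal values
  exactly.

## Known limitations

* The network trains on CPU via BLAS matmuls; it is desk-scale by
  design and not suited to full-resolution collection-scale training.
* The synthetic task is easier than real herbarium segmentation (clean
  backgrounds, stereotyped silhouettes, perfect labels); scores here
  bound the mechanics, not real-world accuracy.
* Only binary (plant vs. everything) segmentation is supported; labels,
  color bars and rulers are not separate classes.
* Thin structures near one pixel at model resolution (fine stipes,
  hair-like pinna tips) are the dominant error source, mirroring the
  known failure mode of full-scale models on mostly-stem specimens.
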