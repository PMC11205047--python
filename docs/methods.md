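# Methods

## Problem setting

Given a top-down RGB photograph of a rosette plant, produce a label map in
which 0 is background and each positive integer is one leaf. Leaves
overlap, differ strongly in size within one plant, and sit on cluttered
soil-like backgrounds, which is why instance-level evaluation (Symmetric
Best Dice) rather than semantic Dice is the primary score.

## Evaluation measures

`metrics` implements the five challenge measures exactly as defined:
pairwise Dice, Best Dice (mean over the first map's instances of the best
Dice against any instance of the second), Symmetric Best Dice (the minimum
of both directions), foreground Dice, and the signed/absolute leaf-count
differences. Implementation notes:

* Best Dice is computed from a joint instance histogram, which is
  algebraically identical to the brute-force double loop over all instance
  pairs (the test suite checks exact equality against that oracle).
* **0/0 convention.** Two empty masks score Dice 1.0 (perfect agreement on
  absence); one empty and one non-empty mask score 0.0. The convention is
  monotone and bounded and keeps blank predictions scoreable.
* **Empty maps.** Best Dice of a map with no instances is 0.0, not an
  error, so dataset evaluation survives failed predictions.
* **Aggregation** is the unweighted arithmetic mean of per-image values; a
  pooled-pixel alternative was rejected because it cannot reproduce
  per-image signed counting errors.
* Reports default to percent with two decimals; fractional scale is kept
  internally and exposed behind a flag.

## Data plumbing

Label maps interchange as indexed/RGB PNGs (distinct non-background colour
= one instance, ids assigned in raster-scan first-appearance order) and as
flat HDF5 containers of 2-D integer datasets (lexicographic key order; the
container layout is deliberately permissive because packaged subsets vary).
Training labels interchange as one-line-per-object polygon annotations:
class id followed by alternating x y coordinates, normalised to [0, 1]
with pixel centres at (i + 0.5)/size, 6-decimal fixed point (lossless to
1e-6 by construction).

Mask→polygon conversion traces the outer iso-contour of each instance
(marching squares at level 0.5 on a padded mask) and simplifies it
Douglas–Peucker style with a 1.0 px default tolerance — compact lines with
sub-pixel fidelity at 512×512. Instances under 3 px are skipped (below
polygon representability) and multi-part instances export their largest
connected component only, since the line format cannot express parts; both
cases are logged. Rasterisation paints records in order, later records
overwriting earlier ones, matching the painter's order of the synthetic
generator. Round-trip fidelity is ≥ 0.95 Dice per convex instance of
radius ≥ 10 px at 512×512.

The train/validation split is deterministic: sort the file list
lexicographically (the order is otherwise undefined) and send every fourth
file to validation, giving the 3:1 ratio. Images resize bilinearly, label
maps nearest-neighbour (never inventing ids).

## Architecture

All variants are built from one declarative graph format (rows of
`[from, repeats, block, args]`, YAML files under `leafseg/configs/`), so the
variants differ only in data, not code.

* **C2f block**: 1×1 projection to 2c channels, split in half, n
  bottlenecks applied sequentially to one half with every intermediate
  retained, concatenation of the (2+n) branches, 1×1 projection. Depth
  multiplier scales n, width multiplier scales channels (rounded up to
  multiples of 8); scales n/s/m/l/x use (0.33, 0.25) … (1.33, 1.25).
* **Ghost module**: `intrinsic = ⌈out/s⌉` maps from a dense primary
  convolution (1×1 by default), the remaining ghost maps from a 5×5
  per-channel depthwise convolution of the intrinsic maps, concatenated
  and truncated to the requested width. Kernel parameter count is
  `k_p²·c_in·⌈out/s⌉ + (s−1)·⌈out/s⌉·k_cheap²`, strictly below the dense
  `k_p²·c_in·c_out` whenever `c_in·k_p² > k_cheap²` — true at every
  substitution site here. The ghost variant substitutes the single P4
  downsampling convolution of the backbone (configurable to widen).
* **BiFPN fusion**: transition nodes fuse the level input with the
  upsampled deeper input, output nodes fuse the level input (same-level
  skip), the transition feature and the downsampled shallower output, each
  as `Conv((Σ wᵢxᵢ)/(Σ wᵢ + ε))`. Raw weights are clamped at 0 before
  normalisation (the non-negativity mechanism is a design choice), each
  fusion node owns an independent weight set, and ε defaults to 1e-4 — the
  customary fast-normalised-fusion constant, exposed in config. Cross-scale
  resampling is nearest-neighbour 2× upsampling top-down, stride-2
  convolution bottom-up, with 1×1 lateral convolutions harmonising
  channels.
* **Head**: decoupled anchor-free branches per level (strides 8/16/32) —
  box edges as discrete distributions over 16 bins, one leaf-presence
  logit, 32 mask coefficients — plus a prototype stack at stride 4 off P3.
  Class-logit biases initialise at −4 so the early score prior is low.
* Every convolution carries batch normalisation (momentum 0.03, eps 1e-3)
  and SiLU unless a head's final 1×1 layer, which is a plain biased
  convolution.

The tensor backend is a package-local NumPy reverse-mode autograd
(`leafseg.autograd`): float32 throughout, convolution as im2col + BLAS
matmul with k² strided slice-adds for the input gradient, a depthwise fast
path for the ghost cheap transform. Every op's analytic gradient is
finite-difference checked in the test suite.

## Assignment and losses

Task-aligned assignment per image: alignment `t = score^0.5 · IoU^6`
restricted to anchor points strictly inside the instance box; each
instance takes its top-10 anchors by `t`; anchors claimed by several
instances go to the highest `t`. Target class scores are `t` rescaled per
instance to peak at that instance's best IoU. Loss components, normalised
by the summed target scores:

* classification: BCE of all anchor logits against the target scores
  (gain 0.5);
* box: `1 − CIoU` on DFL-expectation-decoded boxes, positives only,
  weighted by target score (gain 7.5);
* distribution focal loss: cross-entropy of each edge distribution against
  the two-bin interpolation of the true distance in grid units (gain 1.5);
* mask: BCE of the coefficient–prototype combination against the instance
  mask at prototype resolution, restricted to the instance box and
  normalised by box area (gain 1.0).

The α/β/top-k values and loss gains follow the conventions of the model
family this architecture belongs to (the components are standard; their
values are config-exposed). The CIoU aspect-ratio trade-off coefficient is
detached from the gradient, as usual.

Training is SGD (momentum 0.937, weight decay 5e-4 on kernels), linear
warmup over 3 epochs then linear decay to `lr0·lrf`, with global
gradient-norm clipping (default ceiling 10) — the task-aligned feedback
loop between scores and assignment can otherwise destabilise small-batch
runs. One integer seed
drives initialisation, shuffling and augmentation sampling. Mosaic is
disabled for the final `close_mosaic` epochs; validation SBD is tracked
and the best parameters are restored on return. Study-scale defaults are
250 epochs, batch 16, 512×512; desk-scale runs shrink these (below).

## Inference

Decode all anchors, drop scores below 0.25, class-agnostic NMS at IoU 0.7,
assemble masks as `sigmoid(coefficients · prototypes)`, upsample to image
resolution, crop to the box, binarise at 0.5. Instances paint in ascending
score order so the highest-score instance owns contested pixels — every
foreground pixel belongs to exactly one instance. Inference is
deterministic for a fixed model and input.

## Augmentation

HSV jitter (hue 0.015 of the wheel with wraparound, saturation 0.7 and
value 0.4 gain fractions), flips (p = 0.5 each axis), one random
similarity transform (±180°, ±0.1 translation, 0.5 scale gain), and
four-image mosaic on a double-size canvas with jittered junction.
Geometric ops transform the polygons analytically — masks are rasterised
once, after the chain — avoiding double resampling. Instances whose
clipped outline covers fewer than 3 px are dropped. Random erasing is
implemented (area fraction 0.02–0.2, aspect 0.3–3.3) but off by default:
it is a classification-training augmentation, and whether it was active
for segmentation training is not established; a config flag enables it.
The full stack is bit-reproducible under a fixed seed, and instance count
never increases.

## Synthetic rosettes

The generator emulates what matters to this pipeline: K ~ U[k_min, k_max]
teardrop leaves (ellipses tapered by a sine envelope) placed at
golden-angle increments with Gaussian angular jitter (σ = 12°), uniform
length 0.16–0.34 of the image edge, width 0.35–0.6 of length, bases
scattered σ = 0.03·size around the centre, drawn in a randomised painter's
order (so occlusion statistics are not biased by phyllotaxis order), green
HSV band hues over a textured soil-like or flat background, optional
Gaussian defocus blur (σ up to 1.2 px). Fully occluded leaves are removed
and ids compacted. Defaults (k 5–30, 512 px) mirror the leaf-count and
resolution ranges of the public rosette benchmarks.

Not modelled: venation, specular highlights, perspective foreshortening,
moss/tray clutter, inter-plant variation in leaf shape. Tests passing on
synthetic scenes therefore demonstrate pipeline correctness and
learnability of green-blob instance structure — not photographic-domain
performance.

## Desk-scale experiment sizes

The end-to-end checks train the nano-scale standard variant at 64×64 on
64 synthetic scenes (leaf count 4–8) for 120 epochs, batch 8, lr0 0.005,
mosaic off for the last 40 epochs, and evaluate 16 held-out scenes; the BiFPN and
ghost variants run the identical loop for 2 epochs as a smoke check.
These sizes are the package's chosen CPU-scale experiment: large enough
that a trained model clearly beats the all-background baseline
(foreground Dice well above 0.5 and positive SBD), small enough to rerun
routinely. Competition-scale results require the real challenge data,
long GPU training at the l scale, and the withheld test ground truth, and
are out of scope here.

## Known limitations

* The NumPy backend is single-threaded apart from BLAS; it is meant for
  CPU desk-scale experiments, not 512×512 × 250-epoch training.
* Batch-norm statistics at batch sizes ≤ 8 are noisy; the training loop
  accepts this rather than adding normalisation variants.
* Polygon export cannot represent holes or multi-part instances (largest
  part wins), so extreme occlusion that splits a leaf in two loses the
  smaller fragment in the txt interchange (the PNG/HDF5 path is exact).
* The mosaic canvas returns at twice the sample size and is resized by the
  caller, which slightly softens textures relative to crop-based
  implementations.
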