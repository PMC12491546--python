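# Methods

## The segmentation model

The network is a U-shaped encoder–decoder for single-lesion binary
segmentation of RGB dermoscopy images.  The encoder is a hybrid of a
convolutional patch-embedding stem (4x4 stride-4 convolution + layer norm)
and four windowed-attention stages in the Tiny configuration (depths
2/2/6/2, heads 3/6/12/24, MLP ratio 4, pre-norm residual blocks,
relative-position bias, shifted windows on every second block).  Skip
features are taken before each patch merging so their channel counts are
96/192/384/768 at 1/4 .. 1/32 resolution of the input.

The window size is 8 rather than the conventional 7 so that all four
pyramid resolutions of a 256x256 input (64, 32, 16, 8) partition without
padding.  Maps that are not larger than the window collapse to a single
global-attention window, and the shifted variant is skipped there (a
cyclic shift would wrap the entire map).  Non-divisible maps are padded
symmetrically with zeros before partitioning and cropped after the
inverse.

### Cross-attention skip refinement (CATM)

At each skip connection, a windowed-attention block processes the routing
source (the decoder feature by default), three linear layers project Q, K
and V, and window-local single-head attention `softmax(QK^T / sqrt(d_k)) V`
produces refined tokens that a fusion stage (channel concatenation, 1x1
convolution 2C->C, layer norm, GELU) merges with the skip feature.  The
alternative routings (K/V from the skip, Q from the skip, V from the
skip) exist as configuration for ablation experiments; perturbation tests
pin down that each tensor depends only on its declared source.

The subsequent spatial attention computes per-pixel channel-average and
channel-maximum maps plus a per-level C->1 linear projection of the
feature itself, concatenates the three single-channel maps, and applies a
3->1 1x1 convolution + sigmoid whose parameters are **shared across all
levels**.  Two design points deserve explanation:

* The published description calls the pooling "global", yet requires the
  attention map to be H x W.  Global pooling would collapse all spatial
  structure, so the pooling here runs across the channel axis — the
  standard construction for spatial attention maps.
* Sharing a convolution across levels with different channel counts is
  only well-defined after the per-level C->1 projection; the shared
  component is exactly the final 3->1 convolution + sigmoid (4
  parameters), verified by a parameter audit in the tests.

CATM is applied at all four skip levels, including the deepest (8x8)
skip, where it refines the bottleneck output against its own skip
feature.  Besides giving the "full-stage" parameter sharing a fourth
stage, this is where the published parameter budget (62.91 M at
15.45 GFLOPs) must live: every free width at 16x16 resolution or above
costs at least 256 FLOPs per parameter, so a configuration without
capacity at 8x8 cannot reach that budget under that FLOP ceiling.

### Adaptive fusion block (AFB)

Each decoder feature passes three parallel branches whose outputs are
concatenated (3C channels) and reduced by a 1x1 convolution:

* **Attention branch**, resolution-aware: at level 0 (64x64) the blocks
  of the first two Tiny stages (4 blocks), at level 1 (32x32) three
  stages (10 blocks), at level 2 (16x16) all four (12 blocks) with the
  internal embedding halved, and at level 3 (8x8) a plain 3x3 convolution
  — self-attention has nothing to resolve at that scale.  Blocks run at
  constant resolution (the three-way concatenation requires matched
  H x W), with 1x1 entry/exit projections between the level's channel
  count and the branch's internal width.
* **Deformable branch**: a zero-initialized 3x3 convolution predicts an
  18-channel offset field (per-tap row/column displacements); a 3x3
  deformable convolution samples at the displaced positions with bilinear
  interpolation and zero padding outside the map.  Zero initialization
  means the first forward pass equals a standard convolution — an oracle
  the tests exploit — and training starts from the regular grid.
* **Identity branch**: the unchanged input, preserving low-level detail.

### Decoder and head

From the bottleneck (after its AFB and deepest-skip CATM), each level
applies: bilinear 2x upsampling + 3x3 convolution halving channels
(+ layer norm + GELU), CATM against the skip, channel concatenation and
1x1 fusion, then the level's AFB.  Two further upsampling convolutions
(96 -> 24 -> 24 channels) restore full resolution and a 1x1 convolution +
sigmoid produces the probability map; masks are thresholded at 0.5.

### Parameter/FLOP budget and the free widths

The published architecture fixes the encoder and the pyramid widths but
not the AFB branch widths or the head taper; the published parameter
count (62.91 M) and cost (15.45 GFLOPs at 256x256, 1 MAC = 1 FLOP
counting convolutions, linear layers and attention matrix products) are
the only quantitative constraints.  The defaults

    afb_widths    = (40, 68, 184)   # branch base width at levels 0..2
    head_channels = (24, 24)

were calibrated once, analytically, to land on both numbers
simultaneously; `count_parameters` / `count_flops` recompute them from
the instantiated model at run time.  The FLOP convention counts every
matmul's multiply–accumulates (convolutions are im2col matmuls, attention
contributes QK^T and attention-times-V); normalization, softmax,
activations and interpolation are not counted.

## Loss and training

The loss is `BCE(p, y) + (1 - softIoU(p, y))` with
`softIoU = (sum(p y) + eps) / (sum p + sum y - sum(p y) + eps)`,
`eps = 1e-6`, weights 1:1.  BCE squeezes probabilities affinely into
`[eps, 1-eps]` rather than clipping: a hard clip has zero gradient in the
clipped region, and a saturated float32 sigmoid then freezes training
permanently.

The reference recipe is AdamW with learning rate and weight decay 1e-4,
batch 8, 200 epochs, 256x256 inputs, random flips (p = 0.5 each axis) and
random rotation (uniform ±30°, a configurable range), identical geometric
transforms on image (bilinear) and mask (nearest, re-binarized), and an
8:1:1 train/val/test split by seeded shuffle; five-fold splitting of the
training pool is available.  A constant learning rate is the default;
`warmup_steps` optionally ramps it linearly, which small-data/high-LR
experiments need (see below).  Gradients are clipped to global norm 1.
Training aborts with a diagnostic on a non-finite loss.  Additional
stabilizers: layer norm after every decoder/head upsampling convolution,
and an output convolution initialized near the foreground prior (tiny
weights, bias −1.1) so optimization does not start from an arbitrary
logit field.  Without the squeeze/norm/init measures, AdamW at the
learning rates needed to fit small data within 200 steps drives logits
past float32 sigmoid saturation and all gradients become exactly zero.

## Synthetic dermoscopy data

Real lesions are hard to segment because their edges are irregular and
their pigment fades toward the skin tone.  The generator reproduces
exactly these two properties with exact ground truth: a star-convex
boundary `r(theta) = r0 (1 + sum_{k=2..6} a_k sin(k theta + phi_k))` with
amplitudes scaled by `boundary_irregularity` (and damped as 1/k), radial
pigment interpolation from a dark center tone to the skin tone controlled
by `center_fade`, a small fixed skin-tone palette, Gaussian texture noise
(`noise_sd`, default 0.03), and optional dark hair strokes drawn as
quadratic curves (`hair_density`, default 3).  `r0` is set from a target
area fraction drawn uniformly from `lesion_area_fraction`
(default 0.05–0.4, the realistic range for dermoscopy crops), corrected
for the boundary perturbation's second moment, and resampled until the
rasterized area lands inside the range.  Sample `i` is a pure function of
`(seed, i)`, so datasets are bit-reproducible.

What the generator does **not** emulate: camera vignetting and specular
highlights, multi-lesion scenes, diagnostic class structure, and the
intensity statistics of any real archive.  Passing tests therefore
demonstrate that the architecture, optimization and metrics work as
specified — not that the model reaches any particular accuracy on real
dermoscopy archives, which requires the public datasets and long GPU
training and is out of scope here.

## Evaluation metrics

Confusion counts are pixel-wise between binary masks.  DSC, IoU,
sensitivity, specificity and accuracy follow their set definitions; the
identity `DSC = 2 IoU / (1 + IoU)` is enforced to 1e-12 in tests.
Degenerate inputs: empty-vs-empty DSC is defined as 1.0; any other metric
with an empty denominator yields NaN, is logged, and is excluded from
aggregation (with the exclusion count reported).  Boundaries are mask
pixels with at least one background 4-neighbor (the image border counts
as background); HD is the larger directed maximum and ASSD the mean of
the two directed average Euclidean boundary distances, in pixels.  AUC
pools pixels across the evaluation set into a single ROC curve.
Aggregation uses the population standard deviation; with `folds > 1` the
per-image list is chunked, averaged per fold, and mean ± std taken across
fold means.  Overlays color true positives yellow, misses red and false
positives green, alpha-composited on the image.

## Problem sizes in the test suite

CPU-scale experiments use a width-reduced model (`ModelConfig.reduced`,
embed 24, pyramid 24/48/96/192, all free widths scaled by the same
factor) at 64x64 inputs: the architecture is identical (all four stages,
all four levels, same window behavior by construction), only widths and
resolution shrink.  The overfit-recovery experiment fits 8 synthetic
images for 200 steps at learning rate 3e-3 with 20 warmup steps and
reaches train DSC ≥ 0.95 (typically ≈ 0.999 around step 70).  The
ablation lattice (five structural variants, four Q/K/V routings) runs one
forward+backward step each at the same reduced scale.  Model statistics
(parameters, FLOPs) are always computed on the full default
configuration.

## Known limitations

* The numpy autodiff runs on a single CPU; full-resolution training at
  the reference recipe's scale is impractical here — it exists for
  correctness, small-scale experiments and statistics, not throughput.
* Deformable convolution uses one deformable group and no modulation
  masks.
* The exact internal architectures the published description leaves open
  (CAF depth, AFB branch widths, head taper) are this package's choices,
  constrained by the published parameter/FLOP budget; other choices
  meeting the same budget are possible.
* Checkpoints store float32 weights + configuration in `.npz` form and
  are not portable to other implementations.
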