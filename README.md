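# scalefusionnet

Skin-lesion segmentation from dermoscopy images with a U-shaped
window-attention network whose skip connections are refined by
cross-attention and whose decoder fuses attention, deformable-convolution
and identity branches.

Melanoma screening relies on delineating lesions whose edges are irregular
and whose pigment fades gradually from the center into the surrounding
skin.  Plain U-shaped networks concatenate encoder and decoder features at
skip connections even though the two sit at very different semantic levels
(the "semantic gap"), and fixed-grid convolutions adapt poorly to jagged
boundaries.  This package implements a network that addresses both, along
with its compound loss, the full evaluation-metric stack, the structural
and Q/K/V ablation variants, and a synthetic dermoscopy generator so that
every component is trainable and testable on CPU without any external
dataset.

Because no deep-learning framework is assumed, the network runs on a small
numpy-based reverse-mode autodiff library included in the package
(`scalefusionnet.nn`): batched matmul autograd, im2col convolution,
windowed attention, bilinear sampling and AdamW.

## Model

The encoder is a hybrid conv-stem + windowed-attention hierarchy (Tiny
configuration: depths 2/2/6/2, heads 3/6/12/24, window 8).  A 256x256 RGB
input yields skip features at

    64x64x96,  32x32x192,  16x16x384,  8x8x768.

**CATM (cross-attention transformer module)** sits at every skip
connection.  With decoder feature `X_dec` and skip feature `X_skip`:

    Q, K, V  = proj(SwinBlock(X_dec))                 # routing configurable
    V'       = softmax(Q K^T / sqrt(d_k)) V           # window-local
    X'_skip  = CAF(V', X_skip)                        # concat + 1x1 + LN + GELU
    A        = sigmoid(Conv_1x1[shared]([proj(X'), avg_c(X'), max_c(X')]))
    X_CATM   = X'_skip * A

The final 3->1 convolution producing the spatial attention map `A` is a
single parameter set shared across all four levels ("SharedSA").

**AFB (adaptive fusion block)** processes each decoder feature through
three parallel branches — a resolution-aware stack of attention blocks
(fewer stages at high resolution, a plain 3x3 convolution at 8x8), a 3x3
deformable convolution whose offsets are predicted by a zero-initialized
3x3 convolution, and identity — concatenated and reduced by a 1x1
convolution.

Training minimizes `BCE(p, y) + (1 - softIoU(p, y))` with AdamW
(lr = weight decay = 1e-4 in the reference recipe).  Evaluation reports
DSC, IoU, sensitivity, specificity, accuracy, Hausdorff distance, average
symmetric surface distance and pixel-pooled ROC AUC, aggregated as
mean ± std per fold.

The default configuration has **62.91 M** trainable parameters and costs
**15.45 GFLOPs** (1 MAC = 1 FLOP) for one 256x256 forward pass — a 22.4 %
reduction against the 19.92 G of the strongest published competitor
(D-LKA) at matching accuracy class.

## Worked example

Generate a small synthetic dataset, fit a width-reduced model on CPU, and
evaluate it:

```
$ scalefusionnet generate data --n 20 --seed 7 --image-size 64
wrote 20 image/mask pairs to data

$ scalefusionnet train data --embed-dim 24 --input-size 64 \
      --steps 200 --epochs 200 --lr 3e-3 --warmup 20 --seed 0 --out ckpt.npz
trained 200 steps; train DSC 0.9806, val DSC 0.9887
checkpoint written to ckpt.npz

$ scalefusionnet evaluate ckpt.npz data --split test
  acc: 0.9910 +- 0.0002
 assd: 0.3184 +- 0.0056
  dsc: 0.9844 +- 0.0009
   hd: 1.2071 +- 0.2071
  iou: 0.9692 +- 0.0017
   se: 0.9765 +- 0.0034
   sp: 0.9971 +- 0.0018
  auc: 0.9997 +- 0.0000
```

The test-set Dice of 0.984 means predicted and true lesion masks overlap
almost perfectly on held-out synthetic images; HD ≈ 1.2 px says the worst
boundary deviation is about one pixel.  `scalefusionnet overlay` renders
the standard error map (yellow = correct lesion, red = missed, green =
false positive), and `scalefusionnet stats` prints the parameter/FLOP
budget of any configuration:

```
$ scalefusionnet stats
parameters: 62911736 (62.91 M)
FLOPs @ 256: 15.45 G (1 MAC = 1 FLOP)
```

Ablation variants (the structural method rows and the four Q/K/V routing
configurations) are built with `scalefusionnet ablate --method 2` /
`--routing q_dec_kv_skip`, or programmatically via
`scalefusionnet.pipeline.build_ablation`.

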