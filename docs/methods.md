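# Methods

## Problem and model

The package segments the tongue body (foreground class 1) from RGB
photographs. The network is an encoder–decoder with three parts: a
hierarchical mix-vision transformer encoder producing a stride-4/8/16/32
feature pyramid, a dilated feature-pyramid neck (DiFP), and a
multi-dilation prediction head (MDi). The design premise is that dilated
convolutions enlarge context — receptive field (k−1)·d+1 for kernel k and
rate d — without adding parameters or losing resolution, which matters for
delineating tongue boundaries under small-sample training.

**Encoder.** Four stages, each an overlapped patch embedding (7×7/stride-4
convolution for stage 1, 3×3/stride-2 afterwards) followed by transformer
blocks with (a) spatial-reduction attention — keys/values computed from a
map reduced by an r×r/stride-r convolution, r per stage (8, 4, 2, 1) — and
(b) a mix-FFN whose 3×3 depthwise convolution between the two linear
layers carries positional information, so no positional encodings are
needed. Pre-norm residual wiring with layer normalisation throughout.

**Neck.** Standard top-down pyramid fusion (1×1 lateral projections to a
common width, nearest-neighbour 2× upsampling, addition), but every
post-merge 3×3 convolution is dilated with rate-matched padding p = d so
each level keeps its resolution exactly. Lateral convolutions stay 1×1 —
only the post-merge 3×3 convolutions are replaced by dilated ones, since a
1×1 kernel has no taps to space out. Rates default to (1, 2, 4, 6),
assigned one per level increasing towards the coarser levels (coarser
levels carry broader context); the assignment is configurable. Each output
convolution is followed by batch normalisation and ReLU.

**Head.** Each pyramid level is 1×1-projected to a common width and
bilinearly upsampled to the stride-4 grid (the finest level), giving Z_i.
The MDi block maps Z_i through m parallel dilated 3×3 convolutions
(default m = 3, rates 1, 2, 4 — the small rate preserves fine boundary
detail, the large one captures broad context), keeps the original map, and
fuses the m+1 maps by concatenation → 1×1 convolution → ReLU. MDi is
applied per level before cross-level concatenation. The four fused maps
are concatenated, fused by a 1×1 convolution with batch norm + ReLU,
classified per pixel by a 1×1 convolution, and bilinearly upsampled to the
input size. With MDi off the head is a plain all-MLP decoder; with the
neck off the head consumes the encoder pyramid directly. The two switches
generate the four ablation variants, whose parameter counts are strictly
ordered baseline < (+MDi or +DiFP) < full.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `embed_dims` | (32, 64, 160, 256) base; (16, 32, 48, 64) tiny | stage widths |
| `depths` | (2,2,2,2) base; (1,1,1,1) tiny | blocks per stage |
| `sr_ratios` | (8, 4, 2, 1) | attention key/value reduction per stage |
| neck/head width | 256 base; 32 tiny | common fusion channel width |
| `dilation_per_level` | (1, 2, 4, 6) | neck rates, finest→coarsest |
| `m`, `rates` | 3, (1, 2, 4) | MDi branches per level |
| `lr`, optimiser | 1e-3, AdamW (decay 0.01), poly decay power 0.9 | training |
| `input_size` | (128, 128) | training resolution (inference is native) |

The base sizing lands the full model at 14.47M parameters, matching the
~14M scale of the published configuration this architecture family uses;
the decomposition across encoder/neck/head is our choice since only the
total is known. The tiny preset (0.34M) exists because the stack runs on a
single CPU; it is the default for experiments and tests. The learning rate
1e-3 is chosen for the tiny model trained from scratch; the conventional
6e-5 fine-tuning rate of this architecture family assumes pre-trained
weights, which are out of scope.

Loss is per-pixel cross-entropy over two classes (the field's default for
a two-class softmax head; no auxiliary or boundary losses). Predictions
binarize by argmax. Inputs are standardized per channel with fixed
constants recorded in `model.py`; images whose sides are not multiples of
32 are zero-padded bottom/right and logits cropped back, preserving
top-left alignment.

## Augmentation

Training draws, per sample per epoch: isotropic rescale with factor
uniform in [0.5, 2.0]; a random axis-aligned crop retaining 75% of the
area (side lengths scaled by √0.75, uniform position); horizontal flip
with probability 0.5; brightness delta uniform in [−32, 32] (8-bit);
contrast scaling in [0.5, 1.5] about the image mean; saturation scaling in
[0.5, 1.5] in HSV space. Geometric operators act identically on image
(bilinear) and mask (nearest, so masks stay binary); photometric operators
act on the image only, clipped to [0, 255]. The order scale → crop → flip
→ photometric is fixed by configuration.

## Metrics and evaluation protocol

Dice, IoU, precision and recall are computed per image from pixel
confusion counts; when a denominator is zero (e.g. both masks empty) the
score is 1.0 by convention — perfect agreement about absence — with a
logged warning. Dice and IoU satisfy dice = 2·iou/(1+iou) and Dice equals
the F1 of pixelwise classification, 2TP/(2TP+FP+FN); the tests assert both
identities to 1e−12 against a per-pixel loop oracle. Per-metric summaries
are mean ± z₀.₉₇₅·sd/√n (sample sd; normal approximation, consistent with
symmetric reported intervals), clipped to [0, 1]; a percentile bootstrap
is available as an option. K-fold splitting delegates to
scikit-learn's shuffled `KFold` and is deterministic per seed. The
270/30 train/test split helper mirrors the reference protocol of a
300-image standardized dataset.

## Synthetic scenes

The generator emulates the two regimes of the evaluation design:
**A-like** (standardized capture: centred tongue, plain background, unit
gain) and **B-like** (in-the-wild: variable size/position, cluttered or
gradient backgrounds, gain 0.5–1.5). The tongue is an ellipse whose lower
half is stretched by a droop coefficient — analytic area
π·a·b·(1+droop/2), used as a rasterization oracle — filled with a reddish
hue/value gradient plus lightened speckle (coating), composited, gain-
scaled and perturbed by σ=2 Gaussian sensor noise. Parameter ranges were
chosen so that A-like scenes are colour-separable (high Fisher
separability between foreground and background) while B-like scenes
overlap more, reproducing the qualitative A→B difficulty ordering.

What the synthetic scenes do **not** contain: faces, lips and teeth,
specular highlights, shadows, perspective distortion, or realistic tongue
texture. A model passing the desk-scale tests is therefore shown to learn
colour/shape segmentation under the stated domain shift — not to segment
clinical photographs.

## Desk-scale study and problem sizes

The end-to-end study trains the tiny full model on 200 A-like 128×128
pairs for 6 epochs (batch 8) and evaluates 50 held-out pairs per domain at
native resolution. These sizes give stable results on a single CPU while
keeping the within-domain task learnable to Dice ≳ 0.95; the A-like Dice
is asserted ≥ 0.90 in the acceptance test, while the A→B gap is reported
but not asserted — with synthetic clutter the tiny model degrades strongly
out of domain, and the direction (A ≫ B) is the reproducible fact.

## Numerical choices and limitations

* All computation is float32 NumPy; runs are bit-reproducible for a fixed
  master seed, which fans out to separate initialisation / shuffling /
  augmentation / scene streams.
* Weight initialisation: truncated normal (σ=0.02, ±2σ) for linear
  projections, fan-out-scaled normal for convolutions, unit/zero for
  norms; biases zero.
* Batch-norm running statistics use momentum 0.1 and unbiased variance;
  evaluation always uses running statistics.
* Bilinear resizing uses half-pixel alignment implemented with dense
  separable interpolation matrices, so its adjoint (the gradient) is exact.
* Checkpoints are `.npz` archives of named parameters and buffers with an
  embedded JSON config snapshot; save → load → evaluate is bit-exact.
* The convolution is implemented as a kernel-tap loop of strided-slice
  einsums; it is exact but not competitive with framework kernels — the
  package targets correctness and desk-scale experiments, not GPU-scale
  training.
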