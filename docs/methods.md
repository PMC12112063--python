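# Methods

## The model

`uwseg` implements a lightweight DeepLabv3+ for underwater semantic
segmentation (5 classes: background, echinus, holothurian, scallop,
starfish).  Four components distinguish it from the stock network:

**MobileOne-S0 encoder with structural reparameterization.**  Every block is
a depthwise 3x3 unit followed by a pointwise 1x1 unit.  During training each
unit carries k = 4 parallel conv+BN branches, a 1x1 conv+BN "scale" branch
(3x3 units only) and a BN-only identity branch where shapes permit.  At
inference the branches fold exactly into one convolution: BN folding
(W' = W·γ/√(σ²+ε), b' = β − γμ/√(σ²+ε)) per branch, 1x1 kernels zero-padded
to the center tap of a 3x3 kernel, the identity branch kernelized as a
center-delta kernel, then summed.  The merged network is algebraically
identical; in float32 the per-unit deviation is ~1e-6 and the end-to-end
deviation on O(1)-scale activations is well inside 1e-4.  S0 stage widths
are (48, 48, 128, 256, 256) for the segmentation trunk; the final
1024-channel expansion stage of the classification network is dropped, so
the encoder's natural output stride is 16 and the stride-4 (48-channel)
tap feeds the decoder.  SE blocks are absent in S0; activations are ReLU.
BN ε is 1e-5, and merging always reads running statistics.

**SimAM.**  Parameter-free attention: per channel with spatial mean u and
variance s² = Σ(x−u)²/(M−1), each neuron's inverse energy is
(x−u)²/(4(s²+λ)) + 0.5 and the map is rescaled by its sigmoid (λ = 1e-4).
Outliers relative to their channel get weights above sigmoid(0.5); a flat
channel (and the degenerate single-pixel case) gets exactly sigmoid(0.5).
The default placement is position B — after the ASPP branch concatenation,
before the 1x1 projection; positions A (low-level features before their 1x1
reduction) and C (after fusion, before the 3x3 decoder conv) are available
as toggles, and none of them changes the parameter count.

**Strip pooling in the ASPP.**  The image-pooling branch is replaced by a
gate built from row and column mean profiles: y[c,i,j] = mean(row i) +
mean(col j), z = X ⊙ sigmoid(f(y)) with f a 1x1 convolution.  This is the
minimal direction-aware form (profiles summed raw, single 1x1 conv), not
the richer strip-pooling module with separate 1-D convolutions.  Because
the gate preserves channel count and the high tap is already 256 channels
wide, the branch enters the concatenation directly.  Atrous rates are the
canonical (6, 12, 18) at output stride 16 with 256-channel branches.

**CGA mixup fusion.**  The decoder replaces concatenation by a convex blend
of the (projected, 256-channel) low-level stream and the x4-upsampled
high-level stream: W = CGA(low + high), out = conv1x1(low⊙W + high⊙(1−W)).
CGA adds broadcast channel attention (GAP → 1x1 to C/8 → ReLU → 1x1 back)
and spatial attention (channel mean/max maps → 7x7 conv), then refines the
coarse map with the content: the input and the coarse map are concatenated,
channel-shuffled with 2 groups (interleaving content and coarse-SIM
channels), and passed through a 7x7 convolution with C groups so each
output channel sees exactly its own (content, coarse) pair.  The sigmoid
keeps every weight strictly inside (0, 1), so the pre-conv blend is
pixelwise convex.  After fusion a single 3x3 conv precedes the 1x1
classifier and the final bilinear upsampling.

The ASPP projection is followed by a 3x3 context-refinement conv+BN+ReLU
(at 1/16 resolution, before upsampling into the fusion).  This layer is part
of the mixup-fusion decoder design; together with the wiring above it makes
the architecture census reproduce the published complexity figures of the
improved configuration (see "Complexity calibration").

## Complexity calibration

The published parameter/FLOP table pins several choices the text leaves
open.  The reference DeepLabv3+ (MobileNetV2) matches the common community
implementation **exactly** at 5,814,037 parameters with 5 classes:
torchvision-style trunk without its final 1280-channel conv, five 256-channel
ASPP branches (biased convs + BN), a 24→48 low-level reduction, and two 3x3
decoder convs.  Its printed FLOPs only reproduce at output stride 8 with the
doubled-MAC convention, so the profiler's convention flag is calibrated once
on that row (`mac_as_two`: FLOPs = 2 × conv/linear MACs, bias one MAC per
output element; BN, activations, pooling and interpolation excluded) and then
applied unchanged to every model.  The MobileOne rows only reproduce at
output stride 16 with the encoder profiled in its train-time multi-branch
form, which is therefore the mode the census reports by default (the profiler
reports merged-mode numbers too; merged is strictly cheaper).  Residual
deviations from the printed values are 0.9–1.7%, with inconsistent signs
across rows, so the exact upstream wiring is not fully recoverable; the
per-layer audit table (`ProfileReport.table()`) documents ours.

## Objective and metrics

Hybrid loss = focal + dice (1:1 by default, configurable).  Focal:
mean over pixels of −(1−p_t)^γ log p_t with γ = 2 and p_t floored at 1e-12.
Dice: per class over the batch, 1 − (2Σyŷ + s)/(Σy + Σŷ + s) with s = 1e-6,
averaged over foreground classes; classes absent from both prediction and
truth are skipped.  Evaluation accumulates a (k+1)x(k+1) pixel confusion
matrix (rows = truth, ignore label 255 excluded); IoU_i = p_ii/(Σ_j p_ij +
Σ_j p_ji − p_ii), PA_i = p_ii/Σ_j p_ij, and mIoU/mPA are means over all
classes including background, excluding (and logging) classes absent from
both sides.

## Training protocol

Adam (β = 0.9/0.999, ε = 1e-8) with classic coupled L2 weight decay 1e-4,
batch 8, initial lr 1e-4 multiplied by 0.9 every 10 epochs, 100 epochs at
512x512 in the reference configuration.  "Decayed by 10%" is read as
multiplicative x0.9 (decay TO 10% would freeze learning by epoch 40).  No
data augmentation by default (a horizontal-flip hook exists, off).  Training
aborts on non-finite loss; every run logs its resolved config, seed, and
per-epoch loss/metrics as JSON lines; the best-validation checkpoint is kept.

## Numerical framework

The network runs on a compact numpy/scipy reverse-mode autodiff written for
this package: im2col + batched BLAS matmul convolutions with a
shift-accumulate fast path for grouped kernels with few channels per group
(depthwise 3x3/7x7, the CGA grouped 7x7), a fused batch-norm primitive,
bilinear resampling expressed as two constant 1-D interpolation matrices
(align-corners-false convention), and an Adam optimizer.  Everything is
float32; gradients of all primitives are tested against central finite
differences.  Backward passes free non-leaf gradients eagerly; a training
step at batch 8, 96x96 peaks at ~1.2 GB.

## Synthetic data

The generator emulates the *structure* of benthic survey imagery, not its
appearance: textured blue-green seabed; four shape families (spiny disc,
elongated capsule, fan, five-armed star) with class-specific base colors;
Poisson instance counts with a heavily echinus-dominant default
(4.0 : 0.8 : 0.15 : 0.6 expected instances per scene, echinus:scallop
≈ 27:1 as in the real survey data); degradation pipeline of color cast →
contrast compression → Gaussian blur → sensor noise applied to the image
only, never the mask.  Scenes are pure functions of their seed.  Datasets
are written as VOC-style trees (PNG images, indexed-PNG masks with labels
0–4 and 255 = ignore, 8:1:1 split lists via largest-remainder rounding).
An "easy" preset (milder degradation, larger and more balanced objects) is
the learnability setting: classes there are separable by color and shape by
construction.  What passing tests on this data shows is that the
architecture, losses, metrics and training loop are wired correctly and can
fit separable classes; it says nothing about accuracy on real underwater
imagery, which has occlusion, scale extremes and distribution shift the
generator does not model.

## Scaled-down study sizes

All desk-scale checks run on one CPU.  Architecture censuses use the full
512x512 reference input.  Reparameterization equivalence uses 20 random
probes per unit/backbone (1e-5) and 5 end-to-end probes (1e-4) at 64x64 on
trained-like statistics.  The optimization smoke test fits one batch of 4
easy scenes at 64x64 for 120 steps (lr 2e-3) and requires the hybrid loss to
drop below 10% of its initial value.  The learnability run trains on 54 easy
scenes at 128x128 (7 validation scenes) for 12 epochs at lr 2e-3 (x0.9 every
8 epochs) and requires validation mIoU > 85%; the 128-pixel resolution
matters because the decoder predicts at stride 4, so boundary-band error
bounds the attainable IoU of small objects at coarser inputs.  These sizes
are the package's chosen small-scale study conditions; the thresholds are
unchanged from the full-scale protocol they miniaturize.

## Known limitations

- The exact upstream decoder wiring is inferred from the complexity census,
  not from source; alternatives within ~2% of the printed figures exist.
- Strip pooling follows the minimal formulation (raw profile sum + 1x1
  conv); the richer 1-D-conv module is out of scope.
- float32 reparameterization equivalence degrades on networks whose
  inference-time activations are far from O(1) (e.g. freshly initialized
  nets with uncalibrated BN statistics); the fuse fingerprint therefore
  records both absolute and relative deviation.
- No ImageNet pretraining is available for the backbone; the CLI accepts a
  checkpoint path but all results here are from random initialization.
- Single-device training only; no latency/throughput measurement.
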