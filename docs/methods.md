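# Methods

`octattn` implements an attention-gated, ConvNeXt-style convolutional
classifier for retinal OCT B-scans, a synthetic B-scan generator that stands
in for clinical data, the SGDM training recipe, a six-metric binary
evaluation, and Grad-CAM explainability. This note records the model, the
choices that were genuinely open, the numerics, and what the synthetic
experiments do and do not show.

## The architecture

The network is a sequential composition of four block types.

**Patchify stem.** A 4×4 convolution with stride 4 (kernel = stride, so the
image is partitioned into non-overlapping patches), followed by batch
normalization and the swish activation `swish(x) = x·σ(x)`:

    out₁ = swish(BN(Conv4×4/4(I)))

A 224×224×3 input becomes a 56×56×96 feature map.

**Attention-gated residual block.** With input `x` (C channels):

    d   = BN(DW3×3(x))                  depthwise, stride 1, same-padding
    m   = swish(PW1×1(d)) ⊙ swish(T1×1(d))
    out = σ(m) ⊙ swish(d) + x

`PW1×1` is a pointwise (1×1) convolution and `T1×1` a 1×1, stride-1
transposed convolution — at this kernel/stride the transposed convolution is
the adjoint channel-mixing map `y_o = Σᵢ w[i,o]·xᵢ + b_o`, so both branches
preserve shape. All products are elementwise (Hadamard). The residual
addition forces shape preservation, which is why the depthwise convolution
uses same-padding and both mixers are 1×1: any other choice breaks the
elementwise products or the shortcut. `σ(m)` is a multiplicative attention
gate on the swish-activated depthwise feature.

**Patchify downsampling.** A 2×2 convolution with stride 2 between stages;
it halves the spatial side and doubles the channel width (C → 2C). The
widening location is not dictated by the block equations; placing it in the
downsampling convolution matches the stage-width schedule and the
ResNet/ConvNeXt convention.

**Output head.** Global average pooling, one fully connected layer, softmax.

The default schedule is four stages of width 96/192/384/768 with two
attention blocks each and a downsample after stages 1–3 only, giving spatial
sides 56, 56, 28, 14, 7 and a final 7×7×768 map before pooling.

### Parameter audit

`count_parameters` enumerates every learnable array: convolution and FC
weights and biases, and batch-norm scale/offset (running statistics are
state, not learnables). Component arithmetic: stem 4×4×3×96 + 96 + 2·96 =
4,896; one C=96 attention block (3×3 depthwise + bias, BN affine, two C×C
1×1 mixers + biases) = 19,776; head 768×2 + 2 = 1,538. Summing the full
default schedule gives **4,729,826** learnables (≈4.7 M).

A reconciliation note: the architecture this package implements is commonly
described as having ≈1.6 M parameters. Literal arithmetic over the printed
stage schedule — C→C pointwise and transposed 1×1 mixers at widths
96/192/384/768, two blocks per stage — cannot produce 1.6 M; the two C×C
mixers alone contribute ≈4.6 M. A 1.6 M total would require substantially
narrower mixers (e.g. a bottleneck) that no printed schedule supports. The
package therefore follows the printed schedule literally and reports its own
audited total; the discrepancy is documented rather than silently resolved
by changing widths.

## Initialization and numerics

* Glorot-uniform for all convolution/FC weights; zero biases; BN scale 1,
  offset 0. Initialization is seeded (`numpy.random.default_rng`); the same
  seed reproduces bit-identical parameters.
* Batch normalization: epsilon 1e-5. Training mode normalizes with
  mini-batch statistics and accumulates running statistics with momentum 0.9
  (`running ← 0.9·running + 0.1·batch`). After the final epoch the inference
  statistics are recomputed as exact population statistics over the whole
  training set (one extra pass); with only tens of optimization steps the
  momentum-averaged estimates are still dominated by their 0-mean/unit-var
  initialization and are useless for evaluation, whereas population
  statistics make train- and eval-mode behavior consistent. Both mechanisms
  are implemented; population finalization is on by default
  (`TrainConfig.finalize_bn`).
* Inputs: 8-bit images scaled to [0,1], grayscale replicated to 3 channels,
  resized bilinearly to the configured side, then zero-centered per channel
  with training-set means (stored in the checkpoint and applied at
  inference).
* Everything runs in float32 by default; the test suite rebuilds the same
  layers in float64 for finite-difference gradient checks (tolerance 1e-4
  relative; central differences).
* Argmax ties (e.g. an exactly uniform softmax) resolve to the lowest class
  index. Class order is alphabetical over folder names, so `bipolar` = 0,
  `control` = 1; `bipolar` is the positive class in all metrics.
* Arrays are NCHW row-major with 0-based indices.

## Training protocol

SGDM: `v ← μ·v − lr·(g + λ·w)`, `w ← w + v` with momentum μ = 0.9, initial
learning rate 0.01, mini-batch 32, L2 coefficient λ = 1e-4 applied to
convolution/FC weights only (not biases, not BN affine parameters), 50
epochs by default, shuffling every epoch. The learning rate is multiplied
by 0.1 every `lr_drop_period` epochs (default 10, 0-based:
`lr(e) = 0.01·0.1^⌊e/period⌋`); the drop period is configurable because the
source recipe states only the factor. The loss is softmax cross-entropy —
the softmax output block implies it. The train/validation split is
stratified 80:20 per class with round-half-even rounding; applied after a
fixed 75:25 train/test split this yields an overall 60:15:25 division.
Mini-batches that would be smaller than the batch size (a trailing
remainder) are not formed; with the shipped configurations the training-set
sizes are multiples of the batch size. Validation accuracy is evaluated once
per epoch; there is no augmentation and no best-validation checkpointing.

## The synthetic generator

Real macular B-scans show a dark vitreous above a smoothly curved retina of
stacked reflectivity bands with a central foveal depression and strong
multiplicative speckle. The generator renders exactly these ingredients:
a parabolic surface with a Gaussian foveal dip; seven bands (RNFL 14 px
bright, inner nuclear/plexiform alternation, dark ONL, bright
photoreceptor–RPE complex, textured choroid) with per-image thickness
jitter; per-band additive texture noise; unit-mean log-normal speckle
(`exp(N(−s²/2, s))`, the standard multiplicative model for coherent
imaging). The disease effect is fractional thinning of the RNFL band plus a
small widening of its texture noise, motivated by RNFL involvement being the
leading OCT finding in neuropsychiatric disease; an optional RPE texture
effect is available and off by default. The thinning is rendered with a
locally compensated geometry: the removed thickness is returned to the
adjacent ganglion-cell/plexiform band, so every boundary below it sits at
the same depth in both classes and the image evidence for the disease is
confined to the RNFL band itself. Without the compensation the entire deep
band stack shifts with the RNFL, and a classifier can (and in practice
does) read the class from displaced deep boundaries — which would make
heatmap-based localization claims about the RNFL unfalsifiable. The second scan orientation is
rendered as the 90°-rotated geometry — a modeling placeholder, since the
physical difference between orientations of the emulated dataset is not
described anywhere.

Thickness jitter is truncated at ±2 sd (RNFL sd 0.7 px). This makes the
class-conditional thickness supports disjoint whenever the thinning fraction
is ≥ 0.3: a control RNFL never drops below 12.6 px while a 30%-thinned band
never exceeds 11.2 px. Consequently a simple threshold on measured band
thickness (`measure_rnfl_thickness`, the package's oracle classifier)
separates the classes perfectly by construction — the generated problem is
*intended* to be learnable to 100%, so that a correct implementation of the
network and recipe can be validated against an exact target.

What passing tests on this generator do **not** show: anything about real
bipolar-disorder OCT morphology. The synthetic effect is a stand-in with a
deliberately clean geometry; real scans carry segmentation ambiguity,
pathology heterogeneity, device noise and demographic confounds that the
generator does not model. Results on the generator validate the software,
not the clinical claim.

Default counts per orientation are 403 bipolar and 912 control images
(2,630 total over both orientations), with fixed splits of 303/100 and
684/228 — the structure of the emulated dataset.

## The scaled-down surrogate experiment

The headline experiment trains the full default architecture for 10 epochs
on one orientation with 60 train + 20 test images per class (thinning 0.40,
speckle sd 0.05), the training protocol above, and evaluates the six metrics
on the 40 held-out images. The sizes were chosen so a complete run —
dataset generation, 30 optimization steps at batch 32, BN finalization and
evaluation — finishes in minutes on a single CPU core while still exercising
every component at full architectural scale. `scripts/acceptance.py` runs
it end to end from a single seed.

## Grad-CAM

The class score is the raw logit (so heatmaps are invariant to constant
logit shifts). Channel weights are the spatial mean of the score's gradient
on the target feature map — by default the output of the last attention
block, the deepest spatial map; the rectified weighted channel sum is
upsampled bilinearly to input resolution and normalized to [0,1] by its
maximum (an all-zero map stays zero). Per-image max normalization destroys
cross-image comparability of absolute values; cross-image statements should
use rank statistics or the pre-normalized maps. Raw activation maps can be
obtained from `AttentionGatedNet.forward_collect` as a debug output.

## Known limitations

* Pure-NumPy execution: a training step on the full 224×224 architecture
  takes seconds per mini-batch on one CPU core; the package is sized for
  method validation, not large-scale training.
* Binary classification only; the metric suite deliberately excludes
  ROC/AUC.
* The generator's orientation difference (rotation) is a placeholder; no
  physical A-scan/interferometry modeling.
* `lr_drop_period` interacts with long runs: with the default period 10 the
  learning rate reaches 1e-5 by epoch 30, effectively freezing late
  training. This follows the stated recipe; runs that need sustained
  progress should lengthen the period.
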