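# Methods

## Problem and model

`toothseg` segments the 32 permanent teeth in a panoramic radiograph as 32
*independent* binary masks, one channel per FDI code.  The multi-label
formulation is the central modelling choice: adjacent teeth genuinely overlap
in a panoramic projection, so a pixel may belong to two teeth at once.  A
sigmoid head scores every channel independently and preserves that overlap; a
softmax head (32 teeth + an explicit background class) forces one label per
pixel and is included as the comparison variant.

The network is an encoder-decoder:

* **Encoder.** Five stages at strides 2, 4, 8, 16, 32 produce taps
  D1..D5 with depths 64, 192, 288, 768, 2048 in the reference
  configuration.  The stage stack is InceptionV3-shaped: what the rest of
  the model consumes is the stride/depth contract of the taps, and every
  downstream shape is derived from it.  All convolutions are same-padded —
  with valid padding a 256 x 512 input cannot yield a 128 x 256 first tap,
  so padding is part of the shape contract.  A `tiny` backbone
  (depths 8, 16, 24, 32, 48) keeps the identical contract for CPU-scale
  experiments.  Weights are randomly initialized (He normal); there is no
  pretrained-weight path in this package.
* **Feature integration.** Pointwise convolutions project every tap to a
  common depth (128 reference, 32 tiny), then a top-down pyramid merges
  levels by elementwise addition: F5 = E5, F_{i-1} = Up2(F_i) + E_{i-1}.
* **SE inception gates.** Each of F1..F4 passes a three-branch inception
  block (5x5 conv; two 3x3 convs; 3x3/stride-1 max-pool + pointwise), each
  branch `branch_width` channels wide (64 reference, 8 tiny), each branch
  multiplied elementwise by a squeeze-and-excitation gate.  The gate is two
  stacked pointwise convolutions (squeeze to c/2, expand to c = branch
  depth) followed by a sigmoid; deliberately there is **no global average
  pooling**, so the gate weights vary per pixel.  This is a spatially
  varying attention map rather than the classical per-channel SE vector; it
  is implemented exactly as specified rather than "fixed" to the canonical
  SE form.
* **Fusion and head.** M1..M4 are upsampled (nearest-neighbor by default,
  bilinear by config) to the finest decoder grid and concatenated (depth
  4 x 3 x branch_width = 768 reference), passed through a 3x3
  Conv-BatchNorm-ReLU (width 128 reference), upsampled x2 to full
  resolution and projected by a 1x1 convolution to the output channels.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `tap_depths` | 64,192,288,768,2048 | encoder tap depths (tiny: 8,16,24,32,48) |
| `fib_depth` | 128 | common depth after pointwise reduction |
| `branch_width` | 64 | channels per inception branch; concat depth 3x |
| `activation` | sigmoid | sigmoid = 32 multi-label planes; softmax = 33 classes |
| `threshold` | 0.5 | per-channel cutoff; strictly-greater comparison |
| `head_bias_init` | -3.0 | final-layer bias at the foreground-prior logit, which stops the early optimization from spending epochs discovering that teeth are rare |
| `learning_rate` | 3e-3 | Adam step size for the desk-scale recipes |
| `batch_size` / `epochs` | 2 / 200 | desk-scale defaults (the capacity experiment uses batch 4) |

Loss defaults: mean per-channel binary cross-entropy for the sigmoid head;
per-pixel 33-class categorical cross-entropy for the softmax head, where a
pixel claimed by several teeth is assigned the lowest channel index (a
deterministic tie-break — softmax truth must be single-label by
construction).  Optimizer, learning rate, augmentation set and epoch counts
are this package's own defaults; they are deliberately ordinary choices
(Adam, small rotations, mirror with channel remap) rather than anything
tuned per-dataset.

## Numerical engine

No deep-learning framework is used: `toothseg.nn` is a small reverse-mode
autodiff engine over numpy (im2col convolution, stride-1 same-padded max
pooling, nearest/bilinear upsampling, batch normalization, fused
cross-entropy losses), with float32 arithmetic throughout.  Convolution
recomputes patch matrices in row blocks during the backward pass, bounding
peak memory; the full reference forward pass at 256 x 512 runs in a few
hundred MB and well under a minute on one CPU core.  Correctness is
established by exhaustive forward oracles (direct-summation convolution,
naive pooling) and float64 finite-difference gradient checks in the test
suite.

Two numerical conventions worth noting:

* sigmoids are clamped to the nearest representable values inside (0, 1):
  at float32 a pre-activation beyond about +-17 would otherwise round the
  gate weight to exactly 0 or 1, violating the open-interval contract that
  the gated output is strictly smaller in magnitude than its input;
* thresholding uses a strict inequality (`prob > t`), so a probability of
  exactly 0.5 at the default cutoff is background.

## Synthetic scenes

The generator renders two arches of 16 teeth on parabolic curves; each tooth
is a superellipse crown plus 1-3 tapered root prongs (1 for incisors and
canines, 1-2 for premolars, 2-3 for molars — simplified anatomy that affects
realism only).  Adjacent crowns overlap laterally by `overlap_fraction` of
crown width: crown centers are fixed by the arch, widths are
`spacing / (1 - overlap_fraction)`, which makes the count of multi-label
pixels non-decreasing in the overlap fraction by construction.  The image is
a bone-gradient background plus a fixed per-tooth brightness increment,
bright elliptical restoration-like artifacts, and additive Gaussian noise;
every tooth pixel is strictly brighter than the background mean before
noise, which is what makes the scenes learnable.  Geometry, artifacts and
noise draw from three independent streams spawned from the scene seed, so a
spec reproduces its scene bit for bit and presence flags or the overlap
setting never shift the jitter stream.

Default conditions: 256 x 512 canvas (64 x 128 in the fast recipes), 25 %
crown overlap, 5 % independently missing teeth per scene, noise sigma 0.02,
3 artifacts.  What the generator does **not** emulate: radiographic physics
(beam hardening, ghost images), soft-tissue and bone anatomy, caries,
restorative geometry, or the resolution loss of real detectors.  Passing
tests on these scenes demonstrate that the architecture, losses, metrics and
pipelines behave as contracted — not that the trained weights transfer to
clinical radiographs.

## Evaluation

Per-tooth counts are pooled over all evaluated images before computing
metrics ("micro per tooth"), and the report's Average row is the unweighted
mean over the 32 teeth.  Accuracy is per-channel binary accuracy including
background pixels, which is why it sits near 99.9 % even for mediocre
segmentations — background dominates every channel.  Metrics with zero
denominators are defined as 0 and flagged (`absent`), so a tooth missing
from both truth and prediction yields a clean row rather than NaN.

The 33-label confusion matrix needs one label per pixel, so the multi-label
planes are reduced: predicted label = argmax over channels whose probability
exceeds the threshold (background if none; ties to the lowest channel
index), truth label = lowest-index truth channel.  Because this reduction
differs from the per-channel binary scoring, a recall read off a
confusion-matrix row need not equal the per-channel recall for the same
tooth; both views are provided and neither is forced to agree with the
other.

## Experiment sizes

The capacity experiment trains the tiny configuration on 8 synthetic
64 x 128 scenes for 200 epochs (Adam, batch 4) and scores the training set
itself; the activation comparison trains sigmoid and softmax heads for 100
epochs on 8 scenes with 35 % overlap and scores a disjoint 4-scene test set
across 3 seeds.  These sizes were chosen as the smallest at which the
qualitative behaviors are stable; the published-table arithmetic, shape
contracts and metric oracles are exact and independent of them.

A note on the capacity run: the contract that the epoch-mean training loss
is non-increasing over every 20-epoch window holds for the batch-4 recipe
across all 200 epochs.  With very small batches (e.g. 2) minibatch
recomposition makes the converged trace fluctuate at the ~0.5 % level —
normal stochastic-optimizer behavior at the loss floor — so the batch size
of the smoke recipe is the smallest at which the window property holds
exactly.

## Known limitations

* The encoder realizes the printed tap contract with a compact stage stack,
  not the literal InceptionV3 layer graph, and has no pretrained weights.
* Scene realism is geometric, not physical (see above).
* The softmax comparison inherits every limitation of single-label
  reduction; its per-tooth scores on overlap-heavy scenes are structurally
  depressed, which is exactly the effect the comparison exists to show.
* Reports are rounded to 2 decimals on the percent scale when written to
  CSV; in-memory tables keep full precision.
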