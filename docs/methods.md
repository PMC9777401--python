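# Methods

## Problem and model

Diabetic retinopathy (DR) produces four lesion types in fundus photographs —
microaneurysms (MA), hemorrhages (HE), soft exudates (SE) and hard exudates
(EX) — spanning sizes from a few pixels to large diffuse blobs, on a retina
whose vessels mimic the dark lesions.  The package implements MSLF-Net, an
end-to-end pixel classifier for the five-way problem (four lesions +
background):

* **Encoder**: the VGG16 convolutional configuration, five stages of widths
  (64, 128, 256, 512, 512), 2x max pooling after stages 1–4.  On a 1440x960
  input the fifth stage is 90x60x512.
* **Decoder**: U-Net-shaped — a two-conv transition block at 1/16 scale,
  then four up-steps (2x2 stride-2 transposed convolution, skip
  concatenation with the matching encoder stage, two 3x3 conv+ReLU), giving
  decoder taps of widths (512, 256, 128, 64, 64) at scales 1/16…1/1, and a
  1x1 classification head on the finest tap.  That head is retained as a
  deep-supervision output.
* **MSFE** (multi-scale feature extraction): per tap, a residual 3x3
  conv+ReLU whose output is *added* to the tap, a 1x1 projection to M=5
  channels, and bilinear upsampling to full resolution (the full-resolution
  tap is not upsampled).  Decoder up-sampling is transposed convolution;
  MSFE up-sampling is bilinear — the distinction is deliberate.
* **MLFF** (multi-level feature fusion): the five M-channel maps are
  rearranged *category-major* — output channel `k*5 + (b-1)` holds category
  `k` of block `b` — and fused by an M-group 1x1 convolution, so each class
  channel aggregates only same-class evidence across scales.  The
  rearrangement is a pure, invertible permutation.  No nonlinearity is
  applied between the grouped fusion and the softmax; none is specified for
  this step and a linear per-class mixing keeps the category-isolation
  interpretation exact.

Ablation flags reproduce the component study: baseline (decoder head only),
+MSFE (element-wise mean of the five maps — "simple fusion"), +MLFF (full
category-major fusion).

## Loss

Per head (main and deep-supervision), with per-pixel softmax probabilities
p and one-hot labels y over channels (MA, HE, SE, EX, background):

* weighted cross-entropy `L_ce = mean_px [ -sum_c w_c y_c log p_c ]` with
  `w = (100, 100, 50, 30, 1)`; the mean over counted pixels makes the
  lambda mix resolution-independent (the reduction is otherwise
  unspecified).
* soft Dice `L_dice = M - sum_c 2 TP_c / (2 TP_c + FN_c + FP_c + 1e-7)`
  with probabilistic TP/FN/FP sums; the leading constant is read as the
  class count M, the only reading that gives zero loss at a perfect
  prediction.  The epsilon makes absent classes contribute 0 (not NaN);
  an all-background image predicted perfectly therefore scores M-1, which
  is documented behaviour, not a bug.
* hybrid `L = L_ce + lambda * L_dice`, lambda = 1.0; the ablation encoding
  lambda = -1 selects Dice alone, lambda = 0 cross-entropy alone, and
  values in (-1, 0) are rejected as undefined.
* total = main + `aux_weight` x deep-supervision head (same hybrid loss on
  both; `aux_weight` = 1 by default).  With `fov_masked` on (default),
  pixels outside the field-of-view mask are excluded from both terms — the
  FOV enters training only through this masking, not as an input channel.
* log arguments are clamped at 1e-7.

## Training

SGD with momentum 0.9 and weight decay 5e-4, batch size 2, 200 epochs,
initial learning rate 0.01 decayed per epoch (not per iteration) by the
Poly rule `lr = lr0 * (1 - epoch/total)^0.9`.  Checkpoint selection uses a
seeded 80/20 split with best-validation-mAUPR retention; repeated runs use
seeds (seed, seed+1, …) with results averaged.

One addition: gradients are clipped to a global L2 norm of 5 by default.
The published recipe starts from an ImageNet-pretrained encoder; trained
from scratch (the only option offline), the heavy class weights produce
very large early gradients and un-clipped SGD at practical learning rates
can drive the ReLU network into a dead, constant-output state.  Clipping
removes that failure mode without changing the schedule; it can be disabled
(`clip_grad_norm=None`).

`pretrained_encoder` accepts a path to an `.npz` of VGG16 convolutional
weights; no downloading is performed, and tests run with random
initialization.

## Evaluation

Per-class pixel-level precision–recall curves with AUPR by the
average-precision (step) convention `sum_n (R_n - R_{n-1}) P_n` —
trapezoidal interpolation would differ and is not used.  Scores are the
softmax probability channels of the main output.  Pixels are pooled across
test images before curve construction by default (the retinal-challenge
convention); a per-image-average mode is provided.  Pixels outside the FOV
are excluded; classes with no positive pixels are excluded from mAUPR with
a warning.

## Synthetic data

The generator emulates the structures that drive the method's design: a
bright circular FOV disc on an exactly-black surround, dark curvilinear
vessel-like distractors (quadratic Béziers), and the four lesion archetypes
— MA as 1–2 px dark dots, HE as irregular dark blots, SE as large
soft-edged pale blobs, EX as small bright deposits — with per-class
(min, max) radius ranges ordered so mean MA area < mean EX area < mean SE
area.  Default canvas 128x128 with FOV radius 0.45·min(H, W) and counts
(3, 2, 1, 2); these sizes make desk-scale testing fast while preserving
the size spectrum.  Lesions of different classes are kept disjoint with a
one-pixel separation so one-hot encoding is well defined and component
counts are exact.  Images are quantized to 8 bits so PNG round-trips are
bit-identical; all randomness derives from a single seed via a
SplitMix64-style per-sample derivation.

What the generator does *not* model: optic disc, illumination gradients
across real devices, lesion-class overlap, annotation noise, DR severity
structure.  Tests passing on synthetic data therefore demonstrate
correctness of the pipeline and capacity of the architecture, not clinical
performance on IDRID-like photographs.

## Numerical and implementation choices

* All layers are numpy (float32) with explicit hand-derived backward passes,
  verified against central finite differences layer by layer.  Convolutions
  are computed as sums of shifted channel-mixing matmuls, keeping peak
  memory proportional to a feature map so full-resolution (1440x960)
  inference fits in ordinary RAM.
* Max-pool ties route the gradient to the first maximum.  Bilinear resizing
  uses half-pixel centre alignment expressed as dense separable
  interpolation matrices (exactly transposable in backward).
* "Resize without deformation" is implemented as letterboxing: uniform
  scale `min(tw/W, th/H)`, symmetric zero padding with the extra pixel
  going bottom/right; images bilinear, masks nearest-neighbour, one shared
  geometric map.  A 4288x2848 input letterboxed to 1440x960 has a 1440x956
  content region with 2-px bands top and bottom.
* The FOV mask recipe (unspecified upstream) is Otsu's threshold on the
  max-over-channels image, closing with a radius-5 disc, hole filling, and
  largest-component selection.
* Augmentation ranges left open upstream are set conservatively: rotation
  ±15°, translation ≤5%, shear ≤5°, photometric factors in [0.93, 1.07]
  and hue shift ±0.07 — all exposed in `PreprocessConfig`.  Geometric
  transforms warp a per-pixel class-index map with nearest-neighbour
  sampling and re-encode, so the one-hot invariant survives any
  combination of transforms.
* The published layer table's *input*-size bookkeeping is internally
  inconsistent (e.g. a concatenation listed with the pre-concat channel
  count); the *output* column is treated as the binding contract and
  internal widths are sized to satisfy it.

## Desk-scale problem sizes

The test suite exercises the full architecture at reduced resolutions
(32x32 and 96x64), where the ÷16 shape rules are identical to full scale.
The capacity check overfits four synthetic 96x64 images for 50 epochs and
requires training mAUPR ≥ 0.90; its learning rate is chosen for
from-scratch convergence at that scale (the published 0.01 presumes a
pretrained encoder).  Full-scale (1440x960) shape contracts are verified
with a single inference pass.  Headline dataset results from GPU-scale
training on IDRID/e_ophtha are out of scope by construction.

## Known limitations

* CPU-only and far slower than a GPU framework; practical for toy scales
  and single full-resolution inference, not 200-epoch full-scale training.
* From-scratch initialization differs from the pretrained-encoder recipe;
  absolute segmentation quality on real datasets is not reproduced here.
* The exact internal layout of the multi-scale refinement block is one
  faithful reconstruction (residual-then-project); it is isolated behind a
  single class so it can be swapped.
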