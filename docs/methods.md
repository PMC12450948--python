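# Methods

## Problem and model

The package detects and counts early-stage maize seedlings in top-down RGB
imagery acquired a few meters above a drip-irrigated field. Targets are small
(relative widths mostly 0.02–0.07, heights 0.02–0.10; at the 5280×2970 source
resolution roughly 106–370 px wide and 59–297 px tall) and densely, regularly
distributed along paired crop rows (25 cm within a pair, 50 cm between
pairs, ground sampling distance ≈ 0.07 cm/px).

The detector is an anchor-free one-stage network with three pyramid levels at
strides 8/16/32. Its baseline form is the standard nano-scale architecture:
a CSP backbone with split-transform-merge (C2f) blocks and SPPF, a
path-aggregation (PANet) neck, and a decoupled head with distribution-focal
(DFL) box regression. Three structural replacements can be switched on
independently, giving eight buildable variants:

1. **Backbone** — an HG-style hierarchy (`HGStem` → four stages of densely
   aggregating blocks → depthwise stride-2 downsamples). Each block chains
   `n_light` RepConvs from the block input, concatenates the input with all
   chain outputs, and squeezes through a 1×1 conv pair (cout/2 then cout),
   with a residual add when shapes allow and a learnable affine shunt
   (scale init 1, bias 0) on the activation branch. A RepConv trains as
   3×3-conv+BN ∥ 1×1-conv+BN ∥ BN-only identity (only when cin=cout,
   stride 1), summed before ReLU.
2. **Neck** — bidirectional weighted fusion over the three levels. Every
   merge point is a fusion node: fast normalized fusion
   `Σ ReLU(wᵢ)Iᵢ/(ε+Σ ReLU(wⱼ))` (ε = 1e-4, raw weights init 1) followed by a
   C2f aggregation block. The bottom-up middle node takes three inputs — the
   top-down feature, the downsampled lower level, and a lateral skip from the
   level's original input. Channels stay per-level (64/128/256 after the
   standard backbones); 1×1 convs align channels on the top-down path,
   nearest-neighbor ×2 upsampling and stride-2 group convs resample.
3. **Head (TDADH)** — per-level 1×1 conv+GroupNorm projections to a shared
   width, then two 3×3 conv+GroupNorm layers whose *parameters are shared by
   all levels*. Their concatenated outputs form the task-interaction feature,
   from which (a) a 1×1 conv generates 18 offset + 9 sigmoid-mask channels,
   and (b) two small layer-attention generators (global average pool → 1×1
   conv → sigmoid over the 2-layer stack) decompose the interaction into
   classification and regression features. The regression feature passes
   through a modulated deformable 3×3 convolution (explicit bilinear gather;
   out-of-bounds samples contribute zero) plus GroupNorm; shared 1×1 convs
   predict class logits and 4×reg_max DFL logits, and one learnable scalar
   Scale per level multiplies the decoded regression distances.

### Reparameterization

Batch-norm folding uses the canonical `(x−μ)/√(σ²+ε)` denominator with
ε = 1e-5. Branch fusion pads the 1×1 kernel to 3×3 (value at the spatial
center), converts the identity branch to a per-channel Dirac kernel, folds
each branch's BN, and sums kernels and biases. `reparameterize(model)` fuses
every RepConv in place, is idempotent, leaves all non-Rep weights
bit-identical, and never increases the parameter count. Equivalence of the
training-structure and deployed networks is asserted at 1e-5 max-abs in
32-bit eval mode.

## Label assignment and loss

Task-aligned assignment: for each ground truth, candidate anchors are those
whose cell-center lies strictly inside the box; they are ranked by
`t = s^α · u^β` (s = predicted class probability, u = IoU of the decoded box;
α = 0.5, β = 6, top-k = 10, ties broken by anchor index) and an anchor
claimed by two ground truths goes to the higher t. Target class scores are
the alignment metrics normalized per ground truth to its best candidate IoU.
The loss is `7.5·(1−CIoU) + 0.5·BCE + 1.5·DFL` (weights exposed in config);
DFL is the cross-entropy of the two bins bracketing the true side distance,
linearly weighted; box and DFL terms are weighted by the target scores and
all terms are normalized by the summed target scores.

Training is plain SGD with the study hyperparameters (lr0 0.01, momentum
0.937, batch 16, 400 epochs, 4 loader workers as config parity) and a linear
decay to lr0/100 (i.e. 1e-4). A 3-epoch linear warmup ramps the learning rate
from 0 and momentum from 0.8; without it, small-object training can collapse
early (predicted boxes shrink to zero area before scores align, the IoU^β
term annihilates the alignment metric, and every anchor becomes background).
Gradient-norm clipping at 10 guards the first steps. Classification
prediction convs are bias-initialized to the expected object prior per cell
(log(5/nc/(640/stride)²); the shared head uses the middle stride), regression
prediction convs to 1.

Inference decodes DFL expectations, applies sigmoid confidence (default
threshold 0.25) and class-agnostic greedy NMS (IoU 0.7). The stand count is
the number of surviving detections.

## Canonical configuration and complexity calibration

The backbone's stage widths and the neck/head capacities are not determined
by the architecture description alone; they were calibrated once against the
three locked complexity totals (baseline 3.01 M / 8.1 G; backbone-only
variant 6.9 G; full model 1.58 M / 7.4 G at 640×640, single class) and then
frozen:

* backbone: stem mid/out 16/16; stages (mid, out, blocks, light-convs) =
  (12, 32, 1, 3), (16, 64, 1, 3), (40, 128, 1, 3), (116, 256, 1, 3);
* neck: C2f node repeats (1, 1, 1, 4) for (td4, td3, bu4, bu5), expansion
  0.25, downsample conv groups 4;
* head: shared width 96, GroupNorm groups 16, reg_max 16.

FLOPs are counted as 2 per multiply-accumulate over convolution layers (bias
adds included where a bias exists; the deformable alignment counted as its
equivalent gathered 1×1 convolution), at the model's current structure —
multi-branch while training-structured, single-branch after fusion.
Normalization elementwise work is reported separately. Parameters are counted
on the training structure (BN parameters included), which is the convention
under which the baseline's published totals reproduce exactly. The profiler
reports both fused and unfused numbers, and weight sizes at both 32- and
16-bit encodings (published MB figures for this model family are consistent
only with ~16-bit serialization).

The eight-variant ablation grid reproduces the expected orderings: every
rep-backbone variant has strictly fewer FLOPs than its counterpart, every
shared-head variant strictly fewer parameters. The individual figures of the
two mixed rows (head-only and rep+head) cannot all be matched simultaneously
by any single per-layer accounting — the published component deltas are
mutually inconsistent at this granularity — so those two rows are reported
but not locked.

## Synthetic data

`synthetic_field` renders what the acquisition geometry implies: brown soil
with low-frequency patchiness and grain, crop rows in 25/50 cm pairs
(physical lengths converted through the 0.07 cm/px GSD and rescaled by
canvas-width/5280 so relative statistics survive on desk canvases), and
seedlings drawn as four leaf lobes along the box diagonals plus a brighter
apical center, with per-plant color jitter. Each seedling's label is the
tight bounding box of its painted pixels, so ground truth is exact; sampled
relative sizes default to the field statistics (w 0.02–0.07, h 0.02–0.10) and
the rendered 5th–95th percentiles stay inside those ranges. Weed-like
distractor blobs can be added (off by default) and emit no labels. The
augmentation suite is the offline set: Gaussian noise (σ = 10/255),
salt-and-pepper (rate 0.02), brightness ±25 %, horizontal/vertical/both
flips, and one quarter-turn rotation with the exact label map
(cx, cy, w, h) → (cy, 1−cx, h, w); one representative per original scene is
kept, chosen uniformly from the original plus its variants with a
per-image-id seeded draw. Everything is deterministic from one master seed.

What the generator does **not** emulate: real leaf morphology and occlusion,
shadows, specular soil, perspective and motion blur, or inter-plant overlap
at canopy closure. Passing the training tests therefore shows the pipeline
(assignment, losses, decoding, counting) learns and localizes correctly on
separable small targets — not that the model reaches field-grade accuracy on
real imagery.

## Desk-scale experiment sizes

The numerical stack is pure numpy, so experiment sizes were chosen at desk
scale as the package's own test profile: the training property uses 80
synthetic 160×160 crops with 6 seedlings each and relative sizes 0.08–0.22 —
the same per-target *pixel* statistics as full 640-px frames, since a 160-px
crop of a 640-px scene multiplies relative sizes by 4 — with a
width-halved model, batch 8, up to 40 epochs with early stop once training
mAP@0.5 reaches 0.85. The asserted thresholds (mAP@0.5 ≥ 0.8; exact count
recovery on ≥ 90 % of scenes) are unchanged from the full-scale property.
Reparameterization equivalence is checked at 96-px inputs; the complexity
accounting always runs at the full 640×640.

## Numerical choices and edge cases

* 0/0 precision and recall return 0 (needed at the zero-detection sweep end).
* AP uses all-point interpolation (monotone precision envelope integrated
  over recall); 101-point interpolation would differ slightly and is not
  used. With one class, mAP ≡ AP.
* Greedy detection–truth matching takes, per detection in confidence order,
  the highest-IoU unmatched ground truth at IoU ≥ 0.5.
* Out-of-range label coordinates are rejected on read, never clipped;
  `relative_size_to_pixels` rounds half up (105.6 → 106).
* Dataset splitting uses largest-remainder apportionment after a seeded
  shuffle (993 images at 7:2:1 → 695/199/99 — a consequence of the rounding
  rule, not an observed fact).
* Fusion-node ε = 1e-4; Grad-CAM++ α-denominator stabilized at 1e-8 with
  vanishing-denominator channels given zero weight.
* The deformable sampler clamps nothing: out-of-bounds bilinear corners
  contribute zero, and the gradient to offsets uses the bilinear-weight
  subgradient.
* The Grad-CAM++ score is the sum of post-sigmoid confidences of
  above-threshold detections; the default target layer is the stride-8 neck
  output, where the smallest targets live. The heatmap is normalized after
  upsampling so its peak is exactly 1 whenever the raw map is nonzero.

## Known limitations

* CPU-bound: full-scale (640 px, 400-epoch) training is far outside this
  implementation's intended envelope; it is built for correctness, property
  testing and desk-scale experiments.
* Video support means frame sequences (directories, multi-frame TIFF/GIF,
  iterables of arrays); containerized codecs (mp4/avi) are out of scope.
* The published accuracy of the full-scale system on real UAV imagery is not
  reproducible here: the original dataset is private and the synthetic
  generator is not photorealistic.
* Single-class focus; the multi-class paths (per-class AP averaging, class
  fields in labels) are implemented but only lightly exercised.

## Operating points

mAP is evaluated sweeping all confidences with NMS IoU 0.7 (the family's
evaluation default). Stand counting uses conf 0.25 with suppression IoU 0.45:
seedlings at this growth stage do not overlap, so boxes overlapping above
0.45 are near-duplicates of one plant, and the stricter threshold removes the
dominant counting error mode (double counts) without affecting separable
detections.
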