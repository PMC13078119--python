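# Methods

This note documents the models and procedures implemented in `yolosda`,
the parameter choices that matter, what the synthetic data does and does
not emulate, and the numerical conventions. It states no empirical result
beyond what the test suite and `scripts/acceptance.py` compute.

## Detection skeleton

The detector is an anchor-free backbone–neck–head network. The backbone
emits a stride-8/16/32 pyramid; the neck runs a top-down path (two
upsample → concat → fusion stages) and a bottom-up path (two stride-2
conv → concat → fusion stages); three decoupled heads predict, per cell, a
discretised box (distribution-focal regression over 16 bins per side, in
stride units) and one sigmoid logit per class. Decoding takes the softmax
expectation of the bins, scales by the stride, clips to the image, and
applies greedy per-class non-maximum suppression.

Three switches define the studied variants: `backbone` (conv/CSP baseline
with area-attention tail blocks vs the star backbone), `upsampler`
(nearest vs dynamic resampling) at both neck upsample sites, and
`fusion_block` (baseline area-attention fusion vs its SCSA-augmented
form) at every fusion site. The baseline backbone carries its two
area-attention fusion blocks at strides 16/32; the star backbone is a pure
four-stage hierarchy, so in star builds the fusion swap acts on the three
neck sites only.

## Star backbone

Stages follow a stride-2 stem (3×3 conv → BN → ReLU6). Each stage opens
with a stride-2 3×3 convolution (BN, ReLU6) and chains star blocks:
`X_star = σ(dw7×7(X) ⊗ (W_fc X + b)) + X`, with one 7×7 filter per channel
in the depthwise branch (exactly 49·C weights, no cross-channel terms) and
no normalisation inside the block. The rectifier σ (ReLU6; ReLU via
config) is applied to the merged product: the product of two linear
branches grows quadratically in the input scale, and chaining unbounded
blocks makes activations explode during training — clamping each block's
residual increment keeps the forward bounded while preserving the exact
identity when the pointwise branch is zero (σ(0) = 0). The
global-average-pool classification head of the original backbone design is
intentionally omitted; detection consumes stage features. The stem stride
is 2 so the four stages land on strides 4/8/16/32.

## Dynamic upsampler

Offsets are predicted in *source-pixel units* per output pixel and per
channel group (g groups share one (dy, dx) pair). The base grid places
output pixel (i, j) at source position ((i+0.5)/s − 0.5): with zero
offsets the operator is exactly half-pixel-aligned bilinear ×s resizing,
which is the anchor for the zero-offset equivalence test. The static
branch is the channel-to-space rearrangement of a 1×1 linear map scaled by
a fixed range factor (0.25); the literal reading of a "pixel-shuffle
factor of 0.25" is not well-defined, so 0.25 is implemented as the static
range factor and the rearrangement uses the integer scale s (both
config-exposed). The dynamic branch gates a second linear response by the
sigmoid of a third (`0.5 · sigmoid(Linear₂X) ⊗ Linear₃X`); either operand
could plausibly be the gated one, so the choice is config-switchable.
Sampling is bilinear with border clamping, keeping constant fields exactly
constant and output extrema within input extrema. Default g = 8 at both
neck sites (part of the complexity calibration below).

## SCSA attention

The degenerate reading — 1-D multi-scale convolutions applied to a 1×1
pooled vector — makes every kernel size equivalent, so the default follows
the per-axis design: the map is mean-pooled along W (height profile) and
along H (width profile); shared depthwise 1-D convolutions (kernels 3/5/7)
filter each profile, the three scales are concatenated, group-normalised,
squashed by a sigmoid and averaged back to C gates per axis. The two axis
gates are *averaged* (not multiplied) into W_s ∈ (0,1): averaging keeps
the constant-input collapse exact at ½ (an outer product would give ¼).
The literal pooled-input variant remains available behind
`literal_pooled=True`.

Two exactness choices follow from the collapse invariant (group
normalisation maps constants to zero, sigmoid(0) = ½): the gate
normalisations are per-channel (one group per channel — a group spanning
channels would mix different per-channel constants), and the 1-D gate
convolutions use replicate padding (zero padding breaks constancy at the
sequence edges). Neither choice changes the parameter count.

The channel pathway is single-head: Q is the group-normalised map pooled
to a ≤7×7 token grid, K a per-channel 1×1 projection of the
group-normalised pooled map, and V the same projection at full
resolution, so `A = softmax(QKᵀ)` is a C×C row-stochastic matrix and
`A·V` a full-resolution attended map. No 1/√d temperature is applied by
default (config-exposed). W_c comes from a 9-tap depthwise gate on the
axis profiles, pooled to one value per channel. Output: X_s + X_c.

`A2C2f_SCSA` embeds SCSA between the area-attention and MLP of each unit
and arranges the units as two parallel, independently parameterised
branches (a config flag shares them) off a 1×1 stem, concatenated and
merged by a 1×1 convolution to *half* the output width, scaled by a
learnable scalar (init 1) and restored by a final 1×1 projection. The
half-width merge keeps the high-resolution sites light; see calibration.

## Complexity accounting and calibration

Parameters are exact learnable-element counts (normalisation affine terms
included; running statistics and the fixed DFL expectation excluded).
FLOPs are measured on a real forward pass at the declared input size with
1 MAC = 2 FLOPs over convolution and linear layers; functional attention
matmuls are excluded by default — the convention under which detector
complexity tables are conventionally printed (thop-style counters traverse
modules and do not see functional matmuls) — and can be included with
`include_attention_matmuls=True`. Serialized size is measured on
half-precision checkpoints; the working checkpoint format stays fp32 so
save→load→forward round-trips bitwise.

Nano-scale channel widths are not uniquely determined by the architecture
description, so they are calibrated once, as a design step, against the
baseline's published complexity (2.5 M / 6.5 G at 640), and then *frozen*
in `ArchConfig`; every ablation variant is measured from the same rule
set. The shipped calibration: baseline stem/early widths
(20, 40, 64, 64, 128, 128, 128, 256, 256); star backbone stem 24, widths
(24, 56, 96, 160), depths (2, 2, 6, 2); SCSA fusion hidden ratio 0.0625
with the stride-32 backbone site at hidden width 164 (capacity is cheap in
FLOPs at 20×20, which is what lets the SCSA swap cut FLOPs by ~1 G while
holding parameters level); upsampler groups 8. `width_mult` scales all
widths (quantised to multiples of 4) for desk-scale builds.

One inconsistency is noted rather than reproduced: a content-aware
upsampler strictly adds parameters and FLOPs over nearest-neighbour
interpolation, so the published dysample-only row (FLOPs *below* baseline)
is not derivable from the stated architecture; this package measures
+0.07 M / +0.12 G for that swap.

## Dataset protocol

Labels are YOLO-format text rows `class cx cy w h`, normalized, validated
on read with line-numbered errors. Five augmentation operators are
implemented: random rotation (label boxes become the axis-aligned hull of
the four rotated corners, clipped; boxes keeping <10% of their area are
dropped), Gaussian noise (σ = 10 grey levels), salt-and-pepper (density
0.02), brightness (±25%), and exposure (gamma ∈ [0.7, 1.4]) — parameter
defaults are package choices, config-exposed. Expansion is "original + 4
augmented copies" with operators drawn without replacement, giving exact
×5 per-class counts (a ×(factor+1) mode exists). Splitting is stratified
with largest-remainder rounding anchored to the whole-manifest totals
(7360 at 7:2:1 gives exactly 5152/1472/736); per-class remainders fill the
global quotas by largest fractional part. An image-screening utility
rejects non-RGB files, images under 200×200, and perceptual-hash
duplicates (8×8 average hash, Hamming ≤ 5).

## Synthetic scenes

The generator emulates the *structure* of field imagery: leaf-shaped
ellipses (random pose/size/green) with class-conditional lesion rendering
— none for healthy; few small brown spots (early leaf spot); many large
dark spots (late leaf spot); small orange pustules (early rust); dense
orange-red pustules with bronzing (late rust); chlorotic yellowing
gradient without spots (nutrient deficiency) — on a low-frequency
soil/foliage background, with exact bounding boxes. It does not emulate
leaf venation/texture detail, specular lighting, occlusion by other plant
organs, camera blur, or the intra-class variability of real disease
progression. Passing tests therefore demonstrate that the architecture,
losses, optimiser and metrics behave correctly and can fit structured
signal; they say nothing about accuracy on real peanut leaves.

## Training

The reference protocol (batch 4, 150 epochs, 640 input) is the default
configuration; desk-scale runs override it. Unstated training details
follow ecosystem convention: BCE classification, complete-IoU box loss and
distribution-focal loss (weights 7.5/0.5/1.5, normalized by positives),
SGD with momentum 0.9 and cosine decay (Adam available). Assignment is
deliberately minimal at desk scale: each ground-truth box maps to the
single cell containing its centre, on the level selected by normalized
box size (√(wh) < 1/8 → stride 8, < 1/4 → stride 16, else 32). All
randomness derives from one seed; repeated runs reproduce the loss trace
exactly on the same BLAS.

Repeated-run mean ± std (n−1 denominator, printed as `x.x ± y.y` in
percent) is computed over bootstrap resamples of the evaluation images
when a single checkpoint is evaluated with `runs > 1`; seed-wise
retraining is the expensive alternative the protocol supports through the
CLI.

## Desk-scale problem sizes

The test suite exercises the full-width models only for complexity
accounting (a single 640×640 forward per variant). Behavioural and
training tests run the same architecture at width multiplier 0.25 and
96-px inputs: the overfitting smoke (8 scenes, loss halving within 300
steps, typically ~60–90) and the end-to-end pipeline (16 scenes → ×2
expansion → 7:2:1 split → 2 epochs → bootstrap evaluation). These sizes
are the package's chosen smoke scale; conclusions about full-scale
accuracy require real data and longer schedules.

## Known limitations

- The numpy core is single-threaded BLAS-bound; full-width 640-px training
  is impractical (inference is seconds per image). The package's verifiable
  claims are architectural and behavioural, not throughput.
- The centre-cell assigner underuses large objects compared to
  task-aligned assignment; adequate for the smoke protocols, not tuned for
  competitive mAP.
- Bootstrap run-to-run spread measures evaluation-set variability only,
  not training stochasticity.
- The published dysample-only complexity row is not reproducible (see
  above); all other published complexity figures are.
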