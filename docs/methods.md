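# Methods

`ripedetr` re-implements a lightweight real-time detection-transformer
(RT-DETR) family for five-stage fruit-ripeness grading, together with the
synthetic data, profiling and evaluation machinery needed to study its
architecture on a single CPU.  This note documents the model, the design
choices made where the architecture was genuinely open, the synthetic-data
generator, and the limits of what the shipped tests demonstrate.

## The model family

The detector is end-to-end set prediction without non-maximum suppression:

* **Backbone** — a ResNet-18 "vd" feature extractor (three-conv stem,
  average-pool downsampling shortcuts, four residual stages at widths
  64/128/256/512) emitting a pyramid S3/S4/S5 at strides 8/16/32.
* **Encoder (AIFI)** — one transformer encoder layer over the S5 tokens
  only (width 256, 8 heads, feed-forward 1024, 2-D sinusoidal position
  embedding), switchable between standard multi-head self-attention and
  deformable attention.
* **Neck** — top-down + bottom-up cross-scale fusion (CCFM) at width 256
  with CSP-style rep-conv fusion blocks, switchable to a slim-neck
  (GSConv + VoVGSCSP) and/or a scale-sequence fusion (SSFF) branch.
* **Head** — IoU-aware query selection of 300 initial queries from the
  fused tokens, a 3-layer decoder with multi-scale deformable
  cross-attention (8 heads, 4 points/level), per-layer classification and
  box-refinement heads, contrastive denoising query groups during
  training, and Hungarian matching for the loss.

Four configuration switches reproduce the ablation grid: `pconv_block`
(partial-convolution residual blocks in the last three backbone stages),
`aifi_dat` (deformable attention in the encoder), `slimneck_ssff` (both
neck substitutions), and `inner_eiou` (the box-loss swap).

### Partial convolution

A PConv convolves only a contiguous slice of `cp = round(c/4)` channels
(the *first* `cp`, for contiguous memory access) and passes the remaining
channels through bit-identically.  Its cost is `h·w·k²·cp²`
multiply-accumulates — 1/16 of the dense convolution at ratio 1/4 — and
its approximate memory traffic `h·w·2cp` is a quarter of the dense
figure.  Inside a residual block only the second 3×3 convolution is
substituted: the first may change width or stride, which a channel-
preserving PConv cannot.  This one-of-two substitution is what makes the
per-stage compute saving equal across stages (each stage's two second
convolutions cost the same 0.94 GMACs at 640²) and reproduces the
published ablation deltas; substituting both convolutions would overshoot
the published parameter saving by ~50 %.

### Deformable attention (AIFI-DAT)

Queries remain at every S5 position; keys and values are gathered by
exact bilinear interpolation at reference points displaced by a learned
offset field.  Reference points sit at cell centres, normalised to
[-1, 1] with the edge-based convention (pixel `i` of an axis of length
`W` maps to `(2i+1)/W − 1`), and out-of-range samples clamp to the
border.  The offset network is the smallest design that fits the role:
depthwise 5×5 convolution → SiLU → 1×1 projection to two channels, tanh-
bounded to at most 2 grid cells per axis.  Attention logits receive a
relative-position bias interpolated from a learned 31×31 per-head table
at the continuous query–key displacement.  The reference grid keeps full
S5 resolution (`grid_factor = 1`; S5 is only 20×20 at 640², so no
downsampling is warranted) and offsets are shared across heads.

### Slim neck and SSFF

GSConv halves the width through a standard convolution, applies a
depthwise 5×5 to that half, concatenates and interleaves the halves with
a two-group channel shuffle (reshape → transpose → flatten, a fixed
invertible permutation).  A GS-bottleneck chains two GSConvs and adds a
depthwise shortcut; VoVGSCSP aggregates the bottleneck branch with a 1×1
bypass in a single concatenation.  SSFF resizes P4/P5 to the P3
resolution (nearest-neighbour, for determinism), projects the two resized
levels by 1×1 convolutions, stacks the three maps on a new scale axis and
fuses them with an *unpadded* 3×1×1 3-D convolution that collapses the
scale axis to depth 1 in one step; its output is added to the P3 branch,
where small objects live.  Collapsing by valid convolution rather than
padding-plus-pooling halves the branch's FLOPs and is what keeps the
ssff-mode totals at their published magnitude.

### Inner-EIoU

EIoU decomposes box regression into overlap (1 − IoU), centre distance
(squared centre offset over the squared enclosing-box diagonal) and a
width/height term (squared side differences over squared enclosing
sides).  Inner-IoU evaluates IoU on auxiliary boxes shrunk about their
own centres by a `ratio` (default 0.70, the sweep optimum; selectable
from {0.70, 0.75, 0.80, 1.10, 1.13, 1.15}), with the raw intersection
clamped at zero for disjoint auxiliary boxes.  The combined loss is
`L_EIoU + IoU − IoU_inner`, which reduces exactly to EIoU at ratio 1.
The inner auxiliary box applies to the training loss only, not to the
matching cost.

### Training objective

Per decoder layer (plus the encoder-selection head), Hungarian matching
under a focal-style class cost + L1 + GIoU with weights 2/5/2; the loss
is an IoU-weighted focal (varifocal-style) classification term, L1 on
normalised boxes and the configured IoU-family term, weighted 1/5/2.
Denoising groups (~100 jittered ground-truth copies, centre/size noise
bounded by 0.5, label-flipped negatives) are decoded behind an attention
mask that blocks any flow between groups or into the matching queries and
are supervised with the known assignment.  Optimiser: AdamW at the
published schedule (batch 4, lr 1e-4, 640², 100 epochs).

## Accounting convention (frozen)

Parameters are trainable scalar weights.  FLOPs are measured by tracing a
forward pass on a zero image: convolutions, linear layers and attention
matrix products count as multiply-accumulates (1 MAC = 2 FLOPs);
normalisation, activations, softmax, pooling/resizing and bilinear
sampling are free; a primitive of unknown kind aborts the profile rather
than being skipped.  PConv layers therefore cost exactly `h·w·k²·cp²`
MACs with free pass-through.  The convention was calibrated once against
the published 19.97 M / 57.3 G baseline and then frozen for every
ablation; the encoder-selection box head is applied to the 300 selected
tokens only (scores are computed for all tokens), which is both cheaper
and part of that frozen convention.  Remaining open internals (CSP hidden
width 128 with 3 rep-blocks; VoVGSCSP hidden 256, reduced to 160 at the
stride-8 fusion site; decoder depth 3 / 300 queries) were fixed by the
same calibration and recorded in the default configs.  All seven profiled
table rows land within ±1 % of the published figures.

## Synthetic scenes

The generator emulates outdoor orchard photography, not its photometry:
fruits are shaded ellipses with a radial gradient and a specular
highlight, leaves are elongated green blobs anchored on the fruit rim
(Bernoulli occlusion per fruit, ≤ ~50 % coverage so every fruit stays
well above 20 % visible), lighting multiplies the value channel
(sun 1.15 / overcast 0.85 / shade 0.65).  The five ripeness classes are
pairwise-disjoint hue intervals (green 0.26–0.36, yellow-orange
0.105–0.16, red 0.975–1.045 wrapped, deep dull red 0.90–0.96, dark brown
0.055–0.095 with Poisson-distributed blemishes), so the class is
recoverable from mean fruit hue — a self-consistency property the tests
verify at ≥ 95 % on unoccluded fruits.  Everything is a pure function of
(spec, seed); the 70/10/20 split floors the train and validation counts
and gives the remainder to test, the only rounding consistent with
2275/325/651 out of 3251.

What passing tests on these scenes do **not** show: robustness to real
texture, specular clutter, colour-calibration drift or heavy mutual fruit
occlusion.  The synthetic suite validates the machinery (shapes, losses,
convergence, bookkeeping), not field accuracy.

## Numerical and runtime choices

The tensor engine is a reverse-mode autodiff tape over numpy (float32
weights; convolutions as kernel-position loops over BLAS matmuls).
Gradients of every primitive are finite-difference-checked in the test
suite.  Batch normalisation uses batch statistics in training and running
averages (momentum 0.1, eps 1e-5) at inference; softmax subtracts the row
maximum; the inverse-sigmoid used in box refinement clamps at 1e-4;
IoU denominators carry a 1e-9 guard.  Degenerate (zero-area) boxes warn
and clamp rather than fail.

The smoke preset — the configuration the pipeline tests train — uses 16
scenes at 320×320 for 300 steps at batch 4 and learning rate 1e-3 on a
width-reduced model (widths ÷4, 60 queries, 2 decoder layers).  The
reduced widths are a deliberate choice so that a CPU-only run exercises
the full pipeline (denoising, matching, every loss term) in minutes; the
run reproducibly cuts the training loss by well over half.  Evaluation
uses 101-point interpolated AP (the integral itself does not prescribe a
discretisation), macro-averaged P/R/F1 reported at the F1-maximising
confidence threshold, and a confusion matrix in which unmatched
detections count against background.

## Known limitations

* No GPU path and no pretrained weights; parity with published detection
  accuracy on real data is out of scope by construction.
* The FLOP convention is one defensible choice among several; a counter
  that prices normalisation or sampling would shift totals by a few
  percent uniformly across configurations.
* Denoising uses one noise recipe; schedule-dependent variants (noise
  decay, group-count adaptation) are not implemented.
* The FPS harness measures this numpy implementation and is informative
  only — it says nothing about the latency of an optimised deployment.
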