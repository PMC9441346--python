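# Methods

## Problem and model

Retinal fundus photographs show the vessel tree as dark curvilinear
structures on a brighter disc-shaped field of view (FOV).  The package
segments vessels pixel-wise with an adversarially trained pair of
convolutional networks:

- **Generator G** — a U-shaped encoder/decoder mapping a preprocessed
  grayscale image to a two-class per-pixel softmax `S(x)`.  Four max-pooling
  and four upsampling levels with skip connections; nine convolution blocks
  along the U-path of which seven are SE-ResNet blocks (a residual block
  whose branch is gated per channel by squeeze-and-excitation: global
  average pool → FC `C→C/r` → ReLU → FC `C/r→C` → sigmoid, reduction
  `r = 2`) and two are plain Conv-BN-ReLU×2 blocks.  The assignment of
  the two plain slots is a free architectural choice; the default places
  them at the first encoder block and the bottleneck, and
  `GenConfig.plain_blocks` moves them anywhere.
- **Discriminator D** — scores whether a segmentation map is an expert
  annotation or a generator output: a 3×3 conv stem, four stages of
  [dilated-inception block → 1×1 Conv-BN-ReLU → 2×2 average pooling], a
  CBAM attention module (channel attention then spatial attention), global
  average pooling and a fully connected two-way softmax.  Each
  dilated-inception block runs three parallel 1×1-reduce → 3×3 branches at
  dilation rates 1, 2 and 4 (effective receptive fields 3, 5 and 9),
  concatenates, fuses with a 1×1 conv and adds the input back
  (Inception-ResNet style).  Average pooling is used throughout the
  down-sampling path.

Losses (`sadgan.losses`): the discriminator minimizes the real/fake cross
entropy `L_D = −(1−q)·log(1−D(S(x))) − q·log D(y)` with `q∈{0,1}` marking
provenance; the generator minimizes `L_seg = L_ce + λ_adv·L_adv` with
`L_ce = −Σ_{h,w,c} y_c log S(x)_c` and `L_adv = −log D(S(x))`,
`λ_adv = 0.1` by default.

## Training recipe

Alternating updates at batch size 1: the discriminator first (ground truth
with `q=1`, a detached generator output with `q=0`), then the generator with
gradients flowing *through* the frozen discriminator.  Adam for both
networks — generator lr `2.5e-4` with weight decay `1e-4`, discriminator lr
`1e-4`, β = (0.9, 0.999) — for 20 000 iterations by default (an "iteration"
is one image).  No learning-rate schedule.  The discriminator sees the
generator's soft positive-class plane, not a thresholded mask, so the
adversarial gradient reaches the generator.

Model selection: pooled ROC AUC on the validation split every
`val_every` iterations; the best and last checkpoints are both kept.

## Preprocessing

Four steps, in order: green-channel extraction (highest vessel contrast of
the RGB channels), per-image standardization followed by min–max rescale to
[0,1] (a bounded input is required before the next steps; a constant image
maps to zeros), CLAHE, and a gamma transform (default γ = 1.2).  CLAHE goes
through scikit-image's `equalize_adapthist`; `clahe_clip_limit` therefore
uses that library's normalized convention (default 0.01) with an 8×8 tile
grid.  Augmentation applies one random rotation (uniform in ±180°) and a
mirror flip jointly to image and masks; the image is warped bilinearly,
masks with nearest neighbor and re-binarized at 0.5 so ground truth stays
exactly binary.  The dataset splits 90/10 into train/validation by whole
image under the config seed (`|val| = round(0.1·N)`, so 40 images → 36/4);
when the dataset directory carries explicit `train/` and `test/` folders the
official split is honored instead.

## Numerical core

The networks run on a small NumPy reverse-mode autodiff engine
(`sadgan.nn`): tensors wrap `ndarray`s, convolution is im2col plus one BLAS
matmul (stride 1, zero same-padding, arbitrary dilation), pooling and
bilinear 2× upsampling have hand-written adjoints, and every op's gradient
is verified against central finite differences in the test suite.
Parameters are float32; Kaiming-normal initialization from a seeded
generator makes every build reproducible.  Adam uses the classic
L2-in-gradient weight-decay form.  Log arguments in all losses are clamped
at `epsilon = 1e-12`, so boundary scores 0/1 stay finite.

**Batch-norm statistics.**  At batch size 1, batch normalization reduces to
per-input (instance) statistics, and those are the only statistics the
weights are ever trained under.  Inference therefore also uses per-input
statistics by default (`BatchNorm2d.use_batch_stats_in_eval`); running
averages are still tracked and can be switched on, but they describe a
mixture of real and generated inputs the networks never saw, and in practice
they miscalibrate the discriminator's realness head.

**Cross-entropy reduction.**  The literal summed form is available
(`reduction="sum"`), but training defaults to the per-pixel mean so the loss
magnitude — and hence the published learning rates — behaves identically
across raster sizes.

**Discriminator head.**  The default head is a single scalar `p_real`
(FC + softmax); because the adversarial losses are written as sums over an
output grid, an optional fully convolutional head
(`DiscConfig.spatial_head`) produces a per-cell realness grid whose cells
are averaged in the losses.

## Default widths

Generator levels 16-32-64-128-256 (`base_channels = 16`), discriminator
stages 32-64-128-256 with attention reduction 8 and a 7×7 spatial-attention
kernel.  The widths are free parameters of the architecture; the defaults
are sized so that the full pipeline — including the single-image overfit
and adversarial smoke experiments — runs in minutes on one CPU core while
retaining far more capacity than the synthetic fixtures require.  All widths
are configurable for full-scale runs.

## Synthetic phantoms

`sadgan.phantom` renders the structure the method assumes: a centered FOV
disc (radius `min(H,W)/2·(1−fov_margin_frac)`), `n_trees` recursive
bifurcating vessel trees whose segment width decays geometrically with
branching level (children deviate ≈ ±25° from the parent direction, branches
are pruned at the FOV boundary so each tree's raster stays 8-connected), a
green channel equal to a background level minus a vessel-contrast term,
a smooth radial illumination falloff and Gaussian pixel noise.  The vessel
mask is rasterized hard, so ground truth is exactly binary; the rendered
vessel profile is slightly blurred for photographic-looking edges.  Phantoms
are bit-deterministic given the spec seed.

What phantoms do **not** model: physiological caliber/tortuosity statistics,
pathologies, inter-observer annotation disagreement, color/illumination
variation between cameras.  Passing tests on phantoms demonstrates that the
architecture, losses, training loop and metrics behave as specified — not
that the defaults reach any particular accuracy on real fundus data; the
full-scale recipe for the public datasets is in
`scripts/reproduce_benchmarks.py`.

## Degenerate inputs and tie-breaks

Constant images normalize to zeros and pass CLAHE unchanged; metrics flag
empty denominators (no positives in the FOV) as NaN instead of raising;
pixels whose probability exactly equals the threshold count as positive;
max-pooling routes gradients to the first maximum on ties; reflect padding
splits evenly with the odd pixel to the bottom/right and the crop record
inverts it exactly.

## Known limitations

- CPU-only: a full 20 000-iteration run at DRIVE resolution is an
  overnight-scale job; the engine exists for correctness and desk-scale
  experiments, not throughput.
- The evaluation protocol pools FOV pixels across images before computing
  metrics (per-image rows are also reported); protocols that instead average
  per-image metrics yield slightly different numbers.
- Whether CHASE_DB1's two observer annotations should be merged is left to
  the user via the loader's `label_suffix` argument.
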