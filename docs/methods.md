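# Methods

## Problem and pipeline

Capsule-endoscopy (CE) frames show a roughly circular field of view (FOV) of
the small-bowel mucosa on a black background. Intestinal content — bile,
bubbles, food debris — occludes the mucosa and makes frames hard or
impossible to evaluate. `capclean` scores each frame on a four-category
ordinal cleanliness scale (Poor=1, Fair=2, Good=3, Excellent=4) through the
following stages:

1. **FOV detection.** Pixels whose maximum channel intensity exceeds a
   threshold (default 10/255) form the candidate recording area; the largest
   connected component is kept and holes are filled so dark structures inside
   the bowel (lumen hole, shadows) stay inside the mask. A precomputed mask
   PNG can be supplied instead.
2. **Patch lattice.** 64×64 patches at stride 32 in both directions (50%
   overlap per axis; each interior pixel lies in 4 footprints). A patch is
   admitted only if *all* its pixels are inside the FOV, because annotations
   are defined as *completely* clean or *completely* dirty. Patches are
   normalised by 1/255 with no other preprocessing.
3. **Patch classification.** A light-weight CNN assigns each patch a
   probability of containing intestinal content ("dirty").
4. **Pixel probabilities.** Patch probabilities are planted at the patch
   centres (anchor + (32,32)) and bilinearly interpolated to every FOV pixel.
5. **Scoring.** The FOV-mean dirty probability is mapped to the ordinal scale
   through three calibrated thresholds t1 < t2 < t3 (mean < t1 → Excellent;
   ≥ t3 → Poor; a mean exactly on a threshold falls on the cleaner side of
   the dirtier category, i.e. t1 itself is Good).
6. **Calibration and validation.** Thresholds are learnt against expert
   ratings by maximising single-rater consistency ICC, and the method is
   validated against human raters with linearly weighted kappa and ICC(A,1).

## Architectures

Both classifiers share one head: flatten → dense(128) + LeakyReLU (slope
0.01) + batch norm → dense(2) + softmax.

The light-weight network has four convolutional blocks. Block 1 holds two
stride-1 3×3 convolutions and one stride-2 3×3 convolution; blocks 2–4 hold
one stride-1 and one stride-2 convolution. Every convolution is followed by
LeakyReLU and batch normalisation; there is no pooling and no dropout. Four
stride-2 layers map the 64×64 input to 4×4. Per-convolution output channels
are (48, 48, 48 | 64, 64 | 96, 128 | 192, 320), giving a total of exactly
1,708,610 parameters counting weights, biases and the four batch-norm terms
per channel (scale, shift, moving mean, moving variance). The published
architecture figure from which the channel widths originate is not available
in machine-readable form; the widths used here are a monotone block-structured
assignment chosen to reproduce the published total exactly, which is the
binding constraint. A `width_multiplier` scales all channel counts so reduced
variants (e.g. 0.25 → 231,698 parameters) can be trained on a CPU in minutes.

The comparator is the standard VGG-16 convolutional base (13 3×3
convolutions, five 2×2 max-pools, 64×64×3 → 2×2×512) with the same head:
14,714,688 + 263,042 = 14,977,730 parameters.

## Network runtime

No deep-learning framework is used: the layers (convolution with stride and
"same"/"valid" padding, batch norm, LeakyReLU, max-pool, dense, softmax) are
implemented in numpy with full reverse-mode gradients, validated against
central-difference numerical gradients. Convolutions are computed as a sum
over kernel offsets of strided-slice matrix products, keeping both passes in
BLAS. Numerical choices: float32 arithmetic; He initialisation; batch-norm
eps 1e-3 and moving-statistics momentum 0.9 (lower than the common 0.99 so
inference statistics track training within a few dozen steps at the short
schedules used here); softmax fused with the cross-entropy loss so the
backward pass is seeded at the logits with (p − y)/N.

Training uses batch size 16 and learning rate 5e-4; Nadam (Dozat's
Adam-with-Nesterov formulation) for the light-weight network and SGD with
momentum 0.9, decay 0, for VGG fine-tuning, which proceeds in two stages:
stage 1 trains only the head on frozen-base features (the base is evaluated
once in inference mode, so its parameters and batch-norm statistics are
bit-identical afterwards), stage 2 unfreezes everything. After each epoch the
model is kept only if validation accuracy improved; `max_epochs` defaults to
100 with patience 15 (values chosen here; the training procedure names these
hyperparameters but they are otherwise unconstrained). Training is
deterministic for a fixed seed.

Evaluation reports accuracy, sensitivity and specificity (percent, dirty =
positive class, probability threshold 0.5) and the Matthews correlation
coefficient; zero denominators flag the metric undefined (MCC falls back to 0
by the usual convention).

## Data partitioning

Cross-validation folds are assigned at the *image* level (all patches of a
frame inherit its fold) to prevent leakage between train and test patches of
the same frame; fold sizes differ by at most one image. Class imbalance is
capped by random undersampling of the majority class to floor(1.1 ×
minority) whenever it exceeds that bound ("exactly 10%" excess; flooring
never exceeds the stated bound — the rounding direction is a package choice
as the rule's rounding is unspecified). Undersampling precedes the 80–20
train/validation split, matching the order in which the procedure is
described; the split is applied at patch level within the training images,
and removal is global rather than stratified per frame.

## Pixel-probability interpolation

"One of the central pixels" of a 64×64 patch is fixed to offset (+32, +32)
from the top-left anchor — any of the four central pixels is defensible; one
is fixed for reproducibility. On circular FOVs the planted centres form a
ragged subset of a regular stride-32 lattice: missing lattice nodes are
filled with the value of the nearest existing centre (nearest in lattice
index space via an exact Euclidean distance transform), and pixels outside
the bounding box of the centres take the clamped (nearest-edge) value. This
keeps every value inside [min, max] of the patch probabilities and defines a
probability for *every* FOV pixel, so the frame mean is always well defined.
Constant inputs short-circuit to the exact constant. The non-constant path
agrees with a brute-force per-pixel bilinear oracle to < 1e−9 on full
lattices.

## Threshold calibration

The calibration data are per-frame mean probabilities plus ordinal scores
from two experts. The objective is the single-rater consistency ICC,
ICC(C,1), of the 3-rater table (method categorisation + both experts);
consistency rather than absolute agreement rewards a monotone relationship
even when the experts' calibration is offset from the method's. A
pairwise-average variant (mean of the two method-vs-expert ICC(C,1) values)
is available behind `objective="pairwise"`; the 3-rater reading is the
default.

The search is an exhaustive grid search over ordered triples at resolution
0.01 (≈1.6×10⁵ candidates), ties broken by the lexicographically smallest
triple. It is exact and fast because the method column for thresholds
t1 < t2 < t3 is 4 − a − b − c with binary indicators a ≥ b ≥ c pointwise,
which makes every ANOVA sum linear in per-grid-point statistics; the whole
search costs O(n·G) after an O(n·G) precomputation rather than O(n·G³).
The vectorised objective agrees with the direct ANOVA implementation to
1e−15 and with brute-force search on coarse grids.

Generalisation is assessed by grouped 5-fold cross-validation in which all
frames of a video (one patient) share a fold: thresholds are learnt on four
folds and applied to the fifth, so every frame receives exactly one
out-of-fold score from thresholds that never saw it. The per-fold triples'
mean and standard deviation are the reported calibration estimates — exposed
through the `ThresholdCalibration` model object, whose `fit()` returns a
results object with `params` (fold-mean triple), `bse` (per-threshold fold
SD), agreement diagnostics and a `summary()` table.

## Agreement statistics

Weighted kappa uses linear weights w_ij = 1 − |i−j|/(k−1); quadratic weights
are provided only as an off-default option since they systematically inflate
agreement. The 95% CI is kappa ± 1.96·SE with the Fleiss–Cohen–Everitt
large-sample standard error (verified to machine precision against
statsmodels' implementation). ICC uses the two-way mean-square decomposition
with McGraw–Wong F-based confidence intervals (Satterthwaite degrees of
freedom for the absolute-agreement form), verified against pingouin on random
tables. Ordinal scores are treated as interval numbers, as standard
reliability software does. Missing ratings are rejected, not imputed.
Published point estimates are reproducible to ±0.005 when the corresponding
rating tables are supplied; CI bounds depend on the SE estimator and are
best-effort.

## Synthetic data

The generator emulates the *structure* of CE data, not its photometry:
576×576 frames, circular FOV of radius 280 on black, pinkish-red mucosa from
smoothed random lattices (value noise), optional darkened lumen hole, and
three content types — smooth yellow-green bile blobs, bright-rimmed bubble
clusters, high-frequency brown debris — painted until the realised dirty
fraction is within 0.05 of target, with exact ground-truth masks. Patch
labels follow the annotation protocol: dirty only if the whole footprint is
content, clean only if none is, mixed patches omitted. Rating studies draw
frame means uniformly on [0,1], score them with a true threshold triple and
flip each expert's score to an adjacent category with a controllable
probability. Every generator is a pure function of its seed.

What passing tests on this data do and do not show: the classes are
separable mainly by colour, so a ≥90%-accuracy result on synthetic patches
demonstrates that the architecture, gradients, training loop and pipeline
composition work — not that the network reaches its published accuracy on
real CE imagery, where texture and lighting matter far more. Likewise the
threshold-recovery simulations validate the calibration machinery under the
scoring model's own assumptions (uniform means, adjacent-category noise),
not the ecological distribution of real frame means.

## Problem sizes used in the test suite

The suite trains the width-0.25 network for 10 epochs on ~2,000 synthetic
patches (held-out accuracy ≥ 90% required), runs threshold recovery at 200
frames × 20 seeds × grouped 5-fold CV (mean recovery within ±0.05 of
(0.42, 0.66, 0.94) and mean per-fold SD < 0.05), and checks the
interpolation oracle on the full 17×17 lattice of a 576×576 frame. These
sizes were chosen so the whole suite runs on a single CPU in minutes while
still exercising every stage at full frame resolution.

## Known limitations

- Published classification accuracies (e.g. 95.23% test accuracy) and the
  learned-threshold values on clinical data require the authors' released
  patch/frame datasets and long training; the repository documents the
  recipe (train per image-level fold with the hyperparameters above, then
  calibrate on the validation videos) but does not assert those numbers.
- The channel widths of the light-weight network are an exact-total
  reconstruction, not a transcription of the unavailable figure.
- The FOV detector assumes a bright-enough recording area; an all-black
  frame raises a "no recording area" error rather than guessing.
- Kappa/ICC confidence intervals match the named estimators; other software
  may use bootstrap or jackknife variants and disagree in the bounds while
  agreeing in the point estimates.
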