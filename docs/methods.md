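# Methods

## Problem and model

`painattn` classifies still face images into five pain-intensity
categories derived from the Prkachin–Solomon Pain Intensity (PSPI) score,
an integer 0–10 composed from facial Action Unit (AU) intensities. The
consolidation is fixed: 0 → *No Pain*, 1 → *Mid Pain*, 2–3 → *Moderate
Pain*, 4–6 → *Very Pain*, 7–10 → *Severe Pain* (the scale's descriptor
strings place "Very Pain" below "Severe Pain"; we keep them verbatim).
PSPI values are accepted only as integers — the bins are integer ranges,
and rounding real values would silently resolve ambiguous points such as
3.5 — so non-integers are rejected.

The classifier is a dual-attention CNN. A four-block 3×3 convolution
backbone (channel plan 32→64→128→128, BatchNorm + ReLU per block, 2×2
max-pooling after blocks 1–3) maps a normalized 64×64×3 face to a
128×8×8 feature tensor F. Two attention stages refine it:

* **Multi-head spatial attention.** Each of K = 4 heads computes a
  per-pixel gate A_i = σ(conv1×1(ReLU(conv1×1(F)))) and the refined map is
  the *unweighted sum* F′ = Σ_i A_i ⊙ F. No averaging is applied, so with
  all head weights at zero each gate is σ(0) = 0.5 and F′ = (K/2)·F; this
  fixed point is asserted in the tests and documents the block's neutral
  behavior.
* **Triple-pooling channel attention.** Per-channel average, maximum and
  population standard deviation of F′ are concatenated in the fixed order
  [avg ‖ max ‖ std] into a 3C descriptor z, which drives a two-layer
  squeeze-and-excitation gate s = σ(W2 δ(W1 z)) with reduction ratio
  r = 8; F″ = s ⊙ F′. Std-pooling uses the population (ddof = 0) variance
  with ε = 1e−6 inside the square root so its gradient is finite at zero
  variance.

The classifier flattens F″ — 8192 values under the default plan — through
FC(256) and FC(128) blocks (BatchNorm, ReLU, dropout 0.5) to 5 logits.
Flattening, not global average pooling, is the default because the
8192-dimensional bottleneck is an architectural anchor of the design; a
`global_avg_pool` flag provides the GAP variant. Both attention stages can
be disabled independently without changing any output shape, which yields
the ablation grid (baseline / +spatial / +channel / +both / full).

## Training

Optimization is AdamW — the decoupled update
θ ← θ − η·m̂/(√v̂ + ε) − η·λ·θ — with label-smoothed cross-entropy

L = (1 − α)·(−log p_y) + α·(1/K)·Σ_i (−log p_i),  α = 0.1 by default.

The learning rate ramps linearly over 5 warm-up epochs to η₀ = 1e−3, then
follows cosine annealing η_t = η_min + ½(η₀ − η_min)(1 + cos(πt/T)) down
to η_min = 1e−6 at the final epoch. Default batch size 32, weight decay
λ = 1e−4, early stopping on validation loss with patience 15, and the
best-validation weights are restored. An explicit loss-side L2 term
(λ/2)·‖θ‖² exists behind `TrainConfig.loss_l2` but is off by default:
with decoupled decay active it would penalize the weights twice.

Where the literature on this architecture reports conflicting settings
(learning rate 1e−3 vs 1e−4, weight decay 1e−4 vs 1e−2, dropout 0.4 vs
0.5, one seed vs a seed list), we default to η₀ = 1e−3, λ = 1e−4, dropout
0.5 and use the seed list (42, 123, 999) for repeated runs and 42 for
single runs; every value is overridable in `TrainConfig`.

The network and its gradients are implemented on a small reverse-mode
autodiff engine (`painattn.autodiff`) written for this package:
convolution runs as one BLAS tensordot per kernel tap, and every
primitive's gradient is tested against central differences. Training is
bit-reproducible for a fixed seed and thread count: shuffling, dropout
masks, and augmentation draws all consume a single `numpy` generator
seeded from `TrainConfig.seed`.

## Data handling

Splits are subject-wise: a greedy bin-packing pass (subjects sorted
largest-first, seeded shuffle breaking ties, each assigned to the
partition with the greatest remaining deficit against the 0.72/0.08/0.20
targets, with per-class deficits breaking near-ties) guarantees that no
identity appears in two partitions. The published exact partition sizes
of the original protocol depend on an unpublished subject structure; the
contract here is ratio tolerance (±3 points at ≥20 subjects) plus zero
leakage. Subject-wise k-fold CV spreads subjects so fold sizes stay
within one subject of each other. A record-level split exists only behind
an explicit `unsafe=True` flag.

Training augmentation is horizontal flip (p = 0.5), rotation within ±15°
(bilinear, corners filled with 0 before normalization), color jitter
(brightness/contrast/saturation 0.2, hue 0.1), then ImageNet
normalization (μ = (0.485, 0.456, 0.406), σ = (0.229, 0.224, 0.225)).
Evaluation preprocessing is resize + normalize only and is bit-stable.
Offline class balancing (`balance_offline`) synthesizes flipped/rotated/
brightness-adjusted (±20%) copies of minority-class images until counts
are equal; copies are flagged `augmented=1` and inherit their source
subject id so subject-wise splits keep them with their subject. The
per-batch jitter policy and the offline balancing pass are toggled
independently, since they serve different purposes (regularization vs
class balance).

## The synthetic benchmark

Real clinical facial-pain datasets are access-restricted, so the package
ships a procedural generator whose statistical structure mirrors the
published protocol: ~1500–6000 images, five near-balanced classes,
dozens of subjects with per-subject appearance variation, and
pain-graded facial deformations. Each subject is a deterministic function
of (master seed, index): head ellipse geometry, eye spacing and size,
brow height, mouth width, and skin tone are drawn within documented
bounds. Pain deformations follow the AU cues of the PSPI construction and
scale *linearly* with PSPI/10 — brow drop up to 3.5 px (AU4), eye
aperture down to 0.35× (AU6/7), nasolabial darkening (AU9/10), mouth
opening up to 5 px (AU25/26). Linearity is the simplest monotone scheme
and makes adjacent categories naturally confusable while keeping the
extremes separable; a pixel-distance 1-NN classifier reaches ≥80%
five-class accuracy on noise-free renders, so the benchmark is learnable
by construction. Nuisance variation adds a linear illumination gradient
(amplitude 0.15, random direction), a small translation (±2 px) and
additive Gaussian pixel noise (σ = 0.02). Images are written as 8-bit
PNGs with round(255·x) quantization, so a written-then-reloaded dataset
is byte-identical across runs of the same seed.

`signal_mask` returns the ground-truth pain-informative regions (brow/eye
band and mouth/nasolabial box, covering the full deformation range).
This is what makes the Grad-CAM localization check quantitative: the mask
covers ≥95% of the pixels that change between the neutral and
maximum-pain render of a subject.

What the generator does **not** emulate: photorealistic texture, 3-D
pose, occlusion, spontaneous (non-posed) expression dynamics, or
demographic appearance variation. Passing the end-to-end tests therefore
demonstrates that the pipeline, architecture and training loop work and
that attention localizes the informative regions on a controlled
benchmark — it is not evidence about accuracy on real clinical data.

## Evaluation

The metric panel is: confusion matrices (raw and row-normalized),
accuracy, per-class and unweighted-macro precision/recall/F1, Cohen's κ,
multiclass MCC, macro/micro one-vs-rest ROC AUC (rank statistic with
midpoint tie handling), and expected calibration error over B = 15
equal-width right-closed confidence bins (configurable; 15 is a common
convention). Fold-level statistics use the two-sided t interval
x̄ ± t_{0.975,n−1}·s/√n with the sample (n−1) standard deviation, and
paired t-tests on per-fold differences; zero-variance differences raise
an error rather than returning NaN. Standard metrics delegate to
scikit-learn/scipy; the test suite checks every one against an
independent brute-force implementation (pair counting for AUC, marginal
arithmetic for κ, covariance form for MCC, explicit binning for ECE).

Grad-CAM targets the attention-refined map F″ by default (configurable to
any block): channel weights are the spatial means of the target-logit
gradient, the map is ReLU-combined, bilinearly upsampled and min–max
normalized; a constant raw map degenerates to all-zeros with a warning.
A caveat discovered during validation: the classic spatial-mean
weighting is only faithful when the classifier is (near)
position-invariant. Under the default *flatten* head the gradient varies
per spatial cell, and averaging it can cancel opposing signs — across
training seeds the resulting maps range from sharply localized to
background-diffuse even when test accuracy is stable. `grad_cam`
therefore also offers `method="elementwise"` (per-position
gradient–activation product, ReLU-combined), which stays faithful under
flatten heads; the two methods coincide exactly for a
global-average-pooling head (asserted in the tests). Localization
analyses should prefer the element-wise map; the classic map remains the
default for comparability. Saliency is the max-over-channels absolute
input gradient. Overlays alpha-blend a perceptually uniform colormap
(viridis, named in config) over the de-normalized image.

## Desk-scale study conditions

The acceptance-level end-to-end runs use sizes chosen for a single CPU:

* **Main run:** 60 subjects × 25 images (1500 images), subject-wise
  72/8/20 split, 15 epochs, batch 32, seed 42, channel plan 16→32→64→64.
  The narrowed plan (the default 32→64→128→128 is four times the
  compute) is the package's desk-scale choice; the 8192-flatten anchor is
  verified separately on the default plan. Held-out-subject accuracy must
  reach ≥0.85.
* **Attention ablation:** full configuration (both attentions + label
  smoothing) vs attention-free baseline on 60 subjects × 10 images,
  10 epochs, five fixed seeds (42, 123, 999, 7, 2024); the check asks
  the full model to score ≥ the baseline in at least 4 of 5 seeds. On
  this benchmark the check is **not satisfied**: the plain CNN matches
  or exceeds the full configuration in most seeds, both at this scale
  and at the 1500-image/15-epoch scale where both models sit at a
  ≈0.95+ accuracy ceiling. The schematic faces are separable enough
  that convolution alone saturates performance; label smoothing also
  slows the full model's accuracy convergence in short runs. The
  benchmark therefore demonstrates attention's *localization* benefit
  (below) but not an accuracy advantage; accuracy gains from attention
  should be expected only on data with richer nuisance structure.
* **Localization:** on the main run's correctly classified high-pain
  (PSPI ≥ 7) test images, the CAM mean inside the subject's signal mask
  must exceed the outside mean for ≥80% of images, and the mean CAM mass
  fraction inside the mask must beat the mask's area fraction. The
  harness uses the element-wise CAM weighting (see above) so the check
  measures model attribution rather than the artifacts of spatial
  gradient averaging; the classic map's score is reported alongside by
  the reproduction script.

## Known limitations

* The autodiff engine supports exactly the primitives this architecture
  needs; it is not a general-purpose framework (no higher-order
  gradients, no GPU).
* Bit-reproducibility holds for a fixed BLAS thread count; differing
  thread counts can change floating-point summation order.
* The synthetic benchmark's simplicity means the attention stages add
  no measurable accuracy over the plain CNN there; the benchmark
  validates mechanics and localization, not architecture rankings.
* k-fold stratification is approximated at the subject level; exact
  class balance inside every fold is not guaranteed for skewed subjects.
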