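# Methods

This note documents the model implemented by `neutrokd`, the choices made
where the design was genuinely open, the synthetic data the test suite runs
on, and the limits of what those tests demonstrate.

## The distillation objective

A frozen teacher network produces logits `z_t`; the student produces `z_s`.
Both are softened at temperature `T` (default 4.0).  The per-sample
distillation term is the temperature-scaled forward KL divergence
`T²·KL(p_t ‖ p_s)`; the `T²` factor keeps gradient magnitude invariant to
the choice of temperature, so the no-weighting configuration reduces exactly
to classical knowledge distillation.  The student's logit gradient of this
term is `T · w · (softmax(z_s/T) − p_t) / N`.

Each sample's weight comes from the neutrosophic decomposition of the
*teacher's softened* distribution: truth `T = p_(1)`, falsity `F = 1 − T`
(an exact identity, maintained by construction), and indeterminacy either

* margin mode (default): `I = 1 − (p_(1) − p_(2))`.  A tie between the two
  top classes gives `I = 1` — the consistent limit of the formula — so a
  maximally ambiguous teacher is down-weighted hardest.
* entropy mode: `I = −(1/log C)·Σ p_c log p_c`, with `0·log 0 := 0`.  The
  normalization by `log C` makes the logarithm base irrelevant; natural log
  is used throughout (KL, cross-entropy, entropy).

The weight is `clamp(σ(k·(M − τ)), w_min, w_max)` with `M = 1 − I`:
sigmoid first, then clamping to the configured bounds (they are bounds on
the *weight*, not on the sigmoid argument).  Defaults: `k = 8`, `τ = 0.15`,
`w ∈ [0.10, 1.00]`.

The full objective is `α·L_CE + (1−α)·L_NKD`, where the cross-entropy is
computed from temperature-1 student probabilities (the standard convention)
and `α` decays linearly per epoch from 0.90 to 0.70, constant within an
epoch.  A one-epoch run uses `α_start`; the fixed-α ablation holds `α_start`
throughout.  All logarithms are floored at `ε = 1e−12`.

Two reference student variants are included: a CE-only student (no
distillation) and a *fuzzy* student, in which the teacher's softened
probabilities are power-transformed `p^γ / Σ p^γ` before the KL.  The
exponent γ is configurable with default 2.0 — the smallest integer power
that emphasizes dominant probabilities — and the transformed vector is
renormalized so the KL remains a divergence between distributions.

## Networks and optimization

No deep-learning framework is assumed: `neutrokd.nn` implements convolution
(im2col/GEMM), batch normalization, max/global-average pooling, linear
layers, and residual blocks with explicit forward and backward passes in
single-precision NumPy, verified against central finite differences.  Two
backbone pairs are registered:

* `resnet50` / `resnet18` — the full-scale reference pair (Bottleneck and
  BasicBlock stacks with the standard stage widths; feature widths 2048 and
  512).  No pretrained weights are available to this package, so every
  backbone is He-initialized deterministically from its build seed and
  `pretrained=True` raises.
* `tiny_cnn_large` / `tiny_cnn_small` — a 4-block (16/32/64/64) versus
  3-block (8/16/32) CNN pair preserving the teacher > student capacity
  relation; these train to well above chance on the synthetic task in
  minutes on one CPU and are the default desk-scale pair.

Optimization follows the reference protocol: AdamW (decoupled weight decay
10⁻⁴ applied to convolution/linear weights only), batch size 16, and a
ReduceLROnPlateau scheduler monitoring validation loss with factor 0.5 and
patience 3 (the protocol names the scheduler; factor/patience are this
package's choice).  Gradient accumulation is supported (`dlogits` scaled by
1/steps); `mixed_precision` stores the precomputed input tensors in half
precision (a memory measure — parameters and gradients stay float32) and is
off by default so runs are bit-reproducible.  Model selection keeps the
checkpoint with the best validation accuracy, which guards against
last-epoch overfitting on small splits.  The teacher participates in
student training only through inference-mode forward passes; a parameter
checksum (weights plus batch-norm running statistics) is used in tests to
prove it is never touched.

## Preprocessing

CLAHE is applied to the luminance channel of a LAB decomposition (avoiding
hue distortion, common fundus practice) at full input resolution, before
resizing.  The implementation follows the classic tile-grid formulation in
which the clip limit is a multiple of the mean tile histogram height — the
convention in which the reference parameters (clip 2.0, 8×8 grid) are
stated: 256-bin tile histograms are clipped at
`max(int(clip·area/256), 1)`, the excess is redistributed uniformly, tile
mappings use a midpoint-CDF lookup, and per-pixel values bilinearly
interpolate the four neighbouring tile mappings.  A uniform image passes
through unchanged (to within colourspace round-trip quantization), and the
low-contrast synthetic images measurably gain local contrast (mean 8×8-tile
standard deviation strictly increases) — both are tested.

After CLAHE: optional training-time augmentation (horizontal flip p = 0.5,
rotation ±15°, brightness/contrast/saturation jitter ±0.1 — magnitudes are
this package's defaults, all configurable, drawn from a caller-supplied
generator so augmentation is reproducible), then bilinear resize to the
target size and per-channel ImageNet normalization (mean 0.485/0.456/0.406,
std 0.229/0.224/0.225, stored in config rather than hard-coded).  The
evaluation-time pipeline (CLAHE + standardize, no augmentation) is
deterministic.  Resize-then-normalize order is used; since normalization is
per-pixel affine, the two orders agree exactly anyway.

## Synthetic data

`neutrokd.synthetic` emulates the structure of a balanced 7-class UWF
dataset (seven classes × 100 images in the real protocol): a dark-red
radial fundus background inside a circular aperture, smooth low-contrast
texture (so CLAHE is exercised nontrivially), a bright elliptical
optic-disk analogue, dark random-walk vessel curves, and one
class-conditional lesion motif per class in a fixed order — bright blobs,
dark blobs, *none* (the healthy analogue, class index 2), diffuse haze,
peripheral arc, central ring, streaks.  Defaults: 7 classes × 100 images,
96 px, Gaussian pixel noise σ = 0.08·255, class-separability 0.8 scaling
lesion contrast.  One `numpy` generator derived from the seed drives the
whole dataset, so the same spec and seed reproduce it bit-for-bit.

What it does not emulate: photorealistic retinal texture, inter-class
visual similarity structure (e.g. the healthy/uveitis confusability of real
UWF data), image-quality and demographic covariates, or class imbalance.
Tests passing on this generator demonstrate that the pipeline's mechanics
and the loss's mathematics are correct — not that the method's published
performance transfers to real fundus images.

## Evaluation

All one-vs-rest metrics (sensitivity/recall, specificity, precision, F1,
AUC) are macro-averaged with equal class weight; on balanced test sets
macro recall equals accuracy exactly, which is why those columns coincide
in balanced-protocol reports.  Classes absent from a fold's test split are
excluded from macro averages with a logged warning.  Expected calibration
error uses 15 equal-width bins on the top-probability confidence.  The
primary protocol is stratified 5-fold cross-validation (fold assignment
seeded, default 42); the cumulative confusion matrix is the element-wise
sum over folds, and aggregates are reported as mean ± sd with t-based 95%
intervals (`mean ± t₀.₉₇₅,ₙ₋₁·sd/√n`).  Paired fold-wise model comparisons
use the paired t-test and the Wilcoxon signed-rank test with the *exact*
null distribution — at five folds the normal approximation is meaningless,
and the attainable two-sided p-values are multiples of 2/2⁵.  The teacher
is retrained inside each fold on that fold's training data only, so no
test image leaks into its own fold's teacher; the validation split used for
checkpoint selection is carved from the fold's training portion (15%).

Classical baselines: LBP (radius 1, 8 interpolated circular neighbours,
plain 256-code variant, neighbour ≥ centre convention; the radius-wide
image border, where neighbours are undefined, is excluded from the
256-bin normalized histogram) and HOG (single centred 128-px window,
16-px blocks, 8-px stride, 8-px cells, 9 orientation bins, L2-Hys — 8100
dimensions), classified by standardize-then-SVM pipelines (C = 1,
gamma = 'scale', balanced class weights, probability outputs) with the
scaler fit on training folds only.  A single centred HOG window is used
rather than dense multi-window pooling — the simplest geometry consistent
with the stated 8100 dimensionality.

## Explainability

Grad-CAM++ is computed from the pre-softmax logit of the target class (the
standard choice), at the last residual block of the third stage for ResNet
backbones and, with a logged warning, the last convolution for the tiny
CNNs.  Pixel weights follow the original higher-order-gradient formulation
`α = g²/(2g² + Σ A·g³)`, maps are ReLU-ed, bilinearly upsampled and min-max
normalized with an all-zero guard.  Each explained image is annotated with
the *student's* confidence, normalized entropy, and margin indeterminacy —
the explained model's own distribution, since the analysis concerns the
distilled student alone.

## Desk-scale protocol and problem sizes

The test suite and `scripts/acceptance.py` use the tiny CNN pair on the
synthetic task at 96 px with 20 images per class.  Two schedule choices
matter and are deliberate:

* The tiny CNNs need a larger learning rate than the full-scale default:
  desk-scale runs use 3·10⁻³ (the full-scale default 3·10⁻⁴ barely moves
  the 6k-parameter student in 15 epochs).  The teacher is trained for 30
  epochs — to convergence — before distillation, because the method
  presupposes a converged teacher: an undertrained teacher emits
  near-uniform soft targets whose indeterminacy saturates, clamping every
  weight to `w_min` and degenerating NKD into a down-weighted CE.
* The seed-robustness comparison trains students for 15 epochs on one fixed
  split with one shared teacher, varying only the student seeds.  In this
  mid-training regime the distillation signal acts as a regularizer and the
  NKD student's median hold-out accuracy matches or exceeds the CE-only
  student's.  At full convergence on this easy synthetic task the ordering
  becomes seed-dependent (ties and small inversions occur) — a genuine
  limitation of the desk-scale emulation, not a property claimed about real
  data.  The acceptance script therefore trains its students to convergence
  (25 epochs) and reports whatever it measures, including the signed
  NKD-minus-CE accuracy difference.

The ablation harness runs all six loss variants plus the teacher reference
on one fixed stratified 80/20 split with one shared teacher, so arms differ
only in their distillation configuration; the split checksum and per-epoch
mean sample weights are recorded.

## Known limitations

* NumPy training is CPU-bound; the full-scale ResNet-50/18 protocol at
  224 px is implemented and shape/gradient-correct but not practical to
  train here, and no pretrained initialization is available.
* The synthetic task is far easier and more homogeneous than UWF imagery;
  absolute metric values from the desk-scale runs are not comparable to
  results on real data.
* Wilcoxon p-values at n = 5 folds have a coarse attainable set; they can
  flag only large, consistent differences.
* Grad-CAM++ quadrant localization is validated on a constructed cue, not
  on clinical lesions.
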