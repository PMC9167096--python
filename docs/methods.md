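# Methods

This note records the models and procedures `nevuscope` implements, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical and design decisions a maintainer would want
written down.

## Synthetic data

### Lesion images

`generate_lesion_image` renders a rotated filled ellipse of a pigment color
on a skin-tone background (8-bit RGB, row-major, 0-based coordinates, pixel
centers at integer coordinates), overlays artifacts, then adds i.i.d.
Gaussian channel noise clipped — not wrapped — to [0, 255]. The truth mask is
the exact point-in-ellipse test on pixel centers and is independent of
artifacts and noise. Artifacts emulate what a dermoscope picture carries:

* **hairs** — dark-brown quadratic Bézier strokes of width 1–3 px;
* **bubbles** — bright discs with a one-pixel linear soft edge (immersion
  fluid);
* **acral grooves** — optional additive sinusoidal stripes (period 6 px,
  amplitude 22 intensity units) inside the lesion, giving the acral class a
  texture signature.

Defaults (128×128 px, semi-axes (30, 20), background (224, 172, 138), pigment
(92, 54, 38)) were chosen once as representative of a close-up dermoscopy
crop of a medium-size nevus on light skin; no resolution or color
calibration is implied and everything is configurable. The generator does
*not* attempt photorealism: no vignetting, no pigment network, no
multi-color lesions, no perspective. Tests passing on these images therefore
demonstrate the correctness and robustness of the algorithmic chain, not
clinical performance on real dermoscopy archives.

### Two-view classification data

`generate_two_view_dataset` draws one unit-variance Gaussian blob per class
per view, class means separated by `class_separation` standard deviations
along a fixed per-view direction. The direction is derived from a constant
generator, deliberately *not* from the sampling seed: it is a property of
the data distribution, so datasets drawn under different seeds are samples
from the same classification problem (required for training on one draw and
testing on another). View noise mixes a shared component (weight
`view_correlation`, default 0.3) with an independent one, so the views are
informative but not redundant — the regime where co-training can help.
Unlabeled rows carry hidden true labels used only for scoring.

### Case tables

`generate_case_table` samples clinical records
(`patient_id,group,age,sex,nevus_type,site`). The exact-counts mode returns
a fixed, deterministic 268-case table whose per-type site cells, group
sizes (134/134), sex counts (126/142) and per-group age-bracket counts are
built in; it is the reference input for the tabulation functions and
reproduces their percentage outputs exactly.

## Segmentation

Stages, in order, with defaults:

1. **Artifact removal** (`remove_artifacts`). Hairs: bottom-hat residue of a
   grayscale closing (disk radius 3) of the luminance channel, threshold 20
   intensity units, components kept only if their skeleton length is ≥
   `hair_length_min` (default 15 px) — this rejects compact dark structure
   that belongs to the lesion. Bubbles: luminance ≥ 230 with circularity
   4πA/P² > 0.35. Detected pixels (dilated by 1 px) are filled by biharmonic
   inpainting. If the artifact mask would cover more than 30 % of the image
   the input is returned unchanged with a warning: an image that is mostly
   "artifact" gives inpainting nothing to extrapolate from.
2. **Denoising** (`denoise`): per-channel median filter, radius 2 (5×5
   window). Median filtering is edge-preserving and removes impulse noise
   and inpainting residue. Artifact removal runs *before* denoising: the
   median filter blurs hair strokes and weakens the bottom-hat detector
   (measured on the noisy-3-hair fixtures, the worst-case Dice over 20 seeds
   rises from 0.81 to 0.92 with this order).
3. **Over-segmentation** (`oversegment`): SLIC superpixels (k-means in
   color+position space), default target 64 regions, connectivity enforced.
   For very small targets (< 16), where SLIC's grid seeding is unreliable,
   a seeded k-means over (R, G, B, weighted row, weighted col) with
   connected-component splitting is used instead; a constant image falls
   back to a grid partition with a warning. Region ids are 1..N and each
   region stores its mean-color vector.
4. **Seed selection and merge**: the pair of regions with the largest
   mean-color Euclidean distance (ties broken toward the lexicographically
   smallest id pair) seeds the two groups; every region joins the seed
   nearer in color (ties to the first seed). The merged group with the lower
   pixel-weighted mean luminance (Rec. 601) is the lesion — pigmented nevi
   are darker than the surrounding skin. This darkness rule and the
   nearest-seed assignment are this package's design choices where the
   method family leaves them open.
5. **Boundary smoothing** (`smooth_boundary`): morphological closing then
   opening with a disk (default radius 3), then removal of foreground
   components smaller than radius² pixels. The operation is idempotent at a
   fixed radius.

Only a single over-segmentation + merge is implemented; fusing multiple
independent segmentation algorithms is out of scope.

## Shape, color and texture features

Moments are computed over the binary lesion mask (the foreground indicator),
not intensity-weighted: s_pq = Σ i^p j^q, centroid (s10/s00, s01/s00),
central moments ψ_pq about the centroid (so ψ10 = ψ01 = 0 identically).
The equivalent-ellipse axis lengths are

    L1,2 = sqrt( 8 (ψ02 + ψ20 ± sqrt((ψ02 − ψ20)² + 4 ψ11²)) / ψ00 ),

i.e. 4·sqrt(eigenvalue) of the normalized second-moment matrix. This is the
standard moment-matching form: for a solid disc of radius R it returns
L1 = L2 = 2R (the diameter), and for a rasterized ellipse with semi-axes
(a, b) it returns (2a, 2b) within rasterization error. AR = L1/L2 ≥ 1 and is
invariant to translation, rotation (within ~5 % rasterization tolerance) and
uniform scaling (~3 %). A collinear mask yields L2 = 0 with a warning;
AR is then refused.

The color view is 7 masked statistics (per-channel mean and sd inside the
lesion, plus the lesion/background mean-color distance); the texture view is
4 luminance statistics (variance, entropy of a 32-bin histogram in bits,
mean absolute horizontal/vertical within-lesion gradients). These are a
deliberately minimal fixed set — just enough to give the two-view split
(shape vs color+texture) discriminative, partly complementary views; no
GLCM/wavelet suites and no Hu invariants. Feature fusion is concatenation
with disjoint schema names.

## SVM

The two-class soft-margin dual is solved by SMO: working pairs chosen by
maximal KKT violation (the most violating up/down pair), analytic
two-variable updates, gradient maintained incrementally, stopping when the
violation gap is ≤ `tol` (default 1e-3; tightened to 1e-8 in correctness
tests) or after `max_iter` (default 10 000) passes-worth of updates, in
which case the best iterate is returned with `converged=False` and a
warning. The offset b* is the mean of y_i − Σ_j a_j y_j K(x_j, x_i) over
non-bound support vectors, or the midpoint of the feasible interval if none
exist. Multipliers below 1e-8 are dropped from the stored model.

Kernels: linear x·y, polynomial (γ x·y + c0)^d, sigmoid tanh(γ x·y + c0),
Gaussian exp(−‖x−y‖²/δ²) with γ = 1/δ² (both parametrizations accepted).
Features are standardized to train-set zero mean / unit variance before
kernel evaluation by default (the nonlinear kernels are scale-sensitive);
the constants live on the model, and standardization can be disabled.
Prediction is sign(G(x)) with sign(0) → +1 as the fixed tie-break.

Numerical notes: the two-variable subproblem guards a non-positive
curvature with τ = 1e-12; Σ a_i y_i = 0 is maintained exactly by the paired
updates from the feasible start a = 0. Grid search uses own stratified
k-fold splitting (shuffled within class, round-robin assignment), accuracy
as the criterion, and ties broken toward smaller P then smaller γ.

The logistic sigmoid f(x) = 1/(1+e^(−x)) and its derivative f(1−f) are
exposed as numerically stable utilities (they are conventionally associated
with this classifier family's activation toolbox but are not used by the
SMO solver itself).

## Semi-supervised training

`CoTrainConfig` defaults: confidence floor 0 (top-k only), k_per_round = 2
per class per view, max_rounds = 30. These schedule knobs are design
choices; all are configurable.

* **Self-training** retrains after adding its own top-k most confident
  pseudo-labels (confidence = |decision value|, ties by row index) per class
  per round; stops when nothing qualifies.
* **Co-training** keeps one SVM per view. Both views pick concurrently from
  the same unlabeled pool, and each view's picks are donated — with its
  pseudo-labels — to the *other* view's labeled pool (classic cross-view
  donation). Concurrent picking makes the scheme exactly symmetric under
  swapping the views; an example picked by both views with conflicting
  labels is dropped from the pool without being donated. The combined
  predictor is the sign of the sum of the two decision values (zero → +1),
  which cannot tie, unlike a two-classifier vote.
* **Fusion training** is a single SVM on the concatenated views.

Reduction laws hold exactly: with no unlabeled data co-training equals the
two supervised single-view models, and with an unreachable confidence floor
self-training equals its supervised baseline.

`compare_regimes` evaluates all regimes over replicate datasets. The dataset
object carries its generation parameters, and each replicate redraws a
training set and an independent held-out labeled set (default 200 rows)
under seeds derived from the dataset seed — a fixed single dataset cannot
supply independent replicates, so regeneration is the honest reading of a
multi-seed comparison. The shipped benchmark
(`configs/two_view_benchmark.yaml`: 20 labeled + 400 unlabeled rows,
class separation 2.0, view correlation 0.3, linear kernel, P = 1, 20
replicates) is sized so a full comparison runs in ~10 s on one CPU while
leaving single-view training clearly below ceiling, which is the regime
where the co-training ≥ single-view ordering is observable.

## Evaluation and case statistics

Both specificity conventions are computed and named: `paper_fpr` is the
literal false-positive rate FP/(FP+TN)·100 and `specificity_std` is
TN/(TN+FP)·100 = 100 − FPR; reports carry both so neither convention is
silently imposed. AUC is the rank/Mann–Whitney statistic via average ranks
(ties count half). Percentages are reported to two decimals, rounded
half-up, with all internal arithmetic in full precision.

Contingency-table totals are always recomputed from cells;
`validate_contingency_totals` flags claimed totals that disagree with the
cell sums instead of trusting them. The χ² test is the Pearson statistic
with margin-based expected counts, dof = (r−1)(c−1) and the upper-tail
p-value; zero margins are rejected by name. Default age brackets are
(6–17, 18–38, 39–58, 59–74), configurable. Tabulation is per case; per-lesion
tabulation (a patient can carry several nevi) is not modeled.

## Pipeline

`run_pipeline` executes segmentation → feature extraction (shape view,
color+texture view) → classification under the configured regime, with one
master seed and fixed per-stage offsets, and produces a manifest with the
config hash and per-stage checksums (identical config + seed ⇒ identical
manifest). Two label values give a two-class task; more are bridged
one-vs-rest over the two-class SVM with argmax decision value — the minimal
multi-class construction over a binary classifier. With no unlabeled images
the co-training regime reduces to the two supervised views combined by
decision-value sum. Any stage failure aborts with the stage name; partial
artifacts already written are retained.

## Problem sizes and determinism

Default test and acceptance workloads use 96–128 px images, 20-replicate
Monte-Carlo comparisons, and SVM instances up to a few hundred points;
these sizes were chosen so the whole suite completes in well under a minute
of compute per concern while keeping every statistical margin (Dice floors,
regime orderings, oracle agreements) comfortably wide. All randomness flows
through seeded `numpy.random.default_rng` generators; every reported
quantity is reproducible bit-for-bit under a fixed seed.

## Known limitations

* The synthetic lesions are single-color ellipses; multi-focal or
  low-contrast lesions, pigment networks and real hair geometry are not
  modeled, so segmentation robustness claims extend only to artifacts of the
  modeled kinds.
* The SMO solver is dense (full kernel matrix); it is intended for
  desk-scale data (thousands of points), not archives.
* One-vs-rest decision values are not calibrated across classes.
* Co-training assumes row-aligned views of the same examples; more than two
  views and disagreement-based variants are out of scope.
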