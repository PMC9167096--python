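# nevuscope

Analysis toolkit for dermoscopic images of pigmented nevi (melanocytic
"moles"). Dermoscopy images a lesion through a magnifying lens and immersion
fluid, so the pictures carry hair strokes, bright fluid bubbles and sensor
noise on top of a pigmented lesion that is darker than the surrounding skin.
`nevuscope` implements the full classical recognition chain for such images —
segmentation, shape/color/texture feature extraction, a from-scratch kernel
SVM, semi-supervised two-view training, diagnostic metrics — together with
clinical case tabulation and a synthetic-data generator that makes every
stage testable without any image download.

## What it computes

**Segmentation by color-distance region merging.** After hair/bubble removal
(bottom-hat detection + biharmonic inpainting) and median denoising, the
image is over-segmented into connected color-homogeneous subregions. Each
region *i* gets a mean-color vector H_i = (R̄_i, Ḡ_i, B̄_i); the pair of
regions maximizing the Euclidean color distance

    L(V1, V2) = sqrt((R̄1−R̄2)² + (Ḡ1−Ḡ2)² + (B̄1−B̄2)²)

seeds the foreground/background split, every other region joins its
color-nearest seed, the darker merged group is the lesion, and the boundary
is smoothed morphologically.

**Moment-based shape features.** Binary geometric moments
s_pq = Σ i^p j^q over lesion pixels, the centroid (r0, c0) = (s10/s00, s01/s00),
central moments ψ_pq, the equivalent-ellipse axis lengths

    L1,2 = sqrt( 8 (ψ02 + ψ20 ± sqrt((ψ02 − ψ20)² + 4 ψ11²)) / ψ00 )

and the aspect ratio AR = L1/L2. Color and texture descriptors (masked
channel statistics, histogram entropy, gradients) form a second feature view;
the views can be fused into one vector.

**A from-scratch SVM.** The soft-margin dual (maximize Σa_i − ½Σ a_i a_j y_i
y_j K(x_i,x_j) subject to Σ a_i y_i = 0, 0 ≤ a_i ≤ P) is solved by SMO with
maximal-violating-pair selection; kernels are linear, polynomial, sigmoid and
Gaussian Q(x,y) = exp(−‖x−y‖²/δ²); the decision function is
G(x) = Σ a_i* y_i K(x_i, x) + b*. Cross-validated grid search over (kernel,
P, γ) is included.

**Semi-supervised regimes.** Single-view feature training, fused-feature
training, self-training, and two-view collaborative (co-)training in which
each view's classifier donates its most confident pseudo-labels to the other
view each round.

**Evaluation and case statistics.** Sensitivity TP/(TP+FN), the
false-positive rate FP/(FP+TN) together with its standard complement
specificity TN/(TN+FP), accuracy, Mann–Whitney AUC; nevus-type and
lesion-site tabulations, demographic summaries, and the Pearson χ² test of
independence (α = 0.05).

## Worked example

```python
import nevuscope as nv

spec = nv.SyntheticLesionSpec(semi_axes=(30, 18), rotation=0.6,
                              noise_sd=10, n_hairs=2, seed=42)
li = nv.generate_lesion_image(spec)            # image + ground-truth mask
res = nv.segment_lesion(li.image)              # artifact removal -> merge
print("dice =", round(nv.dice_coefficient(res.mask, li.truth_mask), 4))

sf = nv.extract_shape_features(res.mask)
for name, v in zip(sf.schema, sf.values):
    print(f"{name} = {v:.2f}")
```

prints

```
dice = 0.9658
area = 1806.00
axis_major = 59.26
axis_minor = 39.46
aspect_ratio = 1.50
```

The segmented mask overlaps the true elliptical lesion with Dice 0.97; the
equivalent-ellipse axes (59.3, 39.5) match the generated semi-axes (30, 18)
— full lengths 60 and 36 — and the aspect ratio ≈ 30/18 ≈ 1.6 up to
rasterization and boundary smoothing.

The same stages are available from the shell:

```sh
nevuscope synth image --seed 42 --out out/
nevuscope segment out/image.png --out out/mask.png
nevuscope features out/image.png out/mask.png --views fused --out out/features.csv
nevuscope synth cases --n 268 --mode exact-table --out cases.csv
nevuscope casestats cases.csv --out summary/
```

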