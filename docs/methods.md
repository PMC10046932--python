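# Methods

This note documents the models, the parameters that matter, the synthetic
data the package validates against, and the numerical choices made where
the design was genuinely open.

## Adaptive denoising

The filter assumes additive, zero-mean, locally stationary noise. With
local window mean `μ(a,b)`, local variance `σ̂²(a,b)` and a global noise
estimate `σ_n²`, each pixel is shrunk toward its window mean:

    out = in − min(1, σ_n² / max(σ̂², ε)) · (in − μ)

* The shrinkage ratio is **clamped at 1**: in windows whose variance falls
  below the global noise floor the unclamped ratio would overshoot past
  the mean and invert contrast. Clamping makes the output a convex
  combination of the pixel and its window mean (a property the tests
  assert on random images).
* `σ_n²` is estimated as the **mean of the local window variances**. A
  noise estimate defined through "the difference between the noisy and the
  filtered image" is circular — the filter needs the estimate to exist.
  The mean-of-local-variances estimator is unbiased on pure-noise images
  (recovering a known variance within 15% in the tests) and biased upward
  in the presence of edges, which only makes the filter slightly more
  aggressive on flat regions.
* Window size: 3×3 default, configurable, odd. Borders are handled by
  reflective padding (scipy's `reflect`, i.e. edge-repeating); the choice
  is cosmetic for windows this small.
* `ε = 1e−12` guards division in perfectly flat windows.
* Sharpening is unsharp masking, `in + amount·(in − gaussian(in, σ=1))`,
  clipped to [0, 1]; `amount = 0` is the identity. The sharpening *step*
  is part of the published workflow but no method is named; unsharp
  masking is the standard choice.

Images are float in [0, 1] throughout; integer rasters are scaled by their
dtype maximum on read.

## Fuzzy c-means segmentation

Pixels are clustered on **intensity alone** (no spatial term is published
for this pipeline). The standard alternating updates are used with the
exponent `2/(m−1)`; the printed exponent reuses the iteration counter `n`,
but `m` is the declared fuzziness degree and the standard algorithm uses
it. Defaults: `c = 3` (background / brain / tumor), `m = 2`, `ε = 1e−5` on
the maximum absolute membership change, `max_iter = 100`, with random
uniform center initialization from the image's intensity range (seeded,
sorted ascending). Non-convergence at `max_iter` is flagged on the
returned partition, not raised.

Singularities: a pixel coinciding exactly with a center takes membership 1
there (split equally if several centers coincide with it). This rule also
lets a constant image — where all centers collapse — terminate cleanly.

Defuzzification assigns each pixel its maximum-membership cluster, ties
resolving to the brighter center, and the cluster with the brightest
center is the tumor candidate (tumors are the bright region in the imaging
setup emulated here). Cleanup is a 3×3 binary opening, hole filling, and
retention of the largest connected component if it reaches `min_area`
(default 0.1% of the image).

**Tumor-free decision.** Defuzzification always produces a brightest
cluster, so some rule must declare an image tumor-free. Morphology plus a
minimum area cannot do it: on a tumor-free brain the spare third cluster
either splits the background (making the whole brain the "bright" cluster)
or splits the tissue noise into large spatially-correlated blobs. Two
gates encode *a tumor is a bright minority region*:

* separation — the brightest center must sit at least `min_separation`
  (default 0.05, half the minimum tumor contrast the generator produces)
  above the second-brightest;
* area — the brightest cluster's crisp support must not exceed 35% of the
  image (the generator's ceiling is 0.4 × brain ≈ 28% of the image).

Both thresholds are stated in intensity/area units of the [0, 1] phantom
convention and were fixed from those generator bounds, not tuned per
image.

## LBP-GLCM texture features

The LBP operator compares each pixel's 8 radius-1 neighbors against the
center (`neighbor ≥ center → 1`, so ties count as 1 and a constant image
codes 255 everywhere), packing bits clockwise from the top-left,
most-significant first. Borders use reflective padding. Co-occurrences of
the codes, quantized to `L = 32` bins (floor of `code·L/256`), are
accumulated **symmetrically** at distance 1 along 0°, 45°, 90° and 135°,
normalized, and summarized by the five statistics; the per-angle vectors
are averaged. Entropy is in natural log, maximum `ln L²`. Correlation of a
single-level (zero marginal spread) matrix is defined as 1.

Features are computed on the whole image by default — the published
workflow extracts texture from the raw image, with the segmentation mask a
parallel output — and a `mask` option restricts extraction to the mask's
bounding box.

A note on rotation: rotating the *image* by 90° is not a symmetry of the
composite descriptor, because the LBP code of every pixel is cyclically
shifted by two neighbor positions and the shifted codes fall into
different quantization bins. The true invariants — equivariance of the
code map under rotation, and the 0↔90/45↔135 angle swap of GLCM features
when the *code map* is rotated — are what the tests assert.

## Recurrent convolutional classifier

One block computes, with a fixed feed-forward convolution of the input
re-injected at every step,

    z_t     = conv_ff(x) + conv_rec(state_{t−1}) + b      (t = 0: no recurrent term)
    state_t = lrn(relu(z_t)),   t = 0 … T,   T = 3

so the longest computational path has length T + 1. The reference stack is
a 64×64×3 input, four 256-filter 3×3 recurrent blocks (all four are
recurrent), 2×2 max pooling after blocks 2 and 4 (giving 16×16 before the
dense layers, which type-checks; a third pool would not), dense 512 +
ReLU + dropout 0.5, dense 2, softmax. Grayscale inputs are replicated
across the three input channels.

* **LRN**: divisive normalization `x / (k + α Σ x²)^β` over a window of
  `depth_radius = 5` adjacent feature maps (clipped at the boundaries),
  `α = 1e−4`, `β = 0.75`, `k = 1`. The additive constant matters: `k = 2`
  multiplies every map by `2^{−β} ≈ 0.6` even when activations are tiny,
  and four stacked blocks then attenuate the logits ~13×, which the fixed
  learning-rate schedule cannot recover from; `k = 1` gives near-unity
  gain (this is also the torch default).
* **Optimization**: momentum SGD, cross-entropy loss averaged over the
  batch, learning rate decaying geometrically from 2·10⁻³ to 3·10⁻⁶
  across the 30 epochs (the published end value "0.3 × 10⁵" is read as
  3·10⁻⁶ — a decay target; 3·10⁴ diverges), momentum ramped linearly
  0.5 → 0.9, batch size 32. Weights are scaled-variance uniform
  (±√(6/fan_in)) from a seed; everything — init, shuffling, dropout — is
  reproducible from the seeds, and the history records per-epoch lr,
  momentum, loss and accuracy.
* The implementation is plain numpy (im2col convolutions) with
  hand-written backprop; analytic gradients of the unrolled block match
  central finite differences to < 1e−4 relative error in the tests.
* Checkpoints are a single `.npz` with a JSON header (architecture, seed,
  trained flag) plus flat weight arrays.

**Problem sizes.** The end-to-end benchmark trains a compact variant of
the same topology (32×32 input, 8 filters, 64 hidden units, T = 3) on
200/100 balanced phantoms for the full 30 epochs — a size chosen so the
whole validation suite runs comfortably on a single CPU while exercising
every mechanism (recurrence, LRN, pooling, dropout, the full schedule).
The 256-filter reference spec is constructed and shape-checked in the
tests but not trained at that scale. The capacity check (40 high-contrast
phantoms fitted essentially perfectly) holds the learning rate at the
starting value 2·10⁻³: on a 40-image set the geometric decay leaves too
few effective updates to measure capacity at all.

## Phantoms: what they emulate, and what they do not

A phantom is an elliptical brain (semi-axes jittered so the ellipse covers
40–70% of the image) at intensity 0.45 on a 0.05 background, an optional
tumor — a union of 1–3 overlapping ellipses, fully inside the brain,
rescaled once so its pixel count lands within ±20% of the requested
fraction of the brain area — at `0.45 + contrast`, plus additive Gaussian
noise, clipped to [0, 1]. Defaults: 64×64, tumor fraction 0.1, contrast
0.3, noise variance 0.002. `make_dataset` jitters per-item geometry and
produces exactly `round(n · tumor_fraction)` tumor-labeled items.

The phantoms validate the *mechanics* of every stage: that the filter
denoises, the clustering finds bright blobs, the features separate the
classes, the network learns. They deliberately do not model MRI physics —
no bias fields, partial-volume effects, multi-contrast sequences,
anatomical texture, or skull — so passing the benchmark does not certify
clinical performance on real scans; it certifies that the implementation
of each published mechanism behaves as specified.

## Evaluation

Stratified train/test splitting (overall train size exactly
`round(n · fraction)`, largest-remainder allocation across classes so
proportions hold within one item per class; an 80/20 split of 3100 items
gives 2480/620). Metrics from the 2×2 confusion table with tumor
positive: accuracy, sensitivity TP/(TP+FN), specificity TN/(TN+FP).

The published reference confusion counts for this architecture
(TP=290, TN=135, FP=14, FN=3) total 442 and imply accuracy 96.15%,
sensitivity 98.98%, specificity 90.60% — not the 98.17/98.79/91.34
headline percentages printed beside them, and not a 620-image test set.
The tests assert this arithmetic as documentation of the discrepancy; the
headline numbers are not a reproduction target of this package.

## Known limitations

* Clustering is intensity-only; tumors darker than brain tissue, or
  multi-focal tumors of very different brightness, are out of scope.
* The tumor-free gates assume the [0, 1] intensity convention and
  bright-tumor contrast ≥ 0.1; other acquisition conventions need the
  thresholds rescaled.
* The numpy network is CPU-bound; the full 256-filter stack is practical
  only for forward shape checks, not training, at desk scale.
* Four-class grading (glioma / meningioma / pituitary / none) is
  configurable through `NetworkSpec.num_classes` but untested beyond the
  two-class default, which is the documented operating mode.
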