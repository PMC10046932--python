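# gliopipe

Automated detection and two-class classification (glioma vs. normal) of
brain tumors in 2D MR slices. The pipeline has four stages:

1. **Adaptive denoising** — a Wiener-type filter that shrinks each pixel
   toward its local window mean by the ratio of the global noise variance
   to the local variance, `out = in − min(1, σ_n²/σ_local²)(in − μ_local)`,
   so flat tissue is smoothed while edges pass through.
2. **Segmentation** — fuzzy c-means clustering on intensity: memberships
   `V_ij = 1 / Σ_l (|a_j−c_i| / |a_j−c_l|)^{2/(m−1)}` alternate with
   weighted-mean center updates `c_i = Σ_j V_ij^m a_j / Σ_j V_ij^m` until
   the largest membership change falls below a tolerance; the brightest
   cluster is defuzzified into a tumor mask and cleaned up morphologically.
3. **Texture features** — an 8-neighbor local binary pattern turns the
   image into a map of 8-bit codes; a symmetric gray-level co-occurrence
   matrix over the quantized codes ("LBGLCM") yields energy `Σp²`, entropy
   `−Σp ln p`, contrast `Σp(x−y)²`, homogeneity `Σp/(1+(x−y)²)` and
   correlation, averaged over the four standard directions.
4. **Classification** — a recurrent convolutional network: blocks whose
   state at step *t* adds a recurrent convolution of their own previous
   state to a fixed feed-forward convolution of the input,
   `state_t = lrn(relu(conv_ff(x) + conv_rec(state_{t−1}) + b))`, unrolled
   T = 3 steps, with max pooling, a dense layer with dropout, and a
   softmax head. Training is momentum SGD (momentum ramped 0.5 → 0.9) with
   a geometric learning-rate decay from 2·10⁻³ to 3·10⁻⁶ over 30 epochs.

Because clinical MRI archives cannot ship with a library, the package
includes a first-class **phantom generator**: elliptical brain sections on
a dark background with optional bright, irregular tumor blobs of
controllable area and contrast, additive Gaussian noise, and exact
ground-truth masks. All validation and the end-to-end benchmark run on
these phantoms.

The public surface is sklearn-style estimators — `AdaptiveDenoiser`,
`FuzzyCMeans`, `LBGLCMExtractor`, `CRNNClassifier` — plus functional
equivalents per stage and a `gliopipe` command-line tool
(`phantom`, `preprocess`, `segment`, `features`, `train`, `predict`,
`evaluate`, `run-all`).

## Worked example

```python
import numpy as np
from gliopipe import phantom, preprocessing as pp, segmentation as seg, texture

spec = phantom.PhantomSpec(height=64, width=64, tumor_area_fraction=0.1,
                           tumor_contrast=0.3, noise_variance=0.002, seed=7)
item = phantom.make_phantom(spec)            # image + label + truth mask
img = pp.denoise(item.image, window_size=3)  # adaptive filter
mask = seg.segment_image(img, c=3, seed=0)   # fuzzy c-means + cleanup

percent, count = seg.tumor_stats(mask, phantom.brain_mask(item))
print(f"tumor-affected portion: {percent:.2f}%  ({count} pixels)")

fv = texture.extract_features(img)           # LBP -> GLCM -> 5 statistics
for name, v in zip(texture.FEATURE_NAMES, fv.to_array()):
    print(f"{name:12s} {v:.4f}")
```

prints

```
tumor-affected portion: 10.00%  (241 pixels)
energy       0.0055
entropy      5.7440
contrast     223.7656
homogeneity  0.1691
correlation  0.1574
```

The phantom was built with a tumor covering 10% of the brain ellipse, and
the segmented mask recovers exactly that portion (241 of 2410 brain
pixels; Dice 1.000 against the generator's truth mask on this seed). The
texture statistics are the five co-occurrence summaries of the LBP code
map: low energy and high entropy reflect the noisy, texture-rich slice,
and homogeneity/correlation sit well inside their [0, 1] and [−1, 1]
bounds.

For classification, `gliopipe.pipeline.standard_benchmark()` generates the
balanced 200-train / 100-test phantom benchmark (tumor contrast 0.3, noise
variance 0.002); training `CRNNClassifier` for the default 30 epochs
recovers held-out labels with accuracy ≥ 0.9 (0.96 at seed 0).

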