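# hcwssc

Unsupervised classification of hyperspectral images (HSI) with a
**hybrid changing-weight K-means** built on spectral similarity measures and
a filter feature selection (HCW-SSC).

Hyperspectral sensors record tens to hundreds of narrow bands per pixel, so
every pixel carries a full reflectance spectrum.  Mapping land cover or
crops from such a cube without training labels is usually done by clustering
pixels under a spectral dissimilarity measure.  No single measure suffices:
Euclidean distance (ED) sees brightness, the spectral angle (SAC),
correlation (SCC) and information divergence (SID) see the shape of the
spectral curve.  This package implements a principled way to *combine* two
of them, for remote-sensing practitioners and anyone benchmarking
unsupervised HSI classifiers.

## Method

Four dissimilarity measures between band vectors `x`, `y` (all are 0 for
identical spectra and grow with dissimilarity):

| measure | definition | sensitive to |
|---|---|---|
| ED  | ‖x − y‖₂ | brightness |
| SAC | 1 − cos θ(x, y) | curve shape (scale-invariant) |
| SCC | 1 − r(x, y) (Pearson over bands) | curve shape (affine-invariant) |
| SID | D(p‖q) + D(q‖p), p = x/Σx, q = y/Σy | band probability profile |

The pipeline:

1. **Feature extraction** — for each measure `S`, a per-pixel feature map
   `S(xᵢ, μ)` against the scene mean spectrum `μ`.
2. **Filter selection** — Pearson-correlate the four maps pairwise and keep
   the pair `(S₁, S₂)` with minimal |ρ| (least duplicated information).
3. **CV weighting** — with `CV_S = σ(S)/μ(S)` over pixels, the normalised
   weights satisfy `w₁/w₂ = CV_{S₁}/CV_{S₂}`, `w₁ + w₂ = 1`; each is then
   divided by its feature-map mean `μ̄_S` so both kernels become unitless.
4. **Hybrid K-means** — pixels are assigned by
   `argmin_j  w₁·S₁(xᵢ, μʲ) + w₂·S₂(xᵢ, μʲ)`
   with band-wise-mean centroid updates, an iteration cap and a
   relabelled-pixel change threshold.
5. **Evaluation** — optimal cluster-to-class alignment (Hungarian), overall
   accuracy, Cohen's kappa (chance agreement generalised to C classes),
   per-class precision/recall/F1.

Baselines (single-measure kernels and the unweighted two-measure hybrid),
an elbow-method K suggestion and the triplet-library protocol (cluster
three labelled spectra, two of one class and one of another, with K = 2)
are included, along with synthetic scene/library generators that make the
whole pipeline testable offline.

## Worked example

```python
import numpy as np
from hcwssc import SceneSpec, make_scene, run_hcwssc, evaluate_labels

# a 64 x 64 x 30 five-class scene with multiplicative brightness noise
# (lognormal sigma 0.15) and additive noise (sigma 0.01)
cube, truth = make_scene(SceneSpec(seed=3))

labels, selection, model = run_hcwssc(cube, n_clusters=5, random_state=0)
print(selection.pair, np.round(selection.norm_weights, 3))
report = evaluate_labels(truth.ravel(), labels.ravel())
print(round(report.overall_accuracy, 4), round(report.kappa, 4))
```

prints

```
('ED', 'SCC') [0.525 0.475]
1.0 1.0
```

ED and SCC were the least-correlated feature pair on this scene (brightness
noise decorrelates the ED map from the shape maps), the CV shares split the
kernel roughly evenly, and the weighted hybrid K-means recovers the planted
classes exactly (overall accuracy and kappa of 1).

The same pipeline is available from the shell:

```sh
hcwssc simulate --rows 64 --cols 64 --classes 5 --seed 3 \
    --out scene.img --truth truth.img
hcwssc hcwssc --input scene.img -k 5 --truth truth.img \
    --out labels.img --report report.json
```

Other subcommands: `select`, `cluster` (explicit kernels), `elbow`,
`triplets`, `evaluate`.  Rasters are ENVI (raw + `.hdr`) or TIFF; spectral
libraries are delimited text with class labels in the header row.

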