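# Methods

This note records the modelling choices, numerical conventions and synthetic
study conditions behind the package, and what its tests do and do not show.

## Dissimilarity measures

All four measures return 0 for identical spectra and grow with
dissimilarity, so they can be mixed additively inside one assignment rule.

* **ED** — the Euclidean norm of the band-wise difference.  Homogeneous of
  degree one; carries the physical brightness signal (illumination,
  topography) as well as any class signal.
* **SAC** — `1 − cosθ` between the band vectors, in [0, 2].  Invariant to
  independent positive rescaling of either spectrum.
* **SCC** — `1 − r` with `r` the Pearson correlation across bands, in
  [0, 2].  The correlation convention was chosen to mirror the `1 − cos`
  convention of SAC and the rule that larger values mean less similar;
  alternatives (`1 − r²`, `(1 − r)/2`) are monotone transforms that would
  not change which pair is selected, only the CV magnitudes.  Invariant to
  positive-slope affine maps.
* **SID** — the symmetric Kullback–Leibler divergence between the
  band-normalised probability vectors, in nats by default; the log base is
  configurable (`sid_base`) since conventions differ.  A floor of 1e-12 is
  added inside the logarithms so spectra with zero bands stay finite.

Degenerate inputs (all-zero spectra for SAC/SID, band-constant spectra for
SCC) raise in the scalar API.  Inside vectorised feature maps and cluster
assignment they are instead assigned the maximum observed dissimilarity of
that map or matrix, with a warning — a degenerate pixel must never win an
argmin through NaN ordering, and pushing it away from every centroid is the
conservative choice.

## Filter feature selection

Feature maps are computed against the mean spectrum of the valid pixels;
masked pixels carry no value anywhere downstream.  The Pearson matrix is
computed on the flattened valid-pixel values, pixels paired positionally.
The selected pair minimises |ρ| over the six pairs; exact ties fall back to
the canonical order ED < SAC < SCC < SID, purely for determinism.  A
constant feature map (possible on degenerate scenes) is excluded from
candidacy with a warning; selection fails if fewer than two candidates
remain.

The coefficient of variation uses the **population** standard deviation
(`ddof=0`, configurable): the pixel set of a scene is the complete
population of interest, not a sample from a larger one.

Two weight sets coexist deliberately:

* `norm_weights` — CV shares; sum to one, ratio equal to the CV ratio.
  This is the reported, dimensionless form.
* `weights` — CV share divided by the feature-map mean `μ̄_S`.  Because ED
  values on a reflectance cube are typically an order of magnitude larger
  than SAC/SCC/SID values, the raw shares alone would still let one kernel
  dominate; dividing by the map mean puts both kernels on a common unitless
  scale.  These are the operative weights the clustering kernel consumes.

## Hybrid K-means

Assignment minimises `Σ_k w_k · S_k(x, μʲ)` over centroids; ties go to the
lowest cluster index.  The squared magnitude sometimes written around such
kernels is omitted: all terms are non-negative, so squaring cannot change
the argmin.  Centroid updates are band-wise means.  An empty cluster is
re-seeded to the pixel farthest (under the kernel) from the cluster's
previous centroid, keeping K constant and the run deterministic.

Convergence is enforced by an iteration cap and a **change threshold**: the
run stops when the fraction of pixels that changed label between
consecutive assignment passes falls below the threshold (a "2 %" protocol
value is 0.02), or when labels stop changing.  For a single ED kernel the
summed squared assignment distance descends as in classical K-means, and
the test suite asserts this; for hybrid kernels the mean update does not
necessarily descend the hybrid objective, so the objective trace is
recorded but never asserted.

Seeding: the core estimator defaults to the protocol-faithful uniform draw
of K distinct pixel spectra (`init="random"`, `n_init=1`).  The end-to-end
pipeline defaults to greedy kernel-D² seeding (`init="d2"`: candidates
drawn with probability proportional to squared kernel dissimilarity to the
nearest chosen centroid, the lowest-potential candidate kept) with
`n_init=4` best-of-restarts on inertia.  The reason is structural: a
uniform draw of K pixels lands two centroids in one class and none in
another with probability `1 − K!/K^K` (≈ 96 % at K = 5), and K-means cannot
split a merged pair of well-separated classes afterwards.  D² seeding with
a few restarts removes this failure mode without touching the update rules.

The elbow helper fits over a K range (five restarts per K so the inertia
curve is monotone) and reports distortion (mean kernel dissimilarity to own
centroid) and inertia (summed squared).  `suggested_k` maximises the raw
second difference of inertia and is advisory only; under noise it tends to
sit at or below the planted class count.

### Triplet protocol

A triplet group holds three labelled spectra, two of one class and one of
another; it is clustered with K = 2, an iteration cap of 2 and a 2 % change
threshold, and scored as correct when the same-class pair shares a cluster.
A three-point K = 2 problem admits only three distinct seedings, so the
protocol evaluates `n_init=3` and keeps the lowest-inertia run — this
removes initialisation luck entirely while preserving the iteration cap.
The suite F1 treats the two roles ("member of the pair" / "odd one out") as
the classes of a pooled per-spectrum confusion matrix; a wrongly grouped
triplet contributes, after optimal per-group alignment, exactly two of
three correct roles, so the pooled matrix follows from the per-group
outcome vector alone.

## Evaluation

Cluster indices are aligned to classes by maximum-matching assignment on
the contingency table (Hungarian algorithm); surplus clusters map to their
majority class.  The confusion matrix follows the remote-sensing
convention: columns true, rows predicted.  Kappa uses the chance agreement
`pe = Σ_c rowSum_c · colSum_c / N²`, which reduces exactly to the familiar
binary TP/TN/FP/FN form at C = 2 (asserted on random binary matrices).
Per-class precision or recall with a zero denominator is reported as NaN
and forces that class's F1 to 0.  Pixels with negative labels (masked or
unlabelled ground truth) are excluded.

## Synthetic study conditions

The generators emulate the two data shapes the classifier consumes and are
the fixed conditions under which the acceptance suite runs.

* **Endmembers** — a small random baseline plus 2–4 Gaussian reflectance
  bumps over 400–1000 nm (configurable), rejection-sampled to a minimum
  pairwise spectral angle.  Options: `equal_brightness` rescales every
  endmember to mean reflectance 0.25 (classes differ in shape, not albedo —
  the regime where ED is uninformative), and `max_separation` caps the
  pairwise angle (pinning how distinguishable the classes are).
* **Scenes** — default 64 × 64 × 30 with five classes in block layout;
  per-pixel spectrum = endmember × LogNormal(0, σ_b) + N(0, σ_a), clipped
  at zero, with σ_b = 0.15 and σ_a = 0.01 as the moderate-noise default.
  Multiplicative brightness noise moves ED but not the spectral angle, so
  magnitude- and shape-sensitive feature maps decorrelate by construction.
  The brightness-stress condition (σ_b = 0.35, σ_a = 0.002, 32 × 32 × 20,
  four classes) is used for the weighted-versus-unweighted comparison.
* **Triplet suites** — 80 groups by default; within-class copies scaled by
  U(0.7, 1.3) ("scaled" mode) or jittered with small additive noise.  The
  library study condition uses three classes of equal albedo with pairwise
  angles in [0.5, 0.7] rad: close enough that within-class brightness gaps
  can exceed between-class gaps in ED terms (so a single ED kernel
  misgroups some triplets), while every shape measure separates the classes
  cleanly.

What the generators do **not** emulate: mixed pixels and abundance
gradients, sensor artefacts (smile/frown, striping), band-to-band
correlated noise, atmospheric effects, and spatial autocorrelation of
noise.  Passing tests therefore demonstrate the correctness of the
algorithms and the claimed qualitative behaviour (weighting helps exactly
when one measure's noise dominates), not field-accuracy levels on real
imagery.

## Problem sizes and numerics

The test and acceptance runs use desk-scale problems: 64 × 64 × 30 scenes
(4096 pixels), 80-group libraries, 20 comparison seeds, and a runtime sweep
from 32² to 256² pixels; these sizes are large enough for every asserted
effect while keeping the whole suite in seconds.  Pearson and cosine /
correlation distances are delegated to scipy; tiny negative rounding
residues from those routines are clipped to zero.  Tolerances: exact hand
values to 1e-10, weight identities to 1e-12.

## Known limitations

* Hybrid-kernel K-means has no descent guarantee; pathological geometries
  can cycle until the iteration cap (the change threshold makes this
  harmless in practice).
* The selection considers only the four named measures and exactly one
  pair; selecting more measures or using wrapper/embedded selection is out
  of scope.
* Georeference handling is passthrough only (ENVI `map info` string, TIFF
  description); no reprojection or CRS interpretation.
* The elbow suggestion is a raw-second-difference heuristic; inspect the
  curve rather than trusting the single number.
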