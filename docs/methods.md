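# Methods

## The problem and the model

A label-free phenotypic screen asks whether a drug changed cell morphology,
and by how much, using only bright-field images. Two complementary readouts
answer it: a supervised one — how accurately a linear classifier separates
treated from untreated cells in a morphological feature space — and an
unsupervised one — the maximum mean discrepancy (MMD) between the two
feature distributions. Both are computed here on synthetic data whose
ground truth is known, so every stage of the chain can be validated
quantitatively.

### Dose–response model

The scalar effect size e(c, t) ∈ [0, 1] maps concentration c and treatment
duration t to the strength of the morphological shift:

    e(c, t) = h(c) · r(c) · s(t),   h(c) = c^k / (c^k + EC50^k)

with Hill coefficient k = 1 and EC50 = 50 nM, a rollback factor
r(c) = 1 − ρ for c above the peak dose (1 µM) with ρ = 0.35 — emulating
the solvent-driven drop in separability observed at the highest dose of a
dilution series, where the carrier solvent reaches ~1% v/v — and a duration
factor s(24 h) = 1, s(12 h) = 0.6, so the shorter treatment always has a
strictly weaker effect. This is the simplest form that reproduces the
rise–peak–rollback pattern with a monotone dose axis up to the peak.

On the default dose grid (0, 1 nM, 10 nM, 100 nM, 1 µM, 10 µM) the 24 h
effect sizes are 0, 0.02, 0.17, 0.67, 0.95, 0.65.

### Synthetic cells

Two data paths share all downstream analysis:

* **Image path.** Each cell is an ellipse of area π·r² (r = mean radius,
  baseline 12 px) with configured eccentricity and random orientation,
  band-limited interior texture (Gaussian-filtered white noise with filter
  σ = texture grain), a boundary blurred at the edge-sharpness scale, on a
  flat background (0.15) with additive Gaussian read noise (σ = 0.01), in
  a 96×96 frame. Treatment shifts each phenotype parameter by
  e(c, t) times a fixed maximal displacement (radius +3 px, eccentricity
  +0.20, texture grain +1.5 px, intensity mean +0.10, intensity sd +0.03,
  edge blur +0.6 px), plus truncated-normal cell-to-cell variation.
  Frames serialize to a 1D line-scan waveform whose stacking is an exact
  inverse, so reconstruction is testable bit-for-bit.
* **Feature-table surrogate.** For speed, feature vectors are drawn
  directly: i.i.d. standard normal in 548 dimensions with a class-mean
  shift of e(c, t)·**δ**, where **δ** is a fixed sparse vector touching 20
  features across all four categories with decaying weights and Euclidean
  norm 2.81. That norm sets the full-effect Bayes separability to
  Φ(2.81/2) ≈ 0.92, the ceiling accuracy of the strongest condition;
  finite training samples approach it from below.

Experimental "repeats" are independent draws (different seeds) under the
same parameters; no batch effect is modeled. Every generator is a pure
function of (parameters, seed).

**What the generator does not emulate:** optical physics (diffraction,
dispersion, spectral shading), focus drift, doublets and debris, segmentation
artifacts correlated with treatment, feature–feature correlation structure,
and any real drug's biology — the displacement vector is a free modeling
choice, not a claim about what any particular compound does to any
particular cell line. Passing tests therefore demonstrate that the analysis
chain recovers a known structure from data of realistic dimension and noise,
not that it would reach the same numbers on real images.

## Reconstruction and segmentation

Waveforms are reshaped into frames (trailing partial frames dropped with a
warning). Cell-bearing frames are those whose 3×3-median-filtered intensity
range reaches a contrast threshold (default 0.1). Segmentation is a minimal
standard chain: per-frame min–max normalization; a global threshold started
at Otsu's value and refined isodata-style to the midpoint of the two class
means (Otsu's criterion systematically under-cuts soft object boundaries,
haloing the mask); the minority side of the cut is the cell. Morphological
closing (disk radius 2) plus hole filling define connectivity and the
largest connected component; the final mask is the thresholded pixels, with
enclosed holes filled, inside that component — so the closing bridges
cracks but cannot thicken a clean boundary, and a noiseless synthetic disk
is recovered exactly. Components under 50 px are rejected ("no cell
found"). The crop is a fixed 64×64 window centered on the mask centroid,
padded with the median background; a fixed window (rather than a tight
bounding box) keeps the feature extractor's geometry uniform.

## The 548-feature registry

The registry is fixed and versioned: 43 geometry, 10 granularity, 43
intensity, 452 texture, in immutable order. Parity with any specific
profiling tool's feature identities is not claimed; the taxonomy, counts and
index ranges are the contract.

* **Geometry (1–43).** 13 shape scalars — area, perimeter (Crofton
  estimator, far less biased than pixel-edge counting on smooth
  boundaries), form factor 4πA/P², solidity, extent, eccentricity,
  major/minor axis lengths, orientation, compactness P²/(4πA), equivalent
  diameter, max/min Feret diameter (convex hull + rotating calipers, +1 px
  for pixel extent) — plus 30 Zernike moment magnitudes (orders n = 0–9,
  same-parity m ≥ 0) of the binary mask mapped to the unit disk
  (centroid-centered, radius = max centroid distance). Magnitudes are
  translation- and scale-invariant and vanish for m > 0 on rotationally
  symmetric shapes.
* **Granularity (44–53).** A 10-scale granular spectrum: at scale s the
  fraction of masked intensity removed between reconstructive openings of
  scale s−1 and s (erosion with a disk of radius s followed by
  morphological reconstruction under the original). Reconstruction makes
  the sieve exact — plain openings with discrete disks are not monotone in
  the radius, which would allow negative bins — so every bin is
  non-negative, the spectrum sums to ≤ 1, and a constant-intensity cell
  yields exactly zero.
* **Intensity (54–96).** Ten statistics (integrated, mean, median, sd,
  MAD, min, max, quartiles, IQR) over the mask; the same ten over the
  1-px boundary ring; mass displacement (binary vs intensity-weighted
  centroid); centroid x, y; and a 10-ring equal-area radial profile (mean
  and coefficient of variation per ring, rings = equal-count distance
  deciles from the centroid).
* **Texture (97–548).** Thirteen Haralick statistics of the gray-level
  co-occurrence matrix at 4 angles × 8 distances (1–6, 8, 10 px) = 416
  values, plus Gabor energy at 4 orientations × 9 wavelengths (2–32 px)
  = 36. The GLCM uses 8 gray levels over the masked intensity range (ties
  to the lower bin), counts only pixel pairs fully inside the mask, and is
  symmetrized and normalized. Entropies are base 2. Degenerate cases follow
  sentinel rules: offsets admitting no pair, or statistics with zero
  denominators (correlation of a constant patch, IMC1 with zero marginal
  entropy), yield 0 and are logged. Gabor envelopes are capped at σ = 8 px
  so long-wavelength filters stay local to the 64 px crop; the masked mean
  is removed before filtering.

Non-finite values anywhere in the vector are replaced by 0 with a per-cell
log entry; extraction is deterministic.

## Classification

Features are z-scored with parameters fitted on training rows only
(zero-variance features map to 0); unscaled 548-dimensional inputs would
make a linear SVM scale-sensitive. The margin optimization is delegated to
liblinear (squared hinge, C = 1 by default, exposed as a flag); w and b are
exposed and serialized as JSON. Ties (Y = 0) go to the control class
deterministically. Cross-validation is stratified 10-fold with the
standardizer and SVM fitted inside each training fold (k = n is accepted as
leave-one-out). Classes are balanced by downsampling the larger class
before CV.

Per-dose accuracy uses the four control-group × treated-group pairings
across the two repeats ("four trials"); the dose-response table reports the
trial mean, the trial-to-trial standard error, and the mean within-trial CV
standard error separately, since the two error sources are not the same
thing. Transfer matrices train one model per (dose, experiment) condition
on an 80% stratified split; the diagonal is evaluated on the held-out 20%
only, off-diagonal cells on the full test condition; missing datasets are
NaN, never 0.

## MMD

The unbiased empirical squared MMD with Gaussian kernel
k(x, y) = exp(−‖x−y‖²/2σ²) is computed with within-sample sums excluding
i = j and the cross term over all m·n pairs — the standard unbiased form;
a `printed` variant that also excludes index-equal cross pairs is provided
for comparison with a form sometimes seen in print, and the two differ by
exactly the excluded diagonal terms. The estimator may be negative; the
reported non-negative score is √max(0, MMD²), and both numbers are kept.

Bandwidth defaults to the median heuristic — the median of nonzero pairwise
Euclidean distances over the pooled sample (subsampled beyond 2,000 points
with a logged seed, since the computation is quadratic) — falling back to
the smallest nonzero distance when the median is 0, and erroring when all
points coincide. Per-feature MMD standardizes each feature by its pooled
mean and scale first (otherwise raw feature scale, not distributional
difference, would dominate the ranking) and uses a per-feature median
heuristic; constant features score 0. Ranking is by descending score with
ties broken by ascending registry index. Whole-space MMD in the pipeline
subsamples each class to 2,000 rows by default for the same quadratic-cost
reason.

The elimination curve removes low-MMD features by rank and reports k-fold
CV accuracy at a descending, approximately log-spaced grid of retained
counts, holding the fold seed fixed so the full-feature point equals the
unrestricted CV exactly.

## Numerical and design choices

* All randomness flows through `numpy.random.default_rng` seeded per
  operation; pipeline stage seeds derive from the master seed via CRC32 of
  a stage tag (stable across platforms, < 2³¹). Reruns of a config are
  bit-identical.
* Problem sizes: the default pipeline and the acceptance checks run at
  1,000 cells per condition with the feature-table surrogate; 10,000 per
  condition — the full emulated scale — is a config change
  (`n_per_condition=10000`). The chance-floor calibration uses 2,000 cells
  per class × 20 seeds. Image-path runs are used at small n for
  verification of the full chain, since rendering plus extraction costs
  ~1.5 s per cell.
* The chance-floor check compares the mean CV accuracy under an exact null
  against the binomial 99% confidence band for one experiment's pooled
  test size (N = 4,000).
* Degenerate inputs are rejected with messages naming the valid values
  (unknown dose/duration, n < 2, single-class training data, all-identical
  MMD samples) or handled by documented sentinels (feature extraction).

## Known limitations

* The linear SVM's estimated accuracy at the peak condition sits below the
  configured Bayes ceiling at desk-scale n (548 dimensions, C = 1); it
  approaches the ceiling as n grows.
* Per-feature MMD on 1-D samples is O(n²) per feature; at 1,000 rows per
  class a full 548-feature ranking takes tens of seconds.
* The surrogate's identity covariance makes per-feature ranking easier
  than on real profiles, where correlated feature families share signal.
* Min-Feret and perimeter carry ±1 px discretization conventions; they are
  consistent within the registry but not comparable across tools.
* Frames containing multiple surviving components keep only the largest
  cell; doublet splitting is out of scope.
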