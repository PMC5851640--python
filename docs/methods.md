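# Methods

This note records the models implemented in `sonartex`, the defaults and
the reasoning behind the choices that the method itself leaves open.

## Coordinate and grid conventions

Grids are row-major with row 0 the northernmost row; a raster's `origin` is
the outer (north-west) corner of cell (0, 0), and all polygon membership is
decided by cell- or window-centre containment, with later-listed polygons
winning where they overlap.  Rasters are exchanged as ESRI ASCII grids
(8-bit values, explicit nodata) with an optional `.prj` sidecar carrying the
CRS tag untouched — the package never reprojects.  Point-cloud gridding
defaults to a search radius of 2 × cell size; nodes with no point inside the
radius are nodata, and exact nearest-distance ties go to the lowest point
index so gridding is deterministic.

## GLCM texture model

Grey levels are quantized by the fixed global map `floor(g·N/256)` (default
N = 64) rather than per-image min–max scaling, so calibration signatures
transfer between scans recorded at different gains.  Pair tabulation is
directed (reference pixel → pixel at offset (d, θ)) by default, with a
`symmetric` switch; offsets follow the compass convention θ = 0 → (0, +d),
45 → (−d, +d), 90 → (−d, 0), 135 → (−d, −d) on the north-up grid.  Both
pixels of a pair must be valid for it to count.

Windows tile the raster from its origin without overlap; only complete
L×L-pixel windows are evaluated (the lattice is ⌊rows/L_px⌋ × ⌊cols/L_px⌋ —
a partial window could not be anchored without overlap, so edge remainders
are dropped), and a window's features are defined only when at least 75 % of
its cells are valid, coverage being counted over cells rather than pairs.
Entropy uses the natural logarithm.  GLCM correlation — the standard
co-occurrence correlation of the i and j marginals — is reported NaN when a
marginal variance is zero (e.g. constant windows).  Defaults d = 5, θ = 0,
L = 3 m follow the parameter study behind the method: smaller windows track
texture variation better, larger d widens entropy at the cost of
homogeneity, and the reference angle has little effect on near-isotropic
riverbed textures.

## Calibration signatures

Zonal first-order statistics pool intensities across all patches of a class
before computing moments (never means of per-patch means); CV is σ/mean and
kurtosis the Fisher (excess) convention.  The texture calibration matrix
holds the bootstrapped median (default B = 10 000, percentile 95 % interval,
seeded) of each feature over each class's windows, a window belonging to a
class iff its centroid falls in one of its polygons.  Homogeneity enters the
calibration as H′ = 1 − H so every calibrated feature increases with grain
size.

## Least-squares unmixing

Each window's feature vector `o` is modelled as a convex mixture of class
signatures.  We solve the *simplex-constrained* problem
`min ‖C_z u − o_z‖², u ≥ 0, Σu = 1` (via NNLS on a system augmented with a
heavily weighted sum-to-one row), with features z-scored by the spread of
the class signatures so entropy, H′ and GLCM variance contribute on
comparable scales.  The constraint matters: the three signatures are nearly
collinear in the (E, H′) plane, and an unconstrained non-negative fit
followed by renormalization lets a scaled copy of any single signature
"explain" any window, making the fractions ill-posed.  The simplex solution
agrees with a brute-force grid minimizer over the simplex (property-tested).

Confidence is `α_q = u_q / Σ_{n≠q}(1 − u_n)`, which for q classes with
Σu = 1 equals `u_q/(q−2+u_q)`; at q = 3 it is bounded by 0.5 (a pure
end-member) and equals 0.25 for uniform u.  A window is assigned a null
substrate when *every* α lies strictly inside the open band (0.15, 0.25).
Note an algebraic consequence: for u exactly on the simplex,
max α = max u/(1 + max u) ≥ 0.25 at q = 3, so the band can only fire for
confidences perturbed off the simplex (e.g. from an unconstrained solver);
with this package's exact solver null labels do not occur, and the band is
retained for compatibility with externally supplied confidences.

Optional class weights (`u′_q ∝ w_q u_q`, renormalized; Σw = 1) are fitted
by exhaustive search of the weight simplex in 0.1 increments maximizing the
unweighted mean of per-class accuracies — balanced accuracy, since the
weights exist to rescue the hardest class (gravel) at some cost to the easy
ones.  Ties prefer the maximizer closest to uniform weights (then
lexicographic order), so equal weighting is returned whenever it is already
optimal.

## Gaussian mixture classification

The expectation–maximization fit supports full, diagonal, spherical and
tied covariance structures, with a 10⁻⁶ diagonal floor, relative
log-likelihood tolerance 10⁻⁶ and at most 300 iterations; the
log-likelihood is asserted non-decreasing at every iteration, and
posteriors are evaluated in log space.  Features are fitted on raw
(unstandardized) values so component means remain directly comparable to
calibration medians; z-score externally if features of very different
scale are combined.

Model search (component count 1–5 × four structures × feature subsets) is
scored by BIC = −2 lnL + k ln n with k the exact free-parameter count per
structure.  Search fits are "uninitialized": seeded random observations
serve as hard-assignment cluster seeds, with no proposed solution that the
fit could merely confirm.  (Soft random responsibilities were considered
and rejected: averaging them places every component mean at the grand
mean, a symmetric E-M stationary point from which the algorithm does not
escape.)  A selected model is then re-fit initialized at the calibration
class means; for a 4-component model the two gravel means are the linear
midpoints between the gravel median and each neighbouring class median.

Components map to substrates by their mean along the first feature shared
with the calibration, oriented by the calibration's grain-size trend:
2 components → (sand, boulders), 4 → (sand, gravel, gravel, boulders),
anything else by nearest calibration signature in z-scored distance.
Windows are labeled by their maximum-posterior component; a maximum below
the acceptance threshold (default 0.6 — it must exceed 0.5 to ever reject
under a 2-component model) is labeled "other".  Per-substrate posterior
maps are the sums of member-component posteriors and sum to one wherever
defined.

## Evaluation

Null / "other" windows count against recall (missed windows) but are never
false positives of a substrate; macro averages are unweighted over classes
present in the truth.  Areal fractions are taken over substrate-classified
windows only.  Downstream distance for the cumulative-fraction curves is
the arc-length projection of window centroids onto a user-supplied track
line, falling back to the first principal axis of the classified windows
(oriented so distance increases from the first classified window in lattice
order).

## SLIC windowing

Superpixel segmentation runs iterative intensity–position clustering on the
valid region (compactness 10 on the 8-bit scale, 10 iterations, grid
seeding — deterministic for fixed inputs), merging orphan fragments into
their dominant neighbour.  Per-superpixel GLCMs count only pairs entirely
inside one superpixel and satisfy the same invariants as windowed GLCMs;
a diagnostic reports the fraction of superpixels touching nodata, the
qualitative sign of under-segmentation.  The superpixel-count heuristic is
a zero-intercept least-squares slope (Σxy/Σx²) of count on echogram length;
the packaged reference pairs give ≈ 1.46 superpixels per metre.

## Synthetic scenes

The generator emulates the *statistical* structure of echogram textures,
not sonar physics (no beam pattern or ensonification geometry): per class a
Gaussian random field smoothed to a correlation length and scaled to a
contrast, plus Poisson-placed clasts — each with its own backscatter level,
internal facet noise, and a probabilistic adjacent dark shadow.  Defaults:
sand (correlation 6 cells, contrast 8, no clasts), gravel (1.5, 25, sparse
1-cell clasts), boulders (0.8, 55, 3-cell clasts at supra-pixel density
with frequent shadows).  The reference scene is 400 × 120 cells at 0.25 m
(100 m × 30 m), three downstream bands of sand / gravel / boulders, patch
polygons inset 1.5 m from band edges as a manual delineator would avoid
transition zones, and a nadir nodata stripe.

These choices produce window-entropy medians ordered sand < gravel <
boulders and unimodal per-class feature distributions — the regime the
classifiers assume.  What passing tests on such scenes shows is that the
pipeline recovers a planted layout whose texture statistics match its
assumptions; it does not certify performance on field data with positioning
error, attitude artefacts, vegetation, or radiometric drift, none of which
are simulated.

## Problem sizes and budgets

Tests and the acceptance script use the 100 m × 30 m reference scene
(a 33 × 10 window lattice, ~220 labeled windows), bootstrap B = 10⁴ for
calibration matrices (smaller in unit tests), n = 600–1000 samples for
mixture-recovery studies and 20 seeds for the BIC order-recovery rate —
sizes chosen so the whole suite runs in well under a minute on one CPU
while keeping Monte-Carlo noise far from the asserted margins.

## Known limitations

- The LSQ confidence band (0.15, 0.25) is unreachable under the exact
  simplex solver (see above); null rates will be zero unless confidences
  come from elsewhere.
- GLCM correlation is excluded from the default calibration features; it is
  frequently undefined on smooth windows.
- No geostatistical interpolation into unclassified regions, no spatial
  smoothing of labels, and no change detection between survey dates.
- Decoding of proprietary sonar recordings, radiometric/geometric
  correction and georectification are upstream of this package: it starts
  from georeferenced intensity point clouds or grids.
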