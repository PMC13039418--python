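# Methods

This note documents the models, parameters and numerical choices behind
`mplexquant`, and what the synthetic phantoms do and do not establish
about behaviour on real slides.

## Conventions

Coordinates are 0-based `(row, col)` pixel indices with the origin at the
top-left; areas are reported both in px² and µm² (`µm² = px² ×
pixel_size_um²`). Label maps are integer rasters with 0 reserved for
background and labels contiguous from 1. The default pixel pitch is
0.65 µm/px, the acquisition scale all pixel-valued defaults are quoted at.

## Registration

Rounds are aligned on their nuclei channels. A transform maps the moving
image onto the fixed frame through inverse warping:
`aligned(x) = moving(A(x + d(x)))`, with `A(x) = s·R(θ)(x − c) + c + t`
the rigid map about the image center and `d` a dense displacement field.
All intensity interpolation is bilinear; out-of-domain pixels are 0.

**Rigid stage.** Images from different modalities are first rescaled to a
common pixel size (bilinear, written in the `a + w(b − a)` form so constant
images are preserved exactly). The rotation is found by scoring candidate
angles (±10° in 0.25° steps) with the normalized cross-correlation at the
phase-correlation translation, on 10×-downsized (block-mean) images, then
refined locally in 0.1° steps at 2× downsizing; the translation is finally
re-estimated at full resolution with subpixel phase correlation
(upsampling 20). Degenerate (constant) inputs raise an estimation error
rather than returning a spurious transform.

**Deformable stage.** Displacements are estimated on a coarse grid
(default spacing 500 px, nodes covering the full image extent) at full
resolution. Each node is measured by phase correlation of a window
centered on it; a node keeps its estimate only if the NCC at the recovered
shift reaches 0.3, otherwise it inherits the linear interpolation of its
confident neighbours (zero field if no node is confident) — this prevents
wild vectors in featureless tiles. Two deliberate choices:

- *Half-step windows with iterative refinement.* A window as wide as the
  grid step averages the bilinear field over ±half a cell, mixing ~44 % of
  the neighbouring nodes into each measurement; high-frequency
  (checkerboard) error modes then decay too slowly for sub-pixel node
  recovery. The matching window therefore defaults to half the grid step,
  and the field is refined by re-warping the moving image with the current
  grid and accumulating residual node shifts (at most 6 rounds, stopping
  when the largest update is below 0.15 px). On phantoms this reaches
  ~0.2–0.8 px interior-node error for ±4 px fields.
- *Gauge fixing.* A constant displacement field is indistinguishable from
  rigid translation (`A(x + μ + d') = A(x + d') + sRμ`). Estimates are
  normalized by moving the node-mean of the grid into the translation
  (`normalize_decomposition`); the phantom generator likewise plants
  mean-zero node fields, so recovered and planted decompositions are
  comparable. Only the composite warp is physically meaningful.

`apply_transform` composes both stages in a single resampling pass
(coordinates `A(x + d(x))`), avoiding double interpolation blur.

## Nucleus detection and cell tessellation

The built-in detector is classical: background subtraction, Gaussian
smoothing (σ = 2 px), thresholding (Otsu unless an absolute value is
given), Euclidean distance transform + peak-marked watershed to split
touching nuclei, and removal of objects under 20 px. It is deliberately a
pluggable interface: any detector producing a nucleus label map (including
pretrained deep models) can be substituted; downstream stages consume only
the label map. Blank or constant images yield an empty map, not an error.

Cell regions are the bounded expansion of nuclei: a background pixel joins
the nucleus whose nearest pixel is closest in Euclidean distance, if that
distance is ≤ `round(4.5 µm / pixel size)` = 7 px at 0.65 µm/px
(half-up rounding). Equidistant pixels — the midpoint locus between two
nuclei — are assigned to the smaller label, a deterministic, oracle-checkable
tie rule. The implementation runs one small windowed distance transform
per nucleus and compares exact integer squared distances, so ties are
resolved exactly; the test suite verifies exact label-map equality against
an independent KD-tree brute force. Monotonicity (larger radius never
shrinks a cell) follows from the per-pixel minimization and is
property-tested.

## Background estimation and features

Per channel: block-average downsizing by 10 (edge-padded to a block
multiple), a 7×7 median filter, and bilinear upscaling to the original
shape; correction is `max(0, I − bg)`. Numerical care: block means are
computed relative to a local reference value and the bilinear forms use
`a + w(b − a)`, so an exactly constant image yields an exactly constant
background at any dtype — a useful contract for sanity checks.

Morphology comes from the second-moment ellipse (aspect ratio =
major/minor axis) and the Crofton perimeter (circularity `4πA/P²`,
clamped to 1 against rasterization overshoot; a discrete disk of radius
10 px scores ≥ 0.85). Intensities are per-label sums/means via bincount;
`total = mean × pixel count` holds to rounding by construction.

## Islet segmentation and statistics

Binary map: insulin > t₁ OR glucagon > t₂. Thresholds default to manual
config values (matching practice on real slides); the automatic mode runs
Otsu over the *stained* (non-zero) pixels, because background-corrected
slides are mostly exact zeros and a whole-image Otsu would otherwise
detect "any stain at all". Refinement: morphological closing then opening
with a disk of radius 3 px (~2 µm; the close-open filter is idempotent,
which is asserted in tests), then filling of fully enclosed holes.
Components are filtered **after** hole filling so every final region
satisfies the 400 µm² rule (`ceil(400/0.65²)` = 947 px); the filter is
exact with respect to component pixel areas.

Islet features: area, aspect ratio, circularity and solidity ("shape
factors"), per-channel mean/total over the mask, and a cell census by
nucleus-centroid containment with per-subtype counts and fractions (the
four-way endocrine partition sums to 1). Association statistics are
pairwise two-tailed Pearson correlations (p from the t distribution with
n − 2 df; zero-variance variables reported as missing) and occurrence
versus islet size over equal-count area bins, with the convention that an
exactly constant fraction reports r = 0 (a flat profile) rather than an
undefined correlation.

## Expression landscape

The matrix uses the nuclear mean per marker, except markers flagged
cytosolic (e.g. P16), which use the cell-region mean. Cells are restricted
to non-overlapping square ROIs (default 2000 px ≈ 1.3 mm side, 11 ROIs)
chosen by deterministic greedy row-major packing avoiding an optional
artifact mask. Clustering: global per-marker z-scores (zero-variance
markers contribute a zero column), full PCA, retention of the minimal
number of axes whose cumulative explained variance reaches 95 %, K-means
(k-means++ with 10 restarts, fixed seed). Cluster profiles are per-cluster
mean z-scored marker vectors; occurrence fractions sum to 1. Z-scoring
makes the result invariant to marker order and to affine rescaling of any
marker column (verified by tests). k defaults to 20 and is user-facing, as
is the ROI count; both are study-level choices, not estimated quantities.

Positivity thresholds per marker: manual value, quantile, or automatic
bimodal (Otsu on log1p intensities — robust to the right-skew of
fluorescence intensity distributions). Endocrine subtype is the positive
marker among insulin/glucagon/SST-28; multi-positive cells take the marker
with the highest z-score; cells positive for none are "negative".
Co-occurrence statistics report `P(y+ | x+)` with a Wilson 95 % CI and,
optionally, the mean of a quantitative marker in the four (x±, y±) groups
with group sizes and SEMs; an empty x⁺ set yields a missing fraction with
n = 0 rather than an error.

2D embeddings for visualization use UMAP when installed and degrade to the
first two principal axes (with a logged notice) otherwise, also for very
small inputs where a neighbourhood graph is meaningless (n < 10).

## The tissue phantom

The generator emulates the statistical structure the pipeline is meant to
quantify, with exact ground truth:

- **Geometry** — non-overlapping elliptical nuclei (radii 2.6–5.2 µm,
  axis ratio 0.7–1) placed by rejection sampling (capacity error if the
  requested density is infeasible); cell regions from the same tessellation
  rule the pipeline uses; circular islet compartments.
- **Expression** — each cell draws a profile from a mixture: acinar cells
  from exclusive single-marker-high clusters (high 10 ± 1) plus a diffuse
  low-expression mass (1 ± 0.3, 40 % of cells by default), islet cells
  from an endocrine subtype mixture (β 0.55, α 0.30, δ 0.15). The high/low
  separation (~10 SD) and the tight negative mass reflect amplified
  staining of clearly positive populations over a detection-floor
  background, and make planted-structure recovery a well-posed target.
- **Rendering** — nuclear markers paint the nucleus, cytosolic markers the
  annulus between nucleus and cell boundary; an interstitial islet matrix
  stain (insulin/glucagon outside any cell) keeps islet regions contiguous
  without touching per-cell intensities, so noiseless phantoms reproduce
  drawn values exactly through feature extraction. A smooth low-frequency
  background field (bilinear upscale of a 9×9 random grid) models
  autofluorescence; heteroscedastic noise with σ ∝ √(1 + I) models
  shot-like statistics and is applied last.
- **Misalignment** — `generate_round_pair` plants a rigid transform plus a
  mean-zero uniform(±amplitude) node field (amplitude < step/4) and builds
  the moving round by numerically inverting the aligning warp (damped
  fixed-point iteration to < 10⁻³ px), so the stored truth is exactly the
  transform registration must estimate.
- **Planted statistics** — `planted_islet_population` draws
  (area, marker) pairs from a bivariate normal with the requested
  population correlation; `sample_cluster_expression` draws expression
  matrices without rendering, for clustering benchmarks.

All generator randomness flows from a single seed; outputs are
bit-reproducible.

**What the phantoms do not show.** No optics (PSF, vignetting, spectral
bleed-through), no staining artifacts (folds, edge effects), no irregular
islet shapes or spatial cell-type gradients, and nuclei that are cleanly
separable by construction. Passing the recovery suites therefore
establishes correctness of the algorithms under their stated models —
not detector robustness on difficult real tissue, for which the pluggable
detector interface and manual thresholds exist.

## Problem sizes and benchmarks

Registration benchmarks use 1250² px phantoms (~900 nuclei) so the 500 px
grid has interior nodes while a 20-phantom recovery study stays fast;
clustering benchmarks use 5,000 cells; the islet-filter study uses planted
disks straddling the 947 px cutoff, kept either clearly overlapping or
clearly separated so morphological closing cannot create regions the
area oracle does not see. `scripts/acceptance.py` re-runs all of these
from scratch from a single seed.

## Known limitations

- Rotation search is bounded (±10°) and assumes ≥ 50 % content overlap;
  slides requiring large rotations or with little common content need an
  initial manual transform.
- The deformation model is a single-scale bilinear grid; warps with
  structure finer than the grid step are absorbed as local error.
- The classical nucleus detector under-segments dense clumps with weak
  distance-transform cores; use the detector interface for such tissue.
- Cluster count k is not selected automatically; the workflow reports
  whatever structure k imposes (profiles + occurrences) and leaves model
  selection to the analyst.
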