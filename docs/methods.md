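# Methods

This note documents the models, numerical choices and known limitations of
`erymorph`. Units throughout: lengths in µm, areas in µm², calibration in
µm per pixel; haematology in analyser units (HGB and MCHC g/L, HCT as a
fraction, MCV fL, MCH pg, RDW %).

## Segmentation and measurement

Stained erythrocytes appear darker than the smear background. Segmentation
converts RGB input to luminance, thresholds it (Otsu by default; a fixed
threshold is available for atypical staining), fills interior holes so the
central pallor of discocytes does not split a cell, removes anything
touching the image border (such cells cannot be measured completely), and
labels connected components. Each component's boundary is extracted as a
sub-pixel marching-squares contour.

**Contour smoothing.** Raw marching-squares vertices trace pixel-level
staircases and systematically overestimate the perimeter of smooth shapes
(the classical crack-boundary inflation is ~11 % for a circle, and even
interpolated contours retain a few percent). Boundary coordinates are
therefore circularly Gaussian-filtered (`smooth_sigma`, default 2 vertex
steps) before any measurement. For a disk of radius 40 px this brings both
area and perimeter within 0.5 % of the closed forms; the curvature bias
introduced by smoothing scales as σ²/2r in pixels and is negligible at
cell-sized radii.

**Measures.** Area and convex-hull area come from the (shapely) polygon;
outline is the smoothed polygon's length; length is the maximum Feret
diameter over convex-hull vertices and breadth the maximal caliper extent
perpendicular to the length axis; minimal/maximal radius are the extreme
centroid-to-vertex distances. Interpreting length/breadth as caliper
diameters (rather than fitted-ellipse axes) is a deliberate choice: it
gives roundness exactly 1 for a circle and length = side·√2 for a square,
and published panel means behave like caliper values (length ≈ 2× maximal
radius). How the original acquisition software defined these quantities is
not documented; these definitions are explicit stand-ins.

**Exclusion rules.** Only clean single cells are measured, matching the
original protocol of excluding rather than splitting overlaps. A component
is rejected if its area is below the debris floor (default 6 µm²), above
the single-cell ceiling (default 32 µm², sized to the synthetic geometry
of 2.0–2.9 µm semi-minor axes; real panels with larger cells need a larger
ceiling), its solidity is below 0.95, or its boundary dips more than
0.2 µm inside its convex hull. The concavity rule is the discriminating
one: two fused ellipses always carry a concave neck (≥ 0.4 µm deep for any
overlap geometry we generate) while a single digitized ellipse is convex
to within ~0.02 µm at 0.05 µm/px, so the rule separates the classes with
an order-of-magnitude margin where solidity alone does not.

## Shape indices

The six descriptors are computed verbatim from the size measures (see
README table). "Major axis" in roundness is the caliper length. Indices
are never clamped: rasterization can push form factor slightly above 1 or
the contour index below 2√π, and `flag_out_of_range` reports such cells
instead of silently fixing them. Elongation and ellipticity satisfy
elongation = (ellipticity − 1)/(ellipticity + 1) identically, which the
property suite checks exactly.

## Subpopulation typing

PCA runs on the correlation matrix (the variables mix µm, µm² and
dimensionless scales), implemented as an SVD of the z-scored data
(ddof = 1); the test suite cross-checks the eigenvalues against a direct
eigendecomposition of `numpy.corrcoef` to 1e-8. The Kaiser rule is
inclusive (λ ≥ 1). No rotation is applied by default.

**Representative variables.** Each retained factor is represented by its
largest-|loading| variable. Loadings within 0.05 of the factor maximum are
treated as practically equivalent — variables that correlate > 0.97 with a
factor are interchangeable as its representative — and such ties resolve
to the earliest variable in the canonical column order (outline, convex,
area, length, breadth, roundness, form factor, contour index, elongation,
ellipticity, solidity). This matters in practice: area, convex and outline
form a structural near-tie on the size factor (their published loadings
are 0.97/0.98/0.98), and elongation/ellipticity are monotone transforms of
each other, so a strict argmax flips between equivalent anchors from
sample to sample. `tie_tol=0` recovers the strict rule.

**Cluster count.** A gap-type statistic stands in for the proprietary
"aligned box criterion" of the original software: for each candidate k,
within-cluster dispersion W_k (canonical form — summed squared Euclidean
distance about cluster centroids) is compared against its mean log under
uniform reference draws from the data's axis-aligned bounding box, and the
k maximizing the gap wins. Two choices were settled empirically and are
worth recording. First, defining W by the L1 clustering objective instead
of the canonical squared form makes the gap curve monotone decreasing even
on clearly trimodal data. Second, clustering runs on the **raw**
representative variables, not z-scored ones: classical k-means procedures
do not rescale inputs, and here the scale carries the information — the
size representative (SD ≈ 1.4 µm) dominates the metric while roundness
(SD ≈ 0.06) and elongation (SD ≈ 0.03) contribute little, which is
exactly right because the subpopulations separate along size. On z-scored
representatives two of three dimensions are inter-cluster noise and the
gap statistic cannot resolve k at all. `standardize_clustering=True`
switches to the z-scored variant.

**Robust k-medians.** Centers are coordinate-wise medians under L1
distance (the analogue of a least-absolute-deviations criterion); points
farther than `strict_multiplier` (default 3.0) times the median
within-cluster distance are held out during iterations so tails do not
drag centers, then assigned to their nearest center in a zero-iteration
pass. Initialization spreads seeds with D-weighted sampling under L1;
the best of `n_init` restarts (default 10) by retained-point objective is
kept; empty clusters re-seed from the farthest held-out point. On every
fixture of ≤ 8 points the converged objective equals the exhaustive
partition optimum. Clusters holding under `min_proportion` (default 5 %)
of cells are dissolved into the cluster with the nearest center,
recursively. Final clusters are named ES1/ES2/ES3 by ascending mean
outline (smallest, largest, remainder); for k ≠ 3 the naming degrades to
ES1..ESk with a warning.

**Partition bias, quantified.** Voronoi boundaries sit midway between
centers regardless of cluster weight. On an overlapping mixture this
biases recovered shares: for the default three-component structure
(weights 19.5/57.6/22.9 %, outline separations ≈ 2.5 SD) the exact
population fixpoint of 1-D k-medians — computed by an independent
root-finding oracle in the test suite — yields shares 27.2/45.9/27.0 %.
The full chain reproduces this equilibrium within ~1–3 points per draw
(the optimal boundary lies in a flat region of the objective, so its
finite-sample location wobbles). Latent mixture weights are therefore not
recoverable to a few points by any k-means-family clusterer at this
overlap; a published cluster table produced by such a clusterer already
contains the same bias. The Bayes-optimal classifier itself only reaches
an adjusted Rand index of ~0.63 against the latent labels here; k-medians
reaches ~0.5, about 80 % of that ceiling.

## Group statistics

Groups are formed per haematological index by cut-off; every rule is
"Group 1 iff value ≤ cutoff" except MCHC, which uses strict "<" (the
published grouping's asymmetry, copied cell by cell). Box–Cox selects λ by
profile log-likelihood over a grid (default −2..2 in steps of 0.05; λ = 0
means log). The two-group MANOVA computes Wilks' Λ = |E|/|E+H| directly
and uses the exact F transform for two groups, cross-checked against
statsmodels' MANOVA to 1e-8 and against the t² identity for p = 1 to
1e-10. Tukey-adjusted least-square means go through statsmodels'
`pairwise_tukeyhsd`; with two groups the adjusted p equals the pooled
t-test p. The chi-square is Pearson's without continuity correction on
the 2×3 table (df = 2), the default of the statistical software the
original analysis used.

`reconstruct_counts` rebuilds integer contingency tables from printed
percentages: counts are rounded per cell and the residual (at most 1 per
row) is absorbed into the cell with the largest printed percentage, so row
sums match the printed totals exactly. Five of the six published
chi-square statistics are reproduced within 0.9 % this way; the HGB
statistic differs by 3.2 %, and exhaustive enumeration of *all* integer
tables consistent with the printed percentages and row totals shows none
reproduces the printed value — the published number is internally
inconsistent with its own percentage table at that row.

Cells are treated as independent observations in all group tests,
mirroring the original per-RBC analysis. Cells from one sheep are in fact
correlated (shared physiology, staining and focus), so the per-cell
p-values overstate evidence at the sheep level; a mixed-effects treatment
is deliberately out of scope and this caveat should be kept in mind when
interpreting the group reports.

## Synthetic data

The generator defines the testable study conditions.

**Images.** Cells are ellipses (semi-minor axis uniform in 2.0–2.9 µm,
axis ratio 1.0–1.25, default field 1024² px at 0.05 µm/px) rendered dark
on a light background with an optional brighter central-pallor disk at
half the cell radii, so segmentation must tolerate non-uniform interiors.
A configurable fraction of cells is placed deliberately overlapping
(center distance 0.55–0.85 of the summed semi-major axes); debris blobs
are small irregular star polygons (well under half the minimum cell area)
placed on free background, since debris lying entirely inside a cell's
footprint would be invisible to any image-based method. Overlap flags in
the ground truth are computed by exact polygon intersection. Pixel noise
is additive Gaussian, default σ = 5 % of the dynamic range. Identical
seeds give bit-identical images and tables.

**Feature tables.** Each cell draws a component (default: the published
three-subpopulation structure — outline 15.38/17.21/19.11 µm with SDs
0.59/0.73/0.73 and weights 19.5/57.6/22.9 %, roundness ≈ 0.82, elongation
≈ 0.058 per component) and three latents: outline, elongation, and a
boundary-irregularity factor q. Modelling cells as mildly irregular
ellipses, realized roundness is q·(1−e)/(1+e) — for an exact ellipse
roundness equals breadth/length — with q's per-component moments derived
so realized roundness matches the configured component values. Form
factor and solidity respond linearly to q (correlations 0.95 and 0.7,
SDs 0.035 and 0.008) plus independent noise; area, convex hull, contour
index, length, breadth and ellipticity follow from the defining formula
identities, which therefore hold exactly on every generated row. A small
independent hull-measurement jitter (0.5 %) keeps convex from being a
perfect copy of area. With these defaults the correlation structure
splits into one size factor and two shape factors with exactly three
eigenvalues above 1 (≈ 4.8/3.2/2.3, ~94 % cumulative) and factor anchors
at outline, roundness and elongation. Several alternative noise
structures (attributing form-factor noise to the perimeter trace,
correlating q with elongation) were evaluated and rejected: they either
broke the three-factor structure or degraded the anchor margins.

**Sheep panels.** Sheep alternate deterministically between a low-side
and a high-side haematological profile drawn uniformly within ranges
flanking each grouping cut-off, so both groups of every cut-off are
non-empty for any panel of ≥ 2 sheep. Cells are drawn i.i.d. from the
mixture and tagged with sheep ids; haematology is *not* coupled to cell
morphology, so group comparisons on default panels are null — useful for
calibration checks, but it means passing panel tests says nothing about
detecting real group differences (those are tested with explicitly
planted shifts).

**What the generator does not emulate.** Staining variability, uneven
illumination, rouleaux, white cells and platelets, optical blur,
sheep-level correlation of cell morphology, and any coupling between
haematology and morphometry. Passing tests demonstrate correctness of the
measurement and typing machinery under known geometry, not robustness to
real-world smear artefacts.

## Problem sizes and tolerances

Tests run panels of 4017 cells (the published panel size) for typing and
recovery checks, 10 seeds for the recovery suite, 1024² px images with 20
cells for segmentation fidelity, and ≤ 8-point fixtures for exhaustive
clustering oracles. Rasterized measurement tolerances are 2 % (area) and
3 % (perimeter) at radii ≥ 40 px; analytic shape identities are exact to
1e-9; PCA matches its oracle to 1e-8; probabilistic recovery tolerances
are stated per test next to the oracle that derives them.
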