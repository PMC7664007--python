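# Methods

This note documents the models and procedures implemented in `ippkit`, the
parameters that matter, the synthetic-data generator used to exercise them,
and the design choices made where more than one reasonable option existed.

## Inputs and coordinate conventions

One field *epoch* consists of three co-registered rasters: an 8-bit RGB
orthomosaic, a single-band DSM in metres, and a ground-elevation reference
`E_r` (the DSM of the first, pre-emergence flight). Raster indices are
0-based `(row, col)`; world coordinates are `(x east, y north)` metres with
rows advancing southwards. A north-up affine geotransform (GeoTIFF
pixel-scale + tiepoint tags) maps between the two; pixel area is
`Δσ = px·py`. Elevation no-data is NaN and is excluded from every
percentile and sum. If the three rasters' grids differ, DSM and ground
reference are resampled to the orthomosaic grid by nearest neighbour —
deliberately not bilinear, so elevations are never blended across the
plant/soil edge.

The field is partitioned into plots by a fishnet: bilinear interpolation of
the four boundary corners into `n_rows × n_cols` cells, which tiles the
boundary exactly (cell areas sum to the boundary area to machine
precision). Plot ids are assigned row-major as `r{row}c{col}`. Each plot is
cut from the rasters as its bounding-box window plus an inside-polygon
flag; the planting-line (ridge) direction is supplied per field as an angle
from the x-axis, default 0°.

## WEIPS segmentation

The segmentation rests on one observation: weeds share the crop's color
but not its height, while artifacts such as stakes can share its height
but not its color. Two candidate masks are therefore built per tile.

**Color mask.** A decision-tree classifier (depth ≤ 8, fixed random seed)
on per-pixel features `(R, G, B, ExG = 2G−R−B, g = G/(R+G+B))`, trained on
user-labelled pixels (≥ 10 per class). When no labels exist, an
unsupervised fallback thresholds the excess-green index by Otsu's method,
with an absolute ExG floor of 20 so an all-soil tile does not get split on
texture noise.

**Height mask.** Per-pixel canopy height `h = DSM − E_r` is thresholded at
`max(t, floor)`. The floor (default 0.05 m) guarantees near-ground weeds
are excluded even when the tile's histogram carries no usable structure.
The adaptive part `t` is estimated from the histogram (64 bins) of positive
in-tile heights by the **triangle method**. The choice of estimator
matters: a smooth canopy dome has an essentially *uniform* height histogram
(for a paraboloid dome the area density `dA/dh` is constant), topped by a
dominant near-ground mode from soil noise and weeds. Otsu's criterion, built
for bimodal histograms, places its threshold mid-dome in this situation
(measured 0.12–0.27 m on synthetic tiles) and cuts away the canopy skirt;
the triangle method finds the foot of the near-ground mode (measured
0.04–0.06 m), which is what "weeds are shorter than plants" actually
requires. Otsu remains available (`threshold_method="otsu"`) and both
coincide on genuinely bimodal tiles.

**Combination.** Default mode `region`: the color mask is cleaned
(opening radius 1 px, closing radius 2 px), split into connected
components, and each component is kept only if at least 20% of its area
(`min_height_support`) lies inside the height mask. Green components
without tall support are weeds; tall regions without green are stakes.
Among supported components the one whose centroid is nearest the plot
center is the focal plant (ties: larger area, then lower label) — the
focal plant was planted centrally, so this is the natural deterministic
rule. The plant keeps its full color extent, including the low canopy
skirt below the height threshold.

The alternative mode `intersect` is the strict pixel-wise AND of the two
masks followed by the same morphology and component selection. It bounds
the result inside `veg ∧ hgt` but unavoidably discards the skirt (roughly
`floor/H` of the canopy area, 4–11% for 0.5–1.5 m plants), which is why it
is not the default. When color and height evidence never coincide the
result is an empty mask with a warning string, not an exception, so batch
runs keep going.

An optional height cap (`cap_m`, default off) clamps the canopy height
model before thresholding. It documents the stake problem rather than
fixing it: capped or not, stake pixels that the orthomosaic renders as
canopy still contaminate the trait stage (below).

## Traits

Twelve planar shape descriptors are computed from the single-component
plant mask via region properties and scaled to world units: cover area
`n·Δσ`; major/minor axis lengths, orientation and eccentricity from the
ellipse with matching second central moments (orientation reported in
degrees from the x-axis in (−90°, 90°]); convex area; filled (hole-free)
area; equivalent diameter `√(4A/π)`; solidity `filled/convex`; extent
`A/bbox`; perimeter by the Crofton 4-direction formula; roundness
`4πA/P²`. Crofton was chosen for the perimeter because the chain-code
estimate overestimates a digital disk's circumference by ~4.8%, biasing
roundness to 0.91 where the analytic value is 1; Crofton gives 1.004 at
radius 100 px.

Canopy height is `E_p − E_r` with `E_p` the 99th percentile (linear
interpolation between order statistics, as everywhere in the package) of
the DSM over plant pixels — robust to isolated tall noise pixels — and
`E_r` the *median* of the ground reference under the same pixels, robust
to first-epoch noise. Whether the reference should be a per-plot scalar or
per-pixel is genuinely open; the scalar median is used for height, while
volume is per-pixel by construction. Negative heights pass through in the
height trait (flagged with a warning) so that registration errors stay
visible in validation, but are clamped to zero inside the volume sum
(clamped pixels are counted and reported). An empty mask yields volume 0
with a warning rather than an error so trait time series stay rectangular.

Volume is the cylinder sum `Σ max(h_i, 0)·Δσ` over plant pixels. On a
noise-free paraboloid dome of apex `H` and radius `R` it reproduces the
closed form `πHR²/2` to better than 0.1% at 4 mm GSD (the discretisation
error lives in boundary cells whose heights vanish).

## Canopy outline and form dissimilarity

Plant pixels are projected onto the ridge axis: each pixel contributes its
canopy height at its signed along-ridge distance from the mask centroid.
Distances are binned (default 433 bins of 0.375 cm, centroid at bin
`L//2`), and each bin holds the 99th percentile of its heights; empty bins
hold 0. Centering on the centroid is this package's registration
convention — plots sharing a common grid would make any fixed origin work,
but centroid centering removes the plot-placement nuisance before any
sliding happens.

Two outlines are compared by the minimum distance over the transform set
{slide by n, |n| ≤ 108} × {flip, no flip} applied to one argument. An
n-slide appends |n| zeros to one end and truncates the other (head for
n > 0, tail for n < 0); a flip reverses the vector. Because truncation
makes sliding non-invertible, the directed minima `d(a→b)` and `d(b→a)`
can differ; the operation returns their minimum, making the matrix
symmetric by construction. The kernel is Euclidean by default with an L1
option. The resulting dissimilarity is invariant to flips and to
admissible slides of either argument (sufficient zero margins), scales
linearly under positive scalar multiplication, never increases as
`max_slide` grows — and is *not* a metric: the transform minimisation can
break the triangle inequality, which is why group comparison uses
PERMANOVA rather than any embedding-based test. 108 bins of 0.375 cm
admit ±40.5 cm of translation.

## Evaluation statistics

**Qseg** is the Jaccard overlap of predicted and reference vegetation
pixels, `|A∩B| / |A∪B|` over vegetation; a strict all-pixel agreement
variant (pixel accuracy) is available behind `include_background=True` for
sensitivity checks. Two empty masks make the metric undefined and raise.

**Pearson validation** reports r, the two-sided t-based p, r², and the OLS
slope/intercept of manual on estimated values, covering both the
correlation and regression readings of a validation R².

**Gaussian one-way LRT.** Group-means model vs. grand-mean model under a
Gaussian likelihood with MLE variance: `LR = n·log(SSE_null/SSE_full)`,
referred to χ² with `k−1` df. The statistic is invariant to shifting and
scaling the data. Zero residual variance is rejected as degenerate input.
A second (planting-row) factor is out of scope.

**PERMANOVA.** Pseudo-F from the distance decomposition
`F = (SS_B/(k−1)) / (SS_W/(n−k))` with `SS_W = Σ_g (Σ_{i<j∈g} d²_ij)/n_g`
and `SS_T = Σ_{i<j} d²_ij / n` (equivalent to the Gower-centred form; the
implementation agrees with scikit-bio's to 1e-9, which serves as an
independent cross-check in the tests, never as the implementation). For
two groups with at most 20 000 distinct label arrangements the permutation
distribution is enumerated exhaustively and
`p = #{F_perm ≥ F_obs}/N_arrangements` (identity included); otherwise
random shuffles give `p = (b+1)/(B+1)`, default B = 9 999. Pairwise runs
test every group pair on the sub-matrix and report Bonferroni-adjusted
p-values alongside raw ones. Permutation batches are evaluated with a
vectorised within-group einsum, so a 1 000-replicate null calibration with
999 permutations each runs in seconds. Monte Carlo calibration studies
should use an independent RNG stream per replicate (the package's own
calibration harness spawns `default_rng([seed, rep])`); threading a single
stream through many replicates left the per-replicate tests exact but
produced visibly non-uniform batch rates in one observed realization.

## Synthetic scenes

The generator renders what the framework assumes about a single-grown
trial, with defaults fixed at the study conditions:

| parameter | default | rationale |
| --- | --- | --- |
| plot size | 1.0 m | single-plant spacing in the target trial design |
| GSD | 4 mm/px | typical low-altitude UAV product |
| plant apex height | U(0.5, 1.5) m | mid-season *Helianthus tuberosus*, which reaches 1.5–3 m |
| plant dome radius | U(0.15, 0.35) m | keeps ≥ 2 plants per metre non-overlapping |
| weed height | U(0.01, 0.05) m | ground-hugging seedlings |
| weed density | 10 / m² | visibly weedy but unmanaged-plausible clutter |
| DSM noise sd | 1 cm | photogrammetric elevation repeatability at this GSD |
| color noise sd | 12 (8-bit) | sensor + illumination variation |
| mulch strip | 0.6 m wide | plastic film along each planting row |
| stake height | 2.0 m | support stakes standing above the canopy |

Plants are paraboloid domes `h(r) = H(1 − (r/R)²)⁺` (closed-form volume;
a Gaussian-dome option exists, whose truth volume comes from integrating
the stored noiseless field). Weeds are flat discs placed by a Poisson
process. Stakes are thin tall rectangles crossing the plant's flank; the
DSM carries the full stake spike, while the orthomosaic keeps the canopy
color where the stake crosses vegetation — thin stakes are under-resolved
in a real mosaic — which is precisely the combination that lets the
artifact corrupt height percentiles downstream. The DSM adds Gaussian
noise to the noiseless surface; the ground reference is an independently
noised flat plane. Every scene stores its noiseless height fields and
per-plot truth (plant mask, apex, 99th-percentile height, Riemann-sum
volume, stake flag), and everything is a deterministic function of one
seed.

What the generator deliberately does not emulate: shadows and BRDF
effects, perspective and stitching artifacts, plant-architecture texture
(leaves, stems), wind-induced reconstruction blur, and weeds at canopy
height. Passing tests therefore demonstrate the pipeline's correctness
under its stated assumptions — plants clearly taller than weeds, modest
elevation noise — not robustness to every failure mode of real
photogrammetry. The outline-set generator produces group-specific
two-bump templates (bump separation = the group's form offset) under
random slides, flips and support-restricted noise, so group differences
exist only in form, matching what the form dissimilarity is supposed to
detect.

## Numerical choices and degenerate inputs

Percentiles interpolate linearly between order statistics everywhere.
Otsu/triangle thresholds use 64 histogram bins; near-constant height tiles
fall back to the floor alone. Component-selection ties break by area then
label index, making segmentation fully deterministic; the only randomness
in the pipeline is classifier training, controlled by one seed. Fishnet
windows are computed with a 1e-9 pixel tolerance so metre-aligned plots
yield exact pixel counts (1 m at 4 mm → 250 px). Degenerate inputs raise
typed errors (`InvalidInputError`, `EmptyTileError`, `EmptyMaskError`,
`InvalidMatrixError`, ...) except where batch robustness argues for a
warning-and-continue contract (empty combined mask, empty outline, empty
volume).

## Problem sizes used in the validation suite

The test and acceptance runs use 1×2- to 2×3-plot scenes at the default
4 mm GSD (250 000–750 000 pixels per scene), 20 scenes for segmentation
efficacy, 52 plants for height-error estimation, outline checks at
L = 50–300 with brute-force oracles, and 1 000 null replicates × 999
permutations for PERMANOVA calibration; the end-to-end CLI determinism
check runs the full default outline geometry (L = 433, ±108 slides).
These sizes were chosen to exercise every code path at full default
resolution while keeping the whole suite in the tens of seconds.
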