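# Methods

`budprofiler` implements an unsupervised pipeline for profiling protein
expression in two-channel fluorescence micrographs of budding yeast: a
constitutive red marker (RFP) outlines every cell and drives cell
identification; the green channel (GFP) carries the tagged protein whose
spatial pattern is being profiled. This note records the models, the
numerical choices, and the places where the design was genuinely open.

## Image model and background correction

Images are 12-bit grids (stored in 16-bit containers, saturation clipped).
Camera background varies across the field, so a background image is
subtracted from every frame, flooring at zero. With a large collection the
pixel-wise **mean** over all images is an unbiased background estimate,
because cells occupy any given pixel in a negligible fraction of frames.
At small collection sizes the mean still carries an appreciable share of
cell signal; `compute_background_image` therefore also offers a pixel-wise
**median** (used by the pipeline driver for stacks of five or more images)
and a global scalar fallback below that. Defective CCD pixels are flagged
as those with exactly zero variance across the stack — they report the
same value in every image.

## Foreground segmentation (pseudo-2-D HMM)

RFP levels are modelled by two Normal emission distributions (background,
foreground) tied together by a two-state Markov chain along pixel rows;
this smooths over punctate noise that would break a per-pixel threshold.
EM is run twice — rows as independent chains, then columns — and the
per-pixel foreground posterior is the average of the two. No further 2-D
coupling is applied. Initialisation: emissions from a median split,
transition matrix with 0.95 self-transition; EM stops at a relative
log-likelihood change of 1e-6 or 200 iterations (non-convergence yields a
warning, not an error). The foreground state is, by convention, the one
with the larger mean. The EM itself is delegated to `hmmlearn`'s
`GaussianHMM`; initialisation, the row/column average and the state
convention live here. A constant image raises `DegenerateImageError`.

## Expected edge-distance map

Many later quantities need "distance to the cell edge": contour
extraction, a shape-quality measure, and the distance-to-periphery
feature. Because segmentation is probabilistic, the map is the *expected*
path length to background under moves with geometric costs 1 (axial),
sqrt 2 (diagonal) and sqrt 5 (knight), satisfying

    d(x) = min over moves y->x of  s + (1 - b(y, s)) d(y),

where `b(y, s) = 1 - (1 - q(y)) (1 - p_s)` is the probability that the
walk is absorbed at y: either y is background according to its posterior
`q(y)`, or the hidden state chain switched to background over the step —
`p_s = (T^s)[fg, bg]` with the 2x2 transition matrix raised to the
(fractional) step length via its eigendecomposition (a negative second
eigenvalue has no real fractional power and is clamped to zero).
Pixels with `q >= 0.5` are background-certain and carry 0; image borders
are treated as certain background (cells touching the frame are
low-confidence anyway). In the deterministic limit (posteriors in {0, 1},
transitions the identity) the map reduces *exactly* to the shortest-path
distance, which is how it is tested against a Dijkstra oracle. The map is
monotone: raising any pixel's background probability can only shorten
expected paths. Implementation is a label-correcting heap sweep.

A useful side effect of the absorption form: dim valleys *inside* a clump
(intermediate `q`) shorten expected distances around them, so
clump-internal structure surfaces in the contour band even when no valley
pixel is classified background outright.

## Robust multi-ellipse regression

Cells appear singly or in clumps. The number of cells in a clump is found
by fitting ellipses to the clump's contour pixels — foreground pixels
within 5 px of background (5 px is both the contour thickness and the
expected error scale).

**Parameterisation.** An ellipse is the zero set of the algebraic error
`e(p) = (p-c)^T A (p-c) - r^2` with
`A = R(theta) diag(exp(-g), exp(g)) R(theta)^T`,
`g = -log(ratio_min) eps^2 / (1 + eps^2)`. Since `det A = 1`, `r` is the
geometric-mean radius; `eps = 0` reduces to the circle form
`|p-c|^2 - r^2`; and the minor/major axis ratio `exp(-g)` is bounded below
by `ratio_min` for *every* parameter value, excluding hyperbolae and
degenerate conics by construction. The library default is
`ratio_min = 0.5`; the pipeline driver uses 0.7, since yeast cells are
nearly round and the tighter bound prevents one elongated ellipse from
bridging two adjacent cells.

**Loss.** The algebraic error is divided by `2r` to put residuals on the
geometric pixel scale (near the boundary `|p-c|^2 - r^2 ~ 2 r d`). The
objective is Tukey's biweight with scale sigma = 5 px. A redescending loss
is essential here, not a refinement: with a loss that keeps growing (e.g.
Cauchy), an ellipse sloppily enclosing two tangent circles scores better
than either circle, because the saved outlier cost outweighs the lost
inlier precision; with the biweight, pixels beyond the scale contribute a
constant and the precise single-circle fit wins. This is what makes the
iterative harvest recover two tangent circles instead of their average.

**Search.** Candidates (about 10 per expected ellipse, expected count =
contour pixels / (2 pi 15 px 5 px)) are seeded by the circumcircle of 3
contour pixels — an anchor pixel drawn uniformly plus two companions
within a random local radius, so small buds seed candidates even inside
large clumps. Seeds failing the clamping-rectangle or background-centre
checks are discarded; survivors get eccentricity 0.95 (axis ratio) and a
uniform random angle, then are refined by damped Gauss–Newton on the five
parameters (analytic Jacobian; every step must not increase the true
robust objective, enforced by Levenberg damping with backtracking — the
per-iteration monotonicity is tested). The best candidate consumes the
contour pixels within sigma/2 = 2.5 px of its boundary (the removal
threshold `|algebraic error| < sigma r` expressed in geometric pixels);
an ellipse narrower than 3 px, or consuming under 10% of the pixels its
perimeter predicts, is rejected (its pixels are still consumed). The loop
repeats until no pixels can be removed, fewer than 15 remain, or 30
rounds have run.

**Band-bias correction.** Contour pixels lie in a band 5 px deep *inside*
the cell, so the fitted midline underestimates the boundary by about half
the thickness; accepted ellipses are inflated by sigma/2 on both axes.
On a noiseless rasterised circle of radius 15 the recovered radius is
then within 5%.

## Shapes, watershed and typing

Cells are not exactly elliptical, so final cell areas ("shapes") are
assembled from steepest-ascent watershed basins of the RFP intensity:
every foreground pixel climbs to its strictly-brightest 8-neighbour (fixed
neighbour order breaks exact ties; adjacent equal-valued maxima are merged
as plateaus), and each basin is assigned to the ellipse with the smallest
|algebraic error| at the basin's brightest pixel. A shape is the union of
its ellipse's basins — by construction, boundaries between shapes fall on
dim pixels, and no pixel belongs to two shapes.

Typing uses the reciprocal size-extremum rule. Two shapes are adjacent if
they share at least one 8-connected cross-boundary pixel pair. (M, B) is a
mother-bud pair iff B is M's smallest neighbour, M is B's largest
neighbour, and B has no smaller neighbour of its own; everything else is a
lone cell. Size ties break by smaller ellipse-fit residual then lower
shape id (flagged). Adjacent *independent* cells that satisfy the rule are
deliberately kept as pairs — recently divided G1 cells very likely were a
pair — so the rule is not expected to match generative truth for
lone-lone contacts, and the typing-accuracy test excludes them. The bud
neck is the set of pixels of either shape with an 8-neighbour in the
partner; its mean coordinate is the neck landmark. The rule as stated
yields at most one bud per mother.

## Cell confidence

Four quality measures per object, from the closed-form moment fit
(centroid = centre of mass; semi-axes = twice the square roots of the
second-central-moment eigenvalues; density D = pixel count / fitted
ellipse area):

- `q_density = log(1 - D)`; discrete shapes have D < 1 except the tiniest
  objects, and D >= 1 routes directly to the artifact class;
- `q_perimeter = log(perimeter pixel count / Ramanujan perimeter)`, where
  perimeter pixels have >= 3 non-shape pixels among their 8 neighbours and
  the Ramanujan first approximation is
  `pi [3(a+b) - sqrt((3a+b)(a+3b))]` (exact for circles, ~0.4% high at
  axis ratio 2; the >= 3-of-8 counting rule runs ~0.64x the true perimeter
  on ideal disks — a constant offset the learned bin means absorb);
- `q_circular = log CV of (centroid distance + edge distance)` over shape
  pixels — both sum to the radius exactly on a circle, so the CV is
  floored at 1e-3 before the log;
- mean RFP intensity.

Obvious artifacts are pre-filtered by area < 50 px, fitted minor semi-axis
< 3 px, or D >= 1 (configurable; the original thresholds are not public).
Remaining objects are modelled as a two-component mixture: a cell
component — per-measure Normals in 7 cell-size bins (anchors at equal
quantiles of training sizes; empty bins borrow their nearest neighbour,
flagged), with the quality vector between anchors treated as the linear
interpolation of the two bin variables (mean linear, variance
`(1-t)^2 s_k^2 + t^2 s_{k+1}^2`) — against a uniform alternative spanning
the extremes of the full object collection. Per-measure sds are floored at
1e-3 of the measure's range. The mixing weight rho is fitted by soft-EM
(update: rho <- mean posterior; tolerance 1e-6), all other parameters
fixed. The posterior under this mixture is the cell probability; pair
confidence is the product of the two members' probabilities, and a paired
cell is partially lone with weight `p_cell (1 - p_partner)`.

## Expression features

Six interpretable measurements per cell. The intensity ratio is total GFP
over the RFP total *expected* for the cell's size: the expectation m(N) is
a continuous 3-segment piecewise-linear fit of mean RFP versus cell area
(hinge basis `1, x, (x-b1)+, (x-b2)+`; knots scanned over quantile pairs
and refined by Nelder–Mead), and the reported quantity reduces
algebraically to `sum(GFP) / (N m(N))`. A zero RFP total still raises — it
is the signature of a ruptured cell.

For the five morphological distances, each channel's (clipped-nonnegative)
intensity is normalised into a probability distribution over the cell's
pixels and the expected Euclidean distance to a landmark is computed: the
cell centre (unweighted pixel mean), the channel's own mass centre, the
periphery (via the edge-distance map), the bud neck (mother-bud pairs
only; recorded missing for lone cells), and another protein molecule (the
exact O(N^2) pairwise double sum, chunked for memory above 4000 px). The
feature is the log ratio of the GFP expectation to the RFP expectation of
the same functional — for the between-proteins feature the denominator is
the GFP-RFP *cross* expectation (protein to marker). All five are zero
when GFP and RFP distribute identically and are invariant to scaling
either channel; expectations are floored at half a pixel so a point mass
sitting exactly on a landmark keeps the log finite. Coordinates are
0-based (row, col) pixel centres, no sub-pixel interpolation.

## In-silico synchronization and time profiles

Bud area is the cell-stage clock. Assuming bud volume grows at a constant
rate, time scales with `area^(3/2)` (configurable exponent). For each
protein, the mean and variance of each of the 12 feature streams (6 bud +
6 mother) are estimated at 10 equidistant stage keypoints by local
regression: weights are the pair confidence times a Gaussian kernel of the
stage distance (default bandwidth 1700 stage units — the published value,
exposed in configuration because its scale depends on the stage
transform), and the variance is the plug-in kernel-weighted variance about
the kernel-weighted mean. Keypoints span the 1st-99th percentile of the
observed stage values, shared across proteins within a run so profiles are
comparable. The 120-value profile is laid out side -> feature -> keypoint
(bud block first). Keypoints with kernel mass below 1e-8 are flagged
unreliable (NaN).

Leave-one-pair-out jackknifing quantifies sampling variability as a
fraction of the total cell-to-cell variance at each keypoint (computed by
subtracting each pair's contribution from precomputed sums, verified
against full re-computation). The stage-permutation test shuffles the
stage covariates across pairs — features and confidences stay attached to
their pair — recomputes keypoint means, and reports two-sided add-one
empirical p-values ((b+1)/(n_perm+1), 2.5% per tail; a one-sided option
exists, and an exact mode enumerates all orderings for small n). Under the
null, 5% of keypoints are expected in the tails: 3 of 60, 1 of 20.

## Maximum-likelihood agglomerative clustering

A protein profile is a diagonal Gaussian (LOESS means and variances;
unreliable entries imputed feature-block-wise with the block mean and a
10x inflated variance before clustering; variances floored at 1e-6).
Merging is moment-matched: pooled mean, and per-dimension pooled variance
including the between-means term, so a fold of merges equals the one-shot
moments of the pooled membership. The merge score is the plug-in
log-likelihood ratio of the two-Gaussian versus the merged model; the
data-dependent constants cancel, leaving

    (n/2) sum log s_m^2 - (n1/2) sum log s_1^2 - (n2/2) sum log s_2^2

which is non-negative and zero only for identical components. Greedy
minimum-score merging (ties: lowest node-index pair) proceeds to a single
root; no cluster count is chosen in advance. Covariances stay diagonal
throughout — the initial matrices are diagonal, determinants factorise,
and a full covariance would be unidentifiable for singleton clusters.
Euclidean and correlation metrics with complete linkage are available
behind the same interface for robustness checks (delegated to scipy).
Dendrograms are written as TreeView-compatible CDT + GTR files (display
order: larger child first).

Class profiles merge all proteins sharing an *exact* localization label
set ("nucleus" and "nucleus AND cytoplasm" are distinct classes). Classes
are compared by the Gaussian Bhattacharyya distance
(`(1/8) dmu^T S^-1 dmu + (1/2) log det S / sqrt(det S1 det S2)`, S the
averaged covariance), which does not depend on member counts. The
related-group test compares mean within-group to mean out-of-group class
distances, with a permutation null that reassigns classes to groups
(sizes preserved; singleton groups contribute no within-distance).

## Enrichment over the hierarchy

For every annotation term covering >= 2 clustered proteins, every internal
node (size >= 2) of the dendrogram is scored by the upper-tail
hypergeometric probability of its overlap with the term, computed in log
space from log-gamma pmf terms and logsumexp; the universe is the
clustered proteins. All values are reported in log10; Bonferroni adds
log10(m) (3.30 for 1990 hypotheses, 2.44 for 277). S is the sum over
terms of the best (most negative) log10 P. Significance comes from
topology-preserving permutations: the tree is fixed and proteins are
reassigned to leaves, either freely or only within groups with identical
localization label sets — the constrained null asks whether functional
enrichment exceeds what localization alone explains, and by construction
its S distribution sits closer to the observed S whenever terms correlate
with localization. Both the Z score and the add-one empirical p are
reported, since the null need not be normal. Fully constrained nulls
(all-singleton groups) are degenerate: sd 0, Z = NaN.

## Synthetic scenes: what they emulate, and what they do not

The generator renders ellipsoidal cells (area 250-700 px, axis ratio
0.75-1) with per-cell RFP levels (uniform 500-1200 on a 12-bit scale over
background N(100, 20)), mild radial roll-off, optional vacuole dimming
(probability 0.3, depth 0.4), clumped placement (fraction 0.5), and
mother-attached buds (fraction 0.4 of cells; areas stratified over 30-260
px so the stage axis is fully covered). Inter-cell boundaries are dimmed
by a factor 0.3 over a ~3 px band — dim but above background, matching
the premise that no global threshold separates cells — and the scene is
smoothed with a sigma = 1 px Gaussian (FWHM about 2.4 px) before noise, so
watershed valleys behave as in real images. GFP patterns per simulated
protein: uniform, nuclear disc, peripheral ring, bud-neck spot, punctate,
or stage-switching (pattern changes at a bud-area threshold). Artifacts:
corner blobs, ruptured rings, dim discs, stuck-at-max pixels; all masks,
ellipse parameters, pairings and pattern labels are returned as ground
truth, and identical config + seed reproduces the scene bit for bit.

Not emulated: optical PSF and depth effects, autofluorescence spectra,
uneven illumination fields, cell-wall texture, 3-D stacks, or realistic
artifact frequencies (the artifact taxonomy is qualitative). Passing
tests on these scenes demonstrates the correctness and calibration of the
algorithms under controlled conditions, not performance on real
micrographs. One knock-on effect is documented in the tests: simulated
buds are clean circles, so the empirical "small buds score lower
confidence" pattern seen in real data does not arise here; the mechanism
(wider small-size bins giving lower posteriors) is verified directly
instead.

Detection evaluation matches ground-truth cells to detected objects
greedily by increasing centre distance, one-to-one, within a 10 px radius
(the matching discipline is a choice; the radius is the published
protocol), and reports recall, mean matched-centre distance, the Pearson
correlation of matched areas, the unmatched-detection rate, and how many
unmatched detections sit on artifact pixels.

## Problem sizes

Defaults are chosen so a full test-suite run and the acceptance script
each complete in minutes on one core: scenes are 192x192 px with ~12-18
cells (the source imagery is 1331x1017 with ~80 cells; all algorithms are
linear or near-linear in pixels, so the reduction is a uniform
scale-down), pipeline demonstrations use a few images per protein,
permutation tests use 150-200 permutations except where exactness is
tested by enumeration, and calibration uses 1000 null profiles.

## Known limitations

- Recall on synthetic clumps is ~0.75-0.9 depending on seed, with small
  buds the dominant misses — a bud much smaller than the 5 px contour
  thickness leaves little contour arc to fit. The source method reports
  the same qualitative weakness (low confidence for small buds).
- The piecewise-linear RFP size model assumes exactly two interior knots;
  data with more structure will be under-fitted (by design, for
  interpretability).
- The ML merge criterion uses plug-in (maximum-likelihood) variances; for
  singleton clusters the LOESS variances stand in, which is what makes
  n = 1 merges well-defined but mixes two variance notions.
- `estimate_mixing` updates only rho; if the component models are badly
  mis-specified the fixed point can sit at a boundary.
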