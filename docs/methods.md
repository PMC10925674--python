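# Methods

This note records the model behind `ihcquant`, the parameter choices that
matter, the numerical conventions that make results reproducible
bit-for-bit, and what the synthetic fixtures do and do not demonstrate.

## Scope and data model

The package analyses one RGB microscopy image at a time (8-bit/channel
TIFF or PNG; the motivating acquisition setup produces 4080×3072 frames at
20X). All user decisions about an image live in an *overlay*: the analysis
region (a simple polygon), the optional basal point, the spatial
calibration (µm/px), the nucleus diameter range, and the list of cells
with their staining categories (HIGH / LOW / NONE). Overlays persist as
versioned XML; quantification results as CSV. Coordinates are 0-based,
origin top-left, pixel centers at integer coordinates; polygons are open
vertex lists closed implicitly.

## Region-based detection (RDA)

Assumption: DAB-positive nuclei are simultaneously darker (lower L*) and
less yellow (lower b*) than their surroundings, so the product L·b ranks
pixels by staining intensity with the strongest stain at the minimum.
Counterstained (hematoxylin-only) nuclei also depress the product via b*.
The stages are:

1. **Lab encoding.** sRGB → CIELAB under D65. 8-bit encoding: L* scaled
   from [0,100] to [0,255]; a*, b* offset by +128 and clipped. The offset
   keeps all channels non-negative, without which the L·b product would be
   meaningless.
2. **Grey image.** G = 255·(L·b − min)/(max − min), rounded. A
   constant-product image maps to all zeros rather than dividing by zero;
   min–max (not max-only) normalization was chosen so the full 8-bit range
   is always used.
3. **Four-class Otsu.** The triple (t₁ < t₂ < t₃) maximizing the
   between-class variance of the four classes [0,t₁), [t₁,t₂), [t₂,t₃),
   [t₃,255] over the 256-bin histogram, by exhaustive (vectorized) scan of
   all ~2.7M triples. Exact ties resolve to the lexicographically smallest
   triple, so the result is deterministic. Histograms with fewer than four
   distinct values are degenerate; a blank image therefore short-circuits
   to "no cells" instead of erroring. (The tests check the scan against an
   independent oracle that minimizes within-class variance.)
4. **Binarization.** White where G < t₁ (strict, per the stain-darkest
   convention).
5. **Seeded k-means (k = 4).** Batch k-means on (L, a, b) vectors with
   deterministic seeds: c₀ = mean Lab of mask-black pixels, c₁ = mean of
   mask-white pixels, c₂/c₃ their 1/3 and 2/3 interpolants (only the two
   extremes are physically pinned; interpolants are the natural choice for
   the intermediate staining levels). Empty clusters keep their centroid;
   convergence when the largest centroid shift drops below 1.0 Lab units,
   at most 20 iterations. No RNG anywhere. After convergence, labels are
   re-anchored by proximity to the initial seeds (1 = nearest the white
   seed, 0 = nearest the black seed, 2 = the remaining centroid nearer
   cluster 1, 3 = the last), because raw k-means label identity is not
   stable under updates.
6. **Channel masks.** HIGH = cluster 1 as-is; LOW/WS = clusters 2/3 with a
   3×3 morphological closing to remove small holes.
7. **Splitting touching nuclei (HIGH only).** Exact Euclidean distance
   transform, normalized to [0,255]; thresholded strictly above the
   highest Otsu threshold of the *nonzero* distance histogram (background
   zeros would swamp the class statistics on sparse masks). If that
   histogram has fewer than four distinct values the mask is returned
   unchanged — there is nothing to split. The output is always a subset of
   the input mask.
8. **Cell extraction.** Holes are filled (outer-border semantics), regions
   are 8-connected, the diameter is the rotation-invariant
   equivalent-circle diameter d = 2√(A/π), and the gate is strict on both
   sides: d_min < d < d_max. The cell is the region's area centroid.

**Consequence of step 7 worth knowing:** the distance-threshold split
erodes every blob toward its core, typically to 30–60% of the original
diameter (the highest Otsu threshold of a cone-shaped distance histogram
sits around 60% of the peak depth). When running the HIGH channel on
well-separated nuclei, the diameter gate must therefore admit cores, not
whole nuclei; the tests use a core gate of (2 px, 1.5·d_max) for
HIGH-channel-only runs. In the merged pipeline this rarely matters: the
LOW/WS/EDA channels detect the same nuclei at full size and merging keeps
one point per nucleus.

## Edge-based detection (EDA)

Canny on the L plane with Gaussian width σ = 4 (matched to nucleus scale
at 20X). The hysteresis thresholds are 0.3 and 0.7 of the maximum
smoothed-gradient magnitude. A quantile mode (rates as empirical quantiles
of the nonzero magnitudes) is available behind `EdaParams.threshold_mode`,
but it is not the default: on sparsely populated images most of the
gradient mass is sensor noise and the 0.7 quantile falls into the noise
floor, producing thousands of false contours. Both modes are covariant
under affine intensity changes.

Two guards make the detector sane at the extremes: a constant image has no
nonzero gradients and returns no edges; and when the maximum gradient is
less than 8× the median nonzero magnitude the image is declared
featureless (the max/median ratio of a pure smoothed-noise field is ~4–5
by extreme-value statistics, while any real stained edge pushes it beyond
~20), so noise-only images also return no edges.

Closed contours are converted to cells by 3×3 closing, flood-fill hole
filling, and discarding any component that did not enclose an interior —
an open arc detects nothing. Nested contours yield the outer region only.

## Merging and region clipping

Channels accumulate in the fixed precedence order RDA-HIGH ▸ RDA-LOW ▸
RDA-WS ▸ EDA (stain-specific channels are more informative than the
generic edge channel). A candidate is kept iff its distance to every
already-kept cell exceeds d_min (strict). Greedy suppression is not a
maximum independent set, but it is deterministic, order-faithful and
O(n·k); it is idempotent and guarantees all pairwise output distances
> d_min. The same rule applies within and across channels. Containment in
the analysis polygon is boundary-inclusive — a user-drawn outline should
not silently drop cells it touches.

## Stain classification

Features are deliberately minimal: the mean L, a, b over a square window
of side max(3, round(d_min)) centered on the cell (clipped at image
borders). Classifier: RBF-kernel SVM. Features are standardized by the
training mean/sd before the kernel — without this the fixed σ grid would
be scale-sensitive. λ (the SVM regularization weight, mapped to the usual
C parameter) ranges over {2^(2i−7)}, i = 1…10, i.e. 2⁻⁵…2¹³; the kernel
spread σ over {2^(−(i+1)/2)}, i = −15…0, i.e. 2⁷…2^(−0.5), with
K(x,y) = exp(−‖x−y‖²/2σ²). Model selection: stratified, seeded 4-fold
cross-validation scored by mean Cohen κ; ties prefer smaller λ then
smaller σ (the less complex model); the winner is refit on the whole
training set.

Training sets are capped at 1000 cells with a minimum of 10 per included
class. Each included class receives an equal quota of the cap; classes too
small to fill their quota contribute everything and the shortfall is
redistributed equally among the others (remainders to earlier classes, in
HIGH/LOW/NONE order); within-class sampling is uniform without
replacement, seeded.

Cohen κ is implemented as the standard chance-corrected agreement in
percent, κ = 100·(p_o − p_e)/(1 − p_e), with κ ≡ 0 when p_e = 1. Applied
to the published three-level confusion matrix (percent cells as weights),
this reproduces the reported accuracy 79.8% exactly and κ within rounding
(60.21 recomputed vs 60.23 reported from unrounded counts).

## Strata geometry

The construction assumes the region is a band-like epithelium section: it
computes the minimum-area *rotated* enclosing rectangle (rotating
calipers; corners ordered counterclockwise from the corner nearest the
first region vertex), picks the rectangle side nearest the user's basal
point as the basal side (ties → lowest side index), and sweeps N_L lines
perpendicular to the basal side across the region (at side-fractions
(i−½)/N_L, which avoids degenerate corner intersections). Each line must
cross the contour exactly twice; the chord is divided at 1/3 and 2/3 of
its Euclidean length from the basal end. The two polylines of division
points, extended beyond the region, split the polygon into the basal,
medial and superior layers; each split piece is assigned to the basal or
apical side by the local position of its representative point relative to
the cutting polyline.

Sweep lines crossing the contour in other than two points (folds,
re-entrant outlines) are skipped; if more than 20% are skipped the region
is not a simple epithelium band and an explicit error asks the user to
redraw — guessing a layering for a folded ROI would silently corrupt the
per-layer counts. N_L defaults to 100: on all test fixtures this keeps the
partition within 2% of exact equal-thirds areas while the layer polygons
stay small; the partition always tiles the region exactly (the layers are
a split of the polygon), so only the *placement* of the third-lines
depends on N_L.

Layer assignment is boundary-inclusive with basal-most priority on ties; a
cell falling in a numeric sliver between layers is assigned to the nearest
layer and counted in a warning counter.

## Quantification and evaluation

Positivity defaults to HIGH+LOW (any DAB staining), configurable to HIGH
only, matching the binarized convention used for ki67 scoring. Counts and
percentages are reported globally and, when a basal point is present, per
layer; per-layer counts always sum to the global row.

Detection is evaluated against ground truth by greedy one-to-one matching
in increasing distance order within a radius (default d_min). The three
reported measures are Se = 100·TP/(TP+FN), Sp = 100·TP/(TP+FP) and
AP = 100·TP/(TP+FP+FN). Note that "Sp" here is mathematically the positive
predictive value (precision) and AP the Jaccard index of the detection
sets; the names follow the established detection-scoring convention of
this workflow. Ratios with zero denominators are reported as missing,
never coerced to 0 or 100.

## Synthetic scenes

The generator renders filled ellipses (axis ratio 0.8–1.0, random
orientation — deliberately off the symmetric case so centroid and diameter
code is exercised) with per-pixel Gaussian color noise (sd 8) on a pale
background, at three class colors: dark brown (90,60,30), light brown
(170,130,90), blue-purple counterstain (150,150,200), background
(235,230,238). The palette satisfies the L·b ordering the RDA relies on
(strong stain darkest product, background highest) — verified by an
explicit test, since the method presumes it. Default scene: 512×512, 10
nuclei per class, equivalent diameters within (14, 26) px, centers at
least 1.2·d_max apart, all placement by seeded rejection sampling (bounded
attempts; overcrowded requests raise a capacity error). A band variant
places nuclei in known thirds of a rotated rectangular region (2 px margin
off the third boundaries) with a basal point beyond the basal long side,
giving ground-truth layer labels.

What passing on these scenes shows: the pipeline's stages compose
correctly, the geometry is exact, and the classifier recovers
well-separated class colors. What it does not show: performance on real
tissue, where nuclei overlap and vary in texture, background staining
mimics weak DAB, and epithelium boundaries are irregular — there the
detector is known to be imperfect and the expert-review file formats are
the mitigation, with detection sensitivity in routine use far below the
synthetic figures.

## Numerical conventions and edge cases

- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); detection itself is fully deterministic.
- Otsu tie-break lexicographic; grid-search tie-break smaller λ then σ;
  merge precedence fixed; k-means label anchoring by seed proximity —
  every tie in the pipeline has a documented deterministic resolution.
- Strict inequalities: binarization (< t₁), distance threshold (> t₃),
  diameter gate (both sides), duplicate suppression (> d_min).
- Degenerate inputs: blank/constant images detect nothing; noise-only
  images detect nothing (EDA SNR guard); collinear regions and folded ROIs
  raise; overlays validate cell-in-region and basal-point-outside on both
  read and write; coordinates are serialized with full float precision so
  write∘read is the identity.

## Problem sizes used in the test suite

Unit and acceptance tests run on 512×512 scenes with 20–30 nuclei,
training sets of 30–180 cells over the full 160-point hyper-parameter
grid, 20 random 64×64 images for the Otsu oracle, 50 random polygons for
the rectangle oracle, and 1000 random count triples for the metric
oracle. These sizes were chosen as the smallest at which every behavior
of interest (joined-nucleus splitting, layer misassignment near
boundaries, quota redistribution) is actually exercised.
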