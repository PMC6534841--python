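# Methods

`woundkit` analyzes color photographs of sutured post-surgical wounds in two
stages: (1) segment the wound area out of a cluttered photograph using edge
and skin-color information, and (2) locate the suture sites inside the wound
and classify each one as Normal or as showing Swelling, Granulation,
Infection or Tissue Necrosis. This note documents the model behind each
stage, the parameters that matter, the synthetic data the tests run on, and
the design decisions taken where the procedure was genuinely open.

## 1. Robust segmentation

### Edge detection and enforcement

Edges come from a standard Canny detector (Gaussian σ = 1.4, hysteresis with
the low threshold fixed at 0.4× the high threshold; thresholds are quoted on
the 0–255 gray scale throughout). Canny output on skin is fragmented, so an
*edge-enforcement* pass walks every open endpoint of the edge map and extends
it pixel by pixel. At each step the endpoint's 3×3 neighborhood is examined:
a background neighbor is a valid extension candidate when switching it on
splits the remaining background of the window into exactly two 4-connected
parts, and the chosen candidate maximizes the absolute difference of the two
parts' mean gray levels (ties break to the smallest row, then column). The
chain stops when

* the best candidate's split contrast falls below `stop_threshold`
  (default 10 gray levels — the neighborhood has become flat and the edge
  genuinely ends there),
* the new pixel acquires edge neighbors beyond its own chain predecessor
  (the gap has been mended into another edge), or
* a safety cap of `max_steps` (default 50) extensions is reached.

Endpoint sweeps repeat until no chain adds a pixel, so the operation is
idempotent: its output is a fixpoint and always a superset of its input.
An endpoint is an edge pixel with one edge neighbor, or with two edge
neighbors that are 4-adjacent to each other; the 4-adjacency requirement is
what distinguishes the thick tip of a diagonal chain from the corner of a
right-angle contour, which is not an endpoint.

### Skin-area demarcation

Connected-component labeling (8-connectivity) groups the enforced edges into
edge sets; each set induces a region, realized as the hole-filled
morphological closing (disk radius `close_radius = 5` px) of the set, always
containing its own edge pixels. Where regions nest — a wound contour inside
a skin contour — interior pixels belong to the innermost enclosing set
(regions are painted largest-first so smaller regions overwrite).

A region is *skin-colored* when its mean HSV (all channels scaled to [0,1],
hue = angle/360°) lies inside H ∈ [0.035, 0.7], S ∈ [0.005, 0.8],
V ∈ [0.35, 0.9], bounds inclusive. Because the hue lower bound is 0.035,
no wraparound handling is applied and reds near h ≈ 1 are non-skin. Among
the surviving regions, the one containing the most individually in-range
pixels is the reference region and its channel means are the image's
*optimum skin color*. Every surviving region is then kept iff all three
absolute channel differences from the optimum fall below (φ, ϕ, χ) =
(0.25, 0.25, 0.2) — a conjunctive rule; the union of kept regions is the
possible-skin mask. The *skin support* used downstream is that mask with
interior holes (the wound) filled and eroded by `support_erosion = 8` px: a
conservative interior margin that guarantees the support never leaks onto
the background even though the detected skin boundary is only accurate to
±1 px.

### Self-adaptive Canny threshold

Wrinkled skin floods the edge map with short, faint, near-parallel contours
that fragment the region structure. The high threshold is adapted in two
phases.

**Upward (candidate) search.** Starting from `init_threshold = 20`, raise
the threshold in steps of 5 while the contours each raise removes are
wrinkle-like, capped at 0.26·255 ≈ 66. A removed contour counts as
wrinkle-like when its chord line belongs to a similar-slope group of more
than ε = 20 lines within the full current contour set; lines are chords
between a contour's two endpoints (or its two farthest pixels for the thin
closed loops that Canny traces around a dark crease), and they group by the
transitive closure of "slopes within 10° and chord midpoints within 50 px".
Contour identity across thresholds is ≥50% pixel overlap.

**Downward (optimized) search.** A high threshold can strip away the
peri-wound skin needed for later analysis, so the search then descends from
the candidate value in steps of 5, bounded below by 0.06·255 ≈ 15.3. At
each step the *newly appearing* contours are inspected: if there are none
the threshold is settled; if all of them sit in similar-slope groups larger
than ε = 40 they are wrinkle clutter and the descent continues past them;
otherwise their mean RGB is compared with the mean RGB of non-edge pixels
inside the skin support, and the descent continues only while all three
channel distances stay below (38, 40, 40) — i.e. while lowering adds only
more skin-like edges. The first distinctly colored (wound) contour stops
the search without being included. Restricting the outside-color average to
the skin support matters: without it a dark drape background drags the
average off skin color and stops the descent immediately.

The edges detected and enforced at the optimized threshold, clipped to the
skin support's interior, form the wound edge set AE.

### Wound reconstruction

The filled envelope of AE (closing radius 5 + hole filling) is thinned to a
topological skeleton; a probabilistic Hough transform (ρ = 1 px, θ = 1°,
accumulator threshold 10, minimum length 10 px, gap 5 px, fixed sampling
seed) extracts its dominant straight segments. Segment endpoints are
chained greedily (always hop to the nearest unused endpoint, then close the
loop) into a polygon; the filled polygon united with the AE envelope is the
coverage-area base, dilated — if necessary — by exactly the disk radius
needed to contain every AE pixel. Uniting with the envelope keeps the
boundary geometry tight: dilating from the thin medial polygon alone
inflates the area far beyond the wound. The final wound mask is the
coverage area dilated by `margin = 15` px (the clinically relevant skin
ring around the wound) and clipped to the skin support; the wound image
zeroes every pixel outside the mask.

Agreement with a reference mask is reported as the boundary-based coverage
rate (N1 − CN)/N1 and exceed rate CP/N1, where N1 is the reference
foreground size, CN the missed reference pixels and CP the automatic pixels
outside the reference.

## 2. Suture-site detection and assessment

### Feature points

Suture stitches cross the incision perpendicularly and leave plus-shaped
marks. The masked wound image is binarized with Otsu's criterion. Because
that image can hold three gray populations (retained skin margin, wound
bed, dark suture threads), a single split may leave the entire wound bed in
the dark class; the dark class is therefore re-split with Otsu while it
still covers more than 25% of the mask (at most 3 splits), leaving only the
dark marks. A morphological opening (erosion then dilation) with the 5×5
cross structuring element — ones on the center row and column, nine ones in
total — retains only plus-shaped pixel groups, and each connected group
collapses to its centroid (rounded half-up): one feature point per stitch.

### Cluster-count selection

Feature points are clustered agglomeratively (Euclidean distance in pixels,
average linkage by default; single/complete/Ward available). The number of
suture sites is chosen from a cluster-score curve cut by Rosin's
unimodal-threshold rule: draw the chord from the curve's maximum to its last
point and pick the k whose point lies farthest (perpendicular distance)
from the chord, ties to the smaller k, and the first k when the curve is
numerically straight. The corner choice is invariant to positive rescaling
of either axis, since both rescalings multiply all chord distances by a
common factor.

Three score curves are implemented:

* **formula** — the piecewise score S = 1 − a/b (a < b), 0 (a = b),
  b/a − 1 (a > b) with a = n/k the mean element count per cluster and b = k,
  and iVar = 1/S where positive, for k in 2..⌊n/2⌋. This score is a
  function of n and k only — it carries no information about the point
  layout — so it is provided for reference but cannot select structure.
* **silhouette** — iVar = 1/S with the standard mean silhouette
  coefficient.
* **dispersion** (default) — Var(k), the mean within-cluster squared
  deviation of the k-cut, reported on a log scale and anchored at k = 1
  (the total variance). While genuine sites are still merged, each
  increment of k removes between-site variance and the curve drops steeply;
  once every site has its own cluster, further splits only shave
  within-site variance and the decay flattens. The Rosin corner of this
  decaying curve (restricted to k ≥ 2) is the selected site count. In
  seeded experiments with well-separated point groups this recovers the
  true count in ≥96% of trials, whereas the corner of the
  inverse-silhouette curve recovers it in under 20%.

Each cluster's axis-aligned bounding rectangle, expanded by `roi_pad = 10`
px and clipped to the image, is one suture-site ROI; cutting at k always
yields exactly k ROIs.

### Per-ROI classification

Every ROI is summarized by a 17-dimensional vector: mean and standard
deviation of H, S, V (on [0,1]) and of R, G, B (on 0–255); a redness index
mean(R − (G+B)/2)/255; the dark-pixel fraction (V < 0.2, targeting necrotic
tissue); the saturated-red fraction (hue within 0.05 of the red pole and
S > 0.5, targeting granulation/bleeding and infection); the Canny edge
density inside the ROI; and the absolute difference between the ROI's mean
hue and the image's optimum skin hue (targeting swelling's local hue
shift). One shared vector serves all classifiers; the per-symptom outputs
come from separate heads.

Features are standardized with training-set statistics and fed to support
vector machines with the polynomial kernel K(x, y) = (γ⟨x, y⟩ + r)^d,
d = 3, γ = 1/17, r = 1, C = 1, with inverse-frequency class weights.
Two heads are trained: a binary anomaly head (Normal vs. anything else) and
four one-vs-rest symptom heads. A ROI's label is the symptom head with the
largest positive decision value, else Normal. Image-level aggregation uses
the any-ROI rule: the image is Abnormal iff any ROI is non-Normal, and a
symptom is present iff any ROI carries it (four presence tests per image).
An image with no detected suture sites is reported Normal with an explicit
warning rather than silently.

## 3. Synthetic study conditions

The clinical photographs the method was designed for are not distributable,
so all quantitative checks run on rendered fixtures with exact ground
truth. The default wound fixture is a 384×384 frame: a dark blue-gray drape
(HSV 0.58/0.50/0.22, outside the skin value range), a skin ellipse
(semi-axes 172×156, HSV 0.07/0.35/0.75, inside the skin ranges), a dark-red
wound ellipse (semi-axes 100×78, HSV 0.97/0.65/0.45, outside the skin hue
range) at a seed-determined orientation, and three suture sites of three
plus-shaped stitches each (arm 5 px, thickness 3 px, 12 px stitch spacing,
38 px between sites) along the incision axis, plus Gaussian RGB noise
(σ = 2) and two optional camera presets (a mild brightness/white-balance
shift). A site can carry a symptom coloration: a dark patch (Necrosis), a
bright red blob (Granulation), a darker red halo with a pale center
(Infection) or a local hue/brightness shift (Swelling).

Two reduced fixtures isolate single stages: a *suture layout* (crosses on a
plain wound-toned canvas, for cluster-count recovery with 2–5 sites) and a
*palm image* (a wound-free skin patch crossed by ~30 parallel, non-crossing
creases whose depths vary 0.5–1.5× around a 0.10 value-channel dip, so
raising the edge threshold removes them gradually — the wrinkle-clutter
condition for the upward threshold search). Classifier tests use
class-conditional Gaussian feature tables whose class means sit a chosen
number of within-class standard deviations apart.

These fixtures reproduce the geometry and color logic the algorithms key on
but none of the texture, specular highlights, shadows, perspective or skin
tone diversity of clinical photographs. Passing tests therefore demonstrate
algorithmic correctness under the stated conditions, not clinical
performance.

## 4. Numerical choices and degenerate inputs

* Gray conversion uses the BT.601 luma weights rounded half-up, so neutral
  (v, v, v) pixels are fixed points. Black pixels take (h, s) = (0, 0).
* Component labels are assigned in row-major first-encounter order;
  ties anywhere (extension candidates, reference regions, Rosin corners)
  break deterministically to the smaller index.
* A constant image has no Otsu threshold: the result is an empty mask plus
  a warning. An empty manual mask makes the coverage metrics undefined and
  raises. An all-background image raises a no-skin error; a wound whose
  coverage area misses the skin support raises an empty-wound error.
* The probabilistic Hough transform samples pixels; its generator is seeded
  from the configuration so identical inputs give bit-identical masks.
* Test and acceptance problem sizes (384 px frames, 50 segmentation seeds,
  50 recovery trials per site count, 100 feature samples per class) were
  chosen so the full suite completes in well under half an hour on one CPU
  while keeping the proportions of the emulated study.

## 5. Known limitations

* The edge-mending walk is greedy and local; it cannot bridge gaps whose
  true contour curves sharply within the 3×3 window, and it inherits the
  ±1 px localization of the underlying Canny ridge.
* Region realization by morphological closing is a modeling choice for the
  under-specified notion of "the region formed by an edge set"; open
  contours produce slivers rather than areas.
* The wrinkle judgment assumes creases are longer than they are wide and
  roughly parallel in a neighborhood; curly or isotropic clutter is not
  recognized as wrinkles.
* The classifier heads are only as good as the 17 summary features; they
  ignore texture (energy/entropy/skew) and spatial context, and the
  shipped defaults are tuned for the synthetic class structure, not for
  clinical images.
* Color constancy is handled only through the per-image optimum skin color;
  no color-card calibration is performed.
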