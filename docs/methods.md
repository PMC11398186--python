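# Methods

This note records the models, numerical choices and known limitations of
`rhizocurl`. Inputs are binary segmentation masks of root tissue from a
buried imaging window (microrhizotron, ~1.1 cm), with a user-supplied
calibration (mm per pixel; the imaging hardware does not report one) and a
visible soil depth L.

## Skeletonization (module `skeletonize`)

Masks are thinned with the classic two-subiteration Zhang–Suen algorithm:
both subiterations decide all deletions on a snapshot of the image
(parallel formulation), repeated until a full pass deletes nothing.
Thinning is restricted to the foreground bounding box for speed; the
result is identical. Note that `skimage.morphology.skeletonize(method='zhang')`
is a sequential lookup-table variant and does **not** reproduce the classic
parallel formulation pixel-for-pixel, which is why the algorithm is
implemented here and cross-checked in the tests against an independent
per-pixel reference implementation.

*Spur pruning* removes thinning artifacts: from every free endpoint a walk
proceeds through unique-successor pixels; if it reaches a branching pixel
within `min_branch_px` steps (default 5 px, configurable) the walked
pixels are deleted. A base pixel that touches the main line diagonally is
deleted with its spur when the remaining neighbours stay connected without
it; a true main-line junction pixel is kept. Spurs of exactly
`min_branch_px` pixels are retained (strict `<`). One pass is applied —
enough for thinning artifacts without eroding real short hairs.

*Gap bridging* joins free endpoints of different connected components
within `max_gap_px` (default 10 px) whose local tangent lines — direction
of the 5 pixels adjacent to each endpoint, compared modulo 180° — differ
by at most `max_slope_diff_deg` (default 20°). Pairs are taken
nearest-first, each endpoint used once, and joined by a straight pixel
run. The defaults are operational choices exposed in the configuration;
the rule itself (nearest neighbour with similar slope) is the method's
contract. Restricting bridges to distinct components prevents a tightly
curled hair from being short-circuited into a loop.

## Axis identification and hair separation (module `hair_separation`)

Root axes are millimetre-scale, hairs tens of microns, so the axis is
identified by width: skeleton pixels whose local width (twice the
Euclidean distance transform of the mask) is at least `axis_min_width_px`
(default 5 px), largest connected component. The axis *region* is the set
of mask pixels whose nearest skeleton pixel is an axis pixel; its boundary
coordinates (raster-ordered) are the attachment sites for hairs. Without a
mask (skeleton-only input) the longest single chain serves as a fallback
axis.

Hair components — the non-axis skeleton — are attached at the free
endpoint nearest the axis, if within `max_gap_px`; the gap is filled with
a straight pixel run so every hair path starts adjacent to its attachment
coordinate. Components with no endpoint in range are dropped and counted.
Each qualifying endpoint seeds one traced hair, so a component touching
the axis at both ends yields two hairs (as two crossing hairs do).

Tracing is a two-pass search over the junction/chain graph of the hair
skeleton:

1. a provisional pass accepts at every junction the continuation with the
   smallest tangent-direction change, bounded by the lax end-zone
   threshold (80°), to estimate the hair's total arclength;
2. the final pass applies the positional rule — direction changes of at
   most 30° while the junction lies within the first half of the estimated
   arclength, at most 80° in the tip half, where genuine curling
   concentrates. If no continuation qualifies, the hair ends at the
   junction (roots grow continuously, with no sudden break point).

"Within ½" is read against the hair's own length (curling occurs at the
hair end, so the relevant scale is the hair, not the axis); the two-pass
scheme makes the rule well-defined although the total length is unknown
during the search. Tangents at junctions use 5-pixel windows, matching
the curling-angle convention. Ties between equal-angle branches take the
clockwise turn in image coordinates and are logged as ambiguous. Visited
chains are never re-entered, so cycles terminate. Junction clusters
(8-connected groups of branching pixels) are collapsed; small pixel gaps
they leave in an assembled path are filled with straight runs, keeping
paths 8-connected and duplicate-free. The whole search is deterministic:
attachments are processed in raster order.

Hairs shorter than 12 px are flagged too short for curl measurement (the
midpoint + 5 px forward and endpoint − 5 px backward windows must not
overlap).

## Curling angle (module `curl_metrics`)

The base definition uses four points of the path (ordered axis → tip):
Pᵢ the midpoint (lower median for even lengths), Pⱼ five path-pixels
after it, Pₗ the endpoint, Pₖ five before it, and

β = arccos( PᵢPⱼ·PₖPₗ / (|PᵢPⱼ| |PₖPₗ|) ).

An arccos cannot exceed 180°, while tight curls reach ~270°, so the
*reported* β is the cumulative turning from Pᵢ to Pₗ; the raw arccos value
is emitted alongside for transparency, and the two agree below 180°.

Numerically, single 5-px chords on rasterized curves carry up to
±atan(1/5) ≈ 11° of staircase error — too much for degree-level work —
so the cumulative estimator is computed as (tail tangent − head tangent),
with the winding (how many times the turn passes 180°) resolved by the
unwrapped sequence of 5-px-window tangent angles on a lightly smoothed
path (7-px moving average):

- *head tangent*: total-least-squares line over the first 18 px of
  arclength after Pᵢ. Curling concentrates at the tip, so this region is
  locally straight and a long baseline averages out shallow staircases.
- *tail tangent*: the chord over the last 30 px, whose direction equals
  the tangent at the chord's arclength midpoint for a constant-curvature
  curve, rotated out to the endpoint with a curvature estimate taken from
  the slope of the windowed tangent angles.

On constant-curvature test arcs this estimator is unbiased; across a
1600-case sweep of headings and turnings (0–300°) its worst error is
5.3° and its median 1.1°. It reduces to the raw arccos below 180° and
is invariant under rigid rotation and translation of the path. Hairs in
which curvature is significant already at the midpoint will bias the
head tangent; for the biology addressed here (curling at the hair end)
this does not arise.

A hair is classified *curled* when β strictly exceeds 90° (configurable):
uninfected hairs are wavy but stay below ~45°, so 90° separates induced
curling from baseline waviness. Group summaries report mean, sample SD
(n−1; NaN for a single hair), count and curled fraction.

## Nodule diameter (module `nodule_metrics`)

A nodule approximates a buried sphere. With visible depth L, a sphere of
diameter D sectioned at depth L shows the chord d = 2·√(L·(D−L)); the
conversion D = (4L² + d²)/(4L) inverts it. D(d) grows monotonically from
its minimum D = L at d = 0, and the conversion gap D − d vanishes exactly
at d = 2L. Observed diameters strictly above L are converted; smaller
nodules are still fully visible and reported as observed, flagged
unconverted. L defaults to 1 mm (micro-/minirhizotron scale) but is
configurable, since reported visible depths range to 2–3 mm.

Observed diameter is the maximal Feret extent of the region: the maximum
pairwise pixel-centre distance plus one pixel (a single pixel has extent
1, an n-pixel row extent n), computed on the convex hull. Nodules are
near-circular caps, and perceived widths are caliper widths; an
equivalent-area diameter is available as an option.

Nodule detection is deliberately heuristic and separated from
measurement: cores are foreground pixels whose local width exceeds
`swell_factor` (default 2.0) × the median axis width; each core adjacent
to the axis is grown back to the full cap (mask pixels within the core's
maximal inscribed radius of its deepest point). Measurement can therefore
be validated independently of detection.

## Dose–response (module `density_stats`)

Inoculant doses span 10⁵–10⁹ viable cells per jar across groups A–D, so
responses are regressed on the log₁₀ midpoint of each dose interval
(A→5.5 … D→8.5; a rank coding is available). The uninoculated control
carries no dose and is excluded from fits. Fits are ordinary least
squares (scipy's `linregress` behind the module surface) with
R² = 1 − SSres/SStot, which for a simple regression equals the squared
Pearson correlation; a constant response returns slope 0 with R² defined
as 0, and a constant covariate is an error. Count predictions are floored
at zero. Per-plant values (not group means) are the default unit of
analysis.

## Synthetic scenes (module `synthetic_scenes`)

The generator emulates the imaging geometry: a 1100×1100 px window at
0.01 mm/px (the ~1.1 cm field), one vertical axis bar (9 px default),
hairs as minimal 8-connected paths built from a straight run followed by
a constant-curvature arc — so the tangent direction, hence the total
turning, is exact at every arclength — and nodules as discs whose pixel
diameter is the rounded buried-sphere chord of their true diameter.
Rendering is deterministic per seed, and elements that would merge
ambiguously raise an error rather than render.

Two rasterization choices matter:

- hair paths are *minimal* 8-paths (staircase corner pixels dropped);
  redundant corners otherwise survive thinning as spurious branching
  pixels and fragment the traced geometry;
- test hairs place the turn start at 0.6 of the hair length. Diagonal
  steps make a curved half denser in arclength than in pixel count, so a
  turn starting exactly at the arclength midpoint would begin slightly
  before the path-pixel midpoint Pᵢ and the measurement would miss part
  of the turn by construction. 0.6 keeps Pᵢ in the straight region and is
  consistent with curling occurring at the hair end. (`SceneSpec`'s
  default `turn_start_fraction` remains 0.5.)

Hairs are rendered 1 px wide by default so thinning is near-identity and
separation/angle logic is isolated from thinning artifacts; a thick mode
(3 px) exercises the full stack. Hairs are also rendered longer in pixels
(hundreds) than a literal micron-scale conversion would give — the
equivalent of higher optical magnification — because degree-level angle
recovery needs tangent windows that a 40-px hair cannot support.

The four crossing patterns express the separation contracts: (a) a single
hair; (b) an X-crossing mid-hair, correct continuation collinear; (c) a
genuine sharp turn (45–70°) in the tip zone at a junction with a
distractor, which the 80° end-zone rule must follow; (d) a short hair
ending on another hair, whose moderate-angle (35–60°) false continuation
the 30° mid-hair rule must reject. Pattern-d scenes make the distractor's
tail longer than the short hair so the junction falls in the first half
of the provisional arclength estimate.

`render_group_experiment` draws per-plant responses from per-group
Gaussians and renders small per-plant scenes; the response table feeds
the regression end-to-end. It emulates the design of the dose experiment
(groups × plants), not real biological variance structure.

What passing these tests does *not* show: performance on real
segmentation masks with ragged boundaries, touching hair bundles,
segmentation holes, soil occlusion, or nodules that deviate from
sphericity. The generator's hairs have piecewise-constant curvature;
real deformation morphologies (waving, branching, swelling) beyond
curling are out of scope, as is the upstream segmentation itself.

## Defaults at a glance

| parameter | default | meaning |
|---|---|---|
| `mm_per_pixel` | user-supplied (0.01 in examples) | image calibration |
| `visible_depth_L` | 1.0 mm | soil depth the window perceives |
| `min_branch_px` | 5 px | spur-pruning length (strict `<`) |
| `max_gap_px` | 10 px | endpoint bridging / hair attachment range |
| `max_slope_diff_deg` | 20° | slope agreement for bridging |
| `angle_thresh_mid_deg` | 30° | junction rule, first half of hair |
| `angle_thresh_end_deg` | 80° | junction rule, tip half |
| `curl_threshold_deg` | 90° | curled-hair classification (strict `>`) |
| `axis_min_width_px` | 5 px | minimum width to qualify as axis |
| `swell_factor` | 2.0 | nodule core width ratio vs axis |

All of these live in `RunConfig`; none are hard-coded.
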