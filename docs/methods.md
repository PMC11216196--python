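# Methods

This note documents the models, numerical choices and limitations behind
`annoray`. It complements the README, which states the problem and shows a
worked run.

## Camera model and conventions

One set of conventions is used everywhere and is normative for the camera
JSON schema:

* Pixel origin `(0, 0)` at the **top-left** image corner, `u` right,
  `v` down; annotation coordinates are continuous with no half-pixel shift
  (BIIGLE exports continuous coordinates) and the principal point follows
  the same convention.
* Camera frame `+x` right, `+y` down, `+z` forward, with
  `x_c = R (X − C)` — the OpenCV/OpenMVG convention of the SfM exports the
  tool consumes.
* Distortion is radial-only Brown `(k1, k2, k3)` ("radial K3" in SfM
  intrinsics). Tangential coefficients in an input file are rejected with
  an error rather than silently ignored.

Annotations are made on full-resolution images while cameras are calibrated
at the (downscaled) reconstruction resolution, so pixels are first rescaled
by the width/height ratio; an aspect-ratio mismatch beyond 0.5 % aborts, as
it almost always means an annotation was paired with the wrong image.

**Undistortion.** The radial model is inverted by damped fixed-point
iteration starting from the distorted point, with tolerance `1e-13` on the
normalized-coordinate residual and a cap of 100 iterations. The damping
(step halving whenever the residual grows) extends convergence to strong
distortion; for `|k1| ≤ 0.2, |k2|, |k3| ≤ 0.05` the inversion is exact to
better than `1e-8` px across the whole image (property-tested). With
negative `k1` the radial map folds beyond a critical radius; a fixed point
on the folded branch has a non-positive radial factor and is rejected as
"not invertible at this pixel" rather than returned as a sign-flipped ray.

## Ray casting

The scene mesh is treated as a triangle soup: Poisson reconstructions are
not watertight, have inconsistent winding, and contain slivers. Hence:

* intersection uses Möller–Trumbore without backface culling;
* faces with area < `1e-12 m²` are flagged degenerate and never hit;
* a **miss is a value, not an error** — annotations whose ray misses are
  reported as `discarded`;
* the minimum hit distance `t_min = 1e-6 m` suppresses self-intersection
  at a ray origin lying on the surface.

The spatial index is an axis-aligned BVH built by median split on the
longest centroid axis (ties broken by face index, leaves ≤ 4 faces), making
the structure and the traversal fully deterministic for a given mesh. When
two hits lie within `1e-12 m` of each other along the ray, the lower
original face index wins. The traversal kernel is compiled with numba for
throughput (~10⁵ rays/s on one core); its results are tested against a
dense all-triangle scan written independently of the kernel.

## Reprojection rules

* **Point**: one ray; a miss discards the annotation.
* **Polygon / Rectangle / LineString**: every vertex is cast. In the
  default **strict** mode any miss discards the whole annotation —
  discarding is defined per annotation, not per vertex. A **lenient** mode
  keeps the survivors as `partial` when at least three remain; it is
  opt-in, clearly labelled in the output status, and the conservation
  invariant `input = reprojected + partial + discarded` holds in both
  modes.
* **Circle**: the center pixel and the rim pixel `(cx + r, cy)` are cast;
  the 3D radius is the distance between the two hits. This is a
  conservative extension — a circle on a slope is reported by center and
  one radius, not as a full 3D outline.
* Camera/annotation pairing is by exact filename; a case-insensitive stem
  fallback exists behind a flag because silent fuzzy matching hides pairing
  bugs.

**Footprints** reproject the image boundary: the four corners plus
`densify_n` evenly spaced boundary pixels per edge (default 0). Corner-only
footprints under-represent relief on rough terrain, which is why
densification is exposed. `complete` means all boundary rays hit, `partial`
at least three, otherwise `discarded`.

**Locate-back** projects a 3D feature into every camera; a candidate
(in front, inside bounds) is `visible` when the ray re-cast through that
pixel first hits the mesh within 1 mm of the feature — one order of
magnitude below the ~5 mm resolution typical of the meshes this targets,
so occlusion is detected without rejecting surface points that sit a hair
off their facet.

## Georeferencing

The local metric frame is declared east-north-up at a configured anchor
`(lat₀, lon₀, h₀)`; conversion goes ENU → ECEF → geodetic on the WGS84
ellipsoid (`a = 6378137 m`, `1/f = 298.257223563`). The geodetic inverse
uses Bowring's closed form refined by fixed-point iteration to `1e-9 m` in
height. Round trips are below `1e-6 m` within 10 km of the anchor, and the
conversion agrees with a generic least-squares inversion of the forward
model to below `1e-9°`. Heights are ellipsoidal; seafloor depth is `−h`.
No geoid or tide model is applied — that keeps the transform exact and
dependency-free, at the cost of reporting ellipsoidal rather than chart
depths.

## Survey analyses

**Duplicates.** Candidate pairs are reprojected points sharing a label,
from different source images, within a linkage radius (default **5 cm**,
roughly 10× mesh resolution; configurable). Groups are connected components
of the candidate graph. The duplicate percentage counts
`Σ (group size − 1)` over all annotations — one representative (lowest
annotation id) kept per group, so two coincident annotations are 50 %
duplicated. The convention matters when comparing percentages across tools
and is therefore stated in the output.

**Disjoint selection.** Footprints are projected to the horizontal plane
and a greedy pass in acquisition order accepts an image iff its overlap
fraction with every already-selected footprint is at most the threshold.
The overlap fraction is **symmetric** — intersection area over the
*smaller* of the two areas — so a small footprint nested inside a large one
can never slip through on a denominator technicality. An exhaustive
maximum-subset solver (≤ 20 images) exists purely as a cross-check of the
greedy pass. Greedy output is maximal: no skipped image can be added
without violating the threshold.

**Accuracy.** Reprojection error is the 3D Euclidean distance between a
reprojected point and its reference position, summarized by the median and
the interquartile range with linear-interpolation quantiles (stated in the
report metadata). The 3D distance is used instead of the horizontal one
because on near-vertical terrain two points far apart along the surface can
have zero horizontal separation.

## Synthetic surveys

The generator emulates a small deep-sea photo survey and is the package's
test bed:

* **Terrain**: a height field on a regular grid (default step 0.25 m),
  flat, sinusoidal (amplitude/wavelength), or a seeded random field
  (white noise smoothed by a Gaussian kernel, rescaled to a target
  amplitude) — a controllable-roughness analogue of the contrast between a
  flat sediment terrace and a faulted basalt field.
* **Trajectory**: parallel lawnmower lines at constant altitude (default
  5 m altitude, 3 m line spacing, 1 m between frames) with a fixed-heading
  nadir camera; a 2000×1500 px reconstruction camera with mild radial
  distortion, annotations emitted at 2× that resolution to exercise the
  rescaling path.
* **Features**: points sampled uniformly on mesh faces, at least 0.5 m
  apart in the plane, labelled from a small cycling set of morphotypes.
  Each feature is projected into every camera that sees it (in front,
  in bounds, unoccluded per a ray cast) and emitted as a Point annotation;
  features seen by no camera are re-placed.
* **Navigation noise**: a minimal caricature of hybrid navigation —
  horizontal drift accumulating at `drift_per_m` per meter travelled with
  a slowly wandering direction, reset to truth plus Gaussian noise every
  `reset_interval_m` of travel. It reproduces the qualitative phenomenon
  (meter-scale cross-image disagreement under navigation georeferencing
  versus sub-millimeter agreement under optical reprojection) without
  claiming to model an INS/Kalman stack.

Because ground-truth features lie exactly on mesh facets and the cameras
are exact, end-to-end recovery errors are at floating-point scale; the
pipeline's accuracy on real data is instead limited by pose/mesh quality
and terrain roughness, which the generator does not model (no pose error,
no mesh holes unless the terrain is cut, no photometric effects, no
annotator error). Passing recovery tests therefore validates the
*geometry code*, not field accuracy.

## Problem sizes

Validation runs use a 30 × 8 m survey (three transects, ~90 cameras,
~7,700 faces, 60 features, ~700–800 annotations), 500-triangle random soups
with 1,000 rays, and 1,000-case statistical sweeps — sizes chosen so the
whole suite and the acceptance script each complete in seconds on one core
while still exercising every code path at survey-like geometry.

## Known limitations

* Radial-only distortion; fisheye or tangential models are rejected.
* Single-ray reprojection: no multi-view triangulation of a feature's
  position, matching the single-camera provenance of each annotation.
* The greedy disjoint selection is order-dependent (acquisition order) and
  not guaranteed optimal; the exhaustive solver is for verification, not
  production.
* ENU declaration of the local frame is a configuration statement, not an
  inference; a survey whose SfM export is in a projected CRS must say so.
* The navigation-noise model is qualitative; do not use it to size real
  USBL error budgets.
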