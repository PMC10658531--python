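# Methods

This note documents the models, conventions, and design choices behind
`eafadapt`: what each stage computes, why its defaults are what they are,
and what the synthetic tests do and do not establish about real scans.
All internal geometry is in millimetres; clinical reports are in
centimetres at 0.1 cm precision, rounded half-up.

## Scan QC and surface reconstruction

A structured-light scan of an open abdominal wound arrives as a point
cloud. The workflow gates clouds on a minimum count — fewer than 400,000
points triggers a re-scan — because sparse captures under-sample the
fistula rim, which later defines the adapter hole. The threshold is
configurable (`qc_threshold`); it is applied to whichever cloud the caller
designates, and a rejected first capture may be concatenated with a
second, pre-aligned capture (registration is the scanner software's job
and is out of scope — merging is concatenation only).

Reconstruction is deliberately 2.5-D: wound surfaces seen by a scanner
are height fields over the body surface. The cloud is projected onto its
least-squares plane, binned on a regular grid (default pitch 1 mm, of
the order of the cell size that 500k points over a 16 × 12 cm patch
support), one vertex per occupied cell at the mean of its points, and
complete quads are split into two triangles. Vertex averaging suppresses
scanner noise by roughly √(points-per-cell). The plane normal is oriented
so the residual distribution is not skewed toward it (the wound crater
dips toward the body side), with world +z as the tie-break for flat
patches. If fewer than half the bounding-rectangle cells contain points
the pitch is too fine for the sampling density and reconstruction refuses
with a suggestion to enlarge it. General volumetric reconstruction
(Poisson, learning-based) is out of scope; externally reconstructed
meshes can be supplied directly as STL.

## Morphometry

Selections are closed 3D lassos (plain-text x y z rows). The fistula
region is the set of faces whose centroids project inside the lasso on
the lasso's best-fit plane; the largest edge-connected component is kept.
The region's design frame takes its z-axis from the least-squares plane
of the boundary loop, oriented along the mean face normal, with the
boundary's principal directions as x/y.

The extracted fistula contour is the boundary loop projected into the
frame, resampled to 256 points at uniform arc length, counter-clockwise,
and lightly smoothed (5-sample cyclic moving average). The smoothing
removes the mesh-grid zigzag that face boundaries carry — about half a
grid cell in amplitude — while perturbing a smooth contour's area by
only ~0.1%.

Wound measurements follow caliper convention:

* **length / width** — extents of the wound-rim lasso along its two
  in-plane principal axes, length being the larger. Anatomical
  longitudinal/transverse assignment is not knowable from geometry alone,
  so `--swap-axes` exists.
* **depth** — distance from the rim plane to the wound bed, the bed
  being the 5th percentile of signed surface heights inside the rim.
  The percentile (rather than the minimum) matches a clinician measuring
  the deepest region while resisting mesh-noise outliers.
* **orifice height** — per fistula region, the stoma's top plateau level
  (95th percentile of region vertex heights; the selection boundary
  itself lies on the wound bed and cannot serve as the rim level) minus
  the bed level.

## Parametric adapter

The adapter is a hollow ring: the exteriorized intestinal surface passes
through the central hole, the flanged outer wall carries the NPWT sponge
and sealing film. Parameters, with defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| h (height) | 15 mm | device height, clinical range 10–20 mm tracking wound depth; `height=None` in the workflow derives it from the measured depth, clamped to that range |
| d_b (bottom offset) | 5 mm | bottom sketch offset; kept small so the sponge contacts as much granulating wound as possible |
| d_t (top offset) | ≤ 20 mm | brim that holds the polyurethane film; `None` resolves to min(20 mm, rim clearance − 5 mm) so the brim never crowds the adipose wall |
| f (middle fraction) | height rule | middle sketch at z = f·h with f = 0.25 for h ≤ 10 mm, linear to 0.15 at h ≥ 20 mm — lower devices place the waist proportionally higher |
| d_m (middle offset) | = d_b | keeps the body narrow below the brim, giving the conical form the vacuum dressing needs; configurable |
| e (eccentricity) | (0, 0) | xy shift of the top sketch, used when the fistula sits near the wound edge |
| c (hole clearance) | 0 mm | extra hole offset for press-fit relief, at most 1 mm; 0 means the hole matches the intestinal outline exactly |

Construction: the three sketches (outward offsets with round joins, via
polygon buffering at 32 segments per quadrant) are resampled to 256
points at uniform arc length; ring correspondence uses the cyclic start
shift minimizing total squared inter-ring distance (lowest shift on
ties); the outer surface is ruled between consecutive rings and capped by
ear-clipped planar polygons. The through-hole is **not** cut by general
mesh CSG: because the hole is a straight extrusion strictly inside every
cross-section (validated when the sketches are built, with the violating
margin reported otherwise), the ring is assembled analytically from the
outer loft wall, the inner prism wall, and strip-triangulated annular
caps. This is watertight and consistently oriented by construction and
satisfies volume(ring) = volume(loft) − area(hole)·h; the test suite
verifies the identity to 0.5% across randomized specs and cross-checks
the enclosed volume against an independent 0.25 mm voxel-column oracle
to 1%. A 256-gon approximates a circle's area to ~0.01%, so closed-form
comparisons at 0.5% have two orders of margin.

The ledge (protrusion) report gives, at the top and bottom planes, the
minimum and maximum distance from the hole contour to the outer contour,
in cm, rendered as `a–b` with equal endpoints collapsed to a single
number — matching clinical table formatting.

The fit check poses the adapter in the wound's design frame (optionally
resting it on the surface: lifted along the frame z until the bottom face
just touches, the pose a clinician gives it). Penetration is evaluated at
random bottom-annulus samples against the wound surface height looked up
by nearest vertex in the frame xy-plane — adequate for the height-field
meshes this package produces. Hole containment tests the smoothed fistula
outline against the hole polygon with a 0.5 mm tolerance (half a default
grid cell; the raw boundary vertices zigzag at grid scale, and the hole
may equal the outline exactly).

## Phantoms

The phantom emulates what the scanner sees: a skin plane at z = 0, an
elliptical crater wound, and plateau-topped stomas, as the analytic
height field

    z(x, y) = −depth · crater(x, y) + Σ_k height_k · stoma_k(x, y)

where both crater and stoma profiles are 1 on an inner 60% core and fall
to 0 with a C¹ cosine taper. The flat bed and flat plateau make "wound
depth" and "orifice height" unambiguous truth values; the taper mimics
soft adipose walls and avoids reconstruction artifacts at hard edges.
Defaults are the study conditions: a 16 × 12 cm patch, 12 × 8 cm wound,
2 cm deep, one stoma of base radius 12 mm and height 15 mm, 500,000
sampled points (the order of clinical wound meshes, above the QC gate),
and Gaussian noise of σ = 0.2 mm along the local surface normal — the
middle of the 0.1–0.3 mm resolution band of white-light scanners.
Everything is deterministic given the seed.

What phantoms do *not* model: specular/efflux artifacts, occlusion
shadows, multi-view registration error, texture, and soft-tissue
deformation (remodeling is exercised by generating a second phantom with
an altered spec). Passing the recovery tests therefore shows the
pipeline's geometric correctness and noise robustness, not robustness to
every clinical scan pathology. Stomas are circular-based; truth values
for orifice height assume the stoma stands on the flat bed.

Measured recovery (test suite): at σ = 0.2 mm, median absolute error
over 20 seeded phantoms is well under 2 mm for length/width/depth and
under 1.5 mm for orifice height, and total error grows monotonically
with σ over {0, 0.1, 0.2, 0.3} mm.

## Case-series statistics

The packaged fixtures transcribe the per-device (n = 16) and per-patient
(n = 8) tables of the clinical case series, with a checksum manifest;
blank cells (patient 3's number of changes) load as missing and are
excluded pairwise. The printed report pins down the conventions, which
this module implements explicitly:

* **Quantiles**: weighted average at position h = (n+1)p — the only
  standard rule consistent with all four printed median/IQR triples
  (total time, manufacturing time, pruritus before, VAS after). Verified
  in tests against numpy's equivalent `method="weibull"`.
* **Paired measures**: the printed p-values for length/width/cures match
  the paired Student t, and those for depth/pruritus/VAS match the
  signed-rank test in its zero-drop, midrank, tie-corrected
  normal-approximation form (variance n(n+1)(2n+1)/24 − Σ(t³−t)/48,
  no continuity correction). Both are implemented; routing goes through
  a Shapiro–Wilk gate on the paired differences, with per-variable
  override. An exact 2ⁿ sign-enumeration oracle verifies the asymptotic
  signed-rank p to within ±0.01 at these sample sizes.
* **Group comparisons**: pooled-variance two-sample t by default
  (reproducing the printed manual-vs-scanner design-time p = 0.746);
  Welch available. Mann–Whitney U uses the tie-corrected normal
  approximation, with exact label-permutation enumeration available for
  n ≤ 12 as an oracle.
* **Rounding**: comparisons against printed values use decimal half-up
  rounding at each value's printed precision (2 decimals for summaries,
  3 for p-values).

Known discrepancies in the printed report, documented and excluded from
reproduction targets: the post-processing time "63.13 ± 12.92 min"
(12.92 is the column's variance; its sd is 3.59), the therapy duration
"27.71 ± 13.74 days" (matches the table only with patient 3 excluded,
reason unstated), the aggregate device dimensions (e.g. height
"1.48 ± 0.36 cm" vs a column mean of 1.59), and the processed-points sd
printed as 59,604.00 (the column's n−1 sd is 59,604.29).

## Numerical choices and degenerate inputs

* Contours: simple, counter-clockwise, 256 points; self-intersecting
  projections and zero-area contours are rejected with advice to
  re-select. Offsetting keeps the largest component after cleanup;
  offset(C, 0) = C.
* Ear clipping handles the planar caps (O(n²), with a most-convex-corner
  fallback against numerical stalls). Strip triangulation joins
  equal-length aligned loops (walls and annular caps).
* Degenerate statistics: all-zero paired differences report p = 1 with a
  degenerate flag; zero-variance paired t likewise (p = 1 if the mean
  difference is 0, else p = 0).
* Empty meshes cannot be written to STL; STL round-trips merge the
  triangle soup back into shared topology and preserve volume to six
  significant figures.
* The acceptance script reduces problem sizes to desk scale — 20
  randomized adapter specs for the volume identity and 10 phantoms for
  recovery — sizes at which the medians and maxima it reports are stable
  across seeds.

## Limitations

* Reconstruction assumes a height field; undercut wound walls would need
  volumetric reconstruction and are out of scope.
* Length/width are principal-axis extents, not anatomical axes.
* The adapter hole is a straight prism; a fistula whose outline changes
  materially over the device height is approximated by its rim outline.
* Strip-triangulated annular caps assume the hole and outer contours are
  roughly star-shaped with respect to each other, which offsets of a
  common contour with modest (≤ 2 mm) eccentricity guarantee in
  practice; extreme eccentricity is rejected earlier by the containment
  check.
* The statistics module reproduces the conventions of the printed
  clinical report; it deliberately implements no inference beyond it
  (no survival modeling past the 3-month proportion, no multiplicity
  correction).
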