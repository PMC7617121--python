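# Methods

## The measurement model

All measurements derive from the pinhole back-projection of a z-depth map:
pixel `(u, v)` with depth `d` (mm) maps to
`((u−u0)·d/f, (v−v0)·d/f, d)` in camera coordinates.  Depth maps store the
camera-frame **z coordinate** (optical-axis distance), the convention used by
monocular depth estimation networks, not the Euclidean ray length; the
simulator converts ray length to z-depth when it writes a frame.  No lens
distortion model is applied — real endoscopes are wide-angle/fisheye, and the
pinhole assumption is a stated limitation of this implementation rather than
a solved problem.

Lengths are **geodesics along the imaged surface**: a straight 2D line is
rasterized between two pixels (8-connected Bresenham), every path pixel is
back-projected, and consecutive 3D steps are summed.  Esophageal extents are
wall distances, so chords through the lumen would be wrong.  Two consequences
matter numerically:

* On a straight wall generator the summed steps telescope and the length is
  exact; on oblique paths the ±0.5 px rasterization jitter maps to small 3D
  zigzags whose size is the per-pixel depth footprint `Δz ≈ Δ²/(f·r)` at
  range Δ.  The resulting inflation is below ~0.5% for the measurement
  geometries used here, but grows where one pixel spans many mm of wall —
  circumferential arcs need a wide-angle close-range view to stay within the
  2% discretization budget (the arc test uses f = 32 px at ~3 mm range).
* A path crossing a pixel with no depth (a ray that exited the open tube end)
  cannot be measured; such hull vertices are skipped and flagged rather than
  silently bridged.

Areas integrate the 3D footprint of each pixel: the local surface tangents
along the pixel grid (central differences, one-sided at boundaries and next
to invalid pixels) span a parallelogram whose cross-product norm is the
pixel's area contribution.  This makes areas exactly additive over disjoint
masks.

## Prague C&M and BEA

Following the convex-hull construction: the main Barrett's segment's pixels
are fitted with a convex hull; the junction center is the centroid of the
gastric-fold mask, snapped to the nearest valid-depth pixel when it falls in
the lumen (flagged).  C is the minimum junction-center→vertex geodesic (the
circumferential collar's extent), M the maximum (the longest tongue).  C ≤ M
holds by construction.  Prague categories use half-open, lower-inclusive cm
bins [0,1), [1,3), [3,5), [5,7), [7,9), [9,11), [11,∞); boundary handling is
a convention choice, stated here once.

A_b integrates all pixels enclosed by the hull — in a near-axial endoscopic
view of a circumferential segment the hull encloses the junction region too,
which is why the fold area A_fold is subtracted when it exceeds 1 cm²; below
that threshold A_b already is the BEA estimate.  The hull is fitted to the
main segment only; islands are measured separately (diameter and area per
island) and reported alongside, with an optional combined total.  An
enclosing-ellipse summary of the hull is emitted for display only; every
quantitative area comes from per-pixel integration.

Island diameters are the maximal geodesic between island hull vertices with
the path constrained to the island's own surface (shortest paths in a pixel
graph weighted by 3D step lengths, neighborhood radius 4 to keep the
anisotropic-metric overestimate under ~1%).  This matters because an island
of the post-ablation size wraps a large arc of the wall: a 20.3 mm island on
a 20 mm tube spans ~116°, and a straight pixel line between its extrema cuts
across the lumen, overestimating by ~30%.

Assumption checks are recorded as quality flags, never silent: junction not
visible (C/M unset), junction centroid relocated, camera axis more than 30°
off the junction-plane normal (plane fitted to the back-projected fold
pixels), vertex paths skipped.

## The phantom simulator

The phantom is a straight tube, by default 187.5 mm long with 10 mm internal
radius, with painted regions in cylindrical `(θ, z)` coordinates: squamous
background (light pink), Barrett's bands/tongues/islands (dark pink, islands
the same tissue color — components are separated geometrically, not by
color), and a darker-red gastric-fold landmark.  `z_folds`, the top of the
gastric folds, is the axial origin for all C/M ground truth; when unset it
defaults to the distal edge of the Barrett's paint.  An optional sinusoidal
inward perturbation of the distal radius models fold ridges geometrically.

Rendering casts one pinhole ray per pixel and intersects the tube wall in
closed form (vectorized bisection refines hits when the fold perturbation
makes the radius non-constant), records z-depth in float64 (written to disk
as float32 TIFF), shades Lambertian with a point light co-located with the
camera and quadratic attenuation `I/(1 + k·d²)` plus a small ambient floor,
and emits ground-truth masks from region membership of the hit points.
Brightness tiers (low/medium/bright: 0.55/0.85/1.25) and the attenuation
coefficient (4·10⁻⁴ mm⁻²) are simulator defaults chosen to span dim-to-bright
endoscopic appearance; neither is an empirical constant.  The only
pseudo-randomness is the seeded trajectory jitter (roll 0–45°, inclination
0–30°, axial positions for straight/spiral/zigzag paths, forward or reverse);
everything else is deterministic, and a dataset regenerated from the same
config is byte-identical.

Ground truth is analytic: band/tongue areas are rectangle areas on the
unrolled wall (`r·Δθ·Δz`), islands are unrolled disks/ellipses (`π·a·b`),
custom-shaped regions fall back to fine-grid integration; C scans the
circumference coverage from `z_folds` downward at 0.02 mm resolution, M is
the maximal axial paint extent, island diameters are unrolled-plane maximal
extents.

## The reference validation experiments

Two experiments reproduce a printed-phantom style evaluation in silico, with
the error figures of the physical experiment serving as upper bounds (exact
simulator depth removes the depth-estimator's share of the error).

**Length markers** — one phantom carries a 23.4 mm circumferential collar,
two tapered tongues reaching 70.0 and 65.7 mm from the fold top, and wall
islands of diameter 20.3 and 14.3 mm.  Five frames are rendered with the
camera ~95 mm proximal of the folds, inclined 8–12° toward the fold patch
with randomized roll and ±4 mm axial jitter (f = 256 px, ~53° field of view,
so the junction is resolved at that range).  Each marker is measured on its
own ground-truth mask — the analog of measuring one painted marker at a time
with calipers: C on the collar mask, each tongue's M on band+tongue, islands
individually — and the five per-frame values are averaged.  Frame selection
is part of the method: the junction must be visible, the camera near-axial,
and the marker on the same side as the fold landmark, otherwise the
center→vertex path would cross the lumen; the same care applies to real
endoscopic frames.

**Area markers** — three phantoms carry circumferential bands of total area
62.19, 69.05 and 76.25 cm² distal-bounded by an annular fold region of
2.5 cm² (exercising the A_fold-subtraction rule), viewed head-on from just
proximal of the band; a fourth phantom carries two islands of 2.30 and
2.90 cm².  Again five frames per quantity, means compared to the configured
areas.

Typical recovery (seed 1): overall mean relative error 1.1% over the five
length markers (RMSE 0.31 mm, mean deviation 0.30 mm) and 0.4% over the five
areas — computed fresh by `scripts/acceptance.py` and asserted by the
acceptance tests, not quoted from anywhere.

## What the simulator does and does not show

The phantom has flat colors, a perfect cylinder, exact depth and noise-free
masks.  Passing these experiments demonstrates that the geometric measurement
chain — back-projection, hull fitting, geodesics, area integration — is
correct and that its discretization error at 256×256 is sub-millimeter under
sane viewing geometry.  It does not bound errors from a learned depth
estimator, imperfect segmentation of real tissue, peristaltic deformation,
fisheye optics, or frames violating the visibility assumptions; on real data
those dominate.  The color segmenter included here is a deliberate stand-in
for a trained network, interchangeable behind the `SegMasks` interface.

## Numerical choices

* Rendered depth agrees with an independent per-ray root-finder to 10⁻⁶ mm;
  analytic region areas agree with fine-grid integration to 0.1%.
* Rigid pose estimation is point-to-point closest-point iteration (identity
  initialization, 10% worst-correspondence trimming, ≤60 iterations, 4000-
  point subsampling); it recovers clean synthetic transforms to <0.5° and
  <0.5 mm and reports failure above a 1 mm mean-residual threshold instead of
  returning a bad pose.  Surface fusion chains pairwise poses, concatenates
  clouds in the first frame's coordinates and voxel-averages at 0.5 mm.
* Segmentation classifies pixels by nearest reference color in
  hue–saturation space (brightness invariant); masks are closed with a
  1-pixel disk and components under 25 px (~0.04% of the frame) removed,
  idempotently.  Components are split by 8-connectivity; the component
  touching the junction (or the largest, if none touches) is the main
  segment.
* Statistics: unweighted Cohen's kappa (the weighting scheme is a free
  choice; unweighted is the conservative default), Spearman with average
  ranks for ties, two-sided paired t-tests.  Degenerate inputs (single
  category, constant series, zero-variance differences) are flagged, not
  silently given values; relative error against a zero reference (e.g. a
  post-treatment C0M0 score) is excluded from means and counted separately.
  A derived display field reports accuracy as 100 − mean relative error %.
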