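# Methods

## Scope and data model

`berry3d` measures the 3D shape uniformity of a single strawberry from a
coloured point cloud. The expected scene is one berry glued to a dark-blue
polymeric-foam holder (38 × 19 × 19 mm; height × length × width),
reconstructed by Structure-from-Motion at an arbitrary scale and pose, with
per-vertex RGB colour. The pipeline carries two containers:

* `ColouredPointCloud` — raw points + RGB (+ derived HSV) colour;
* `BodyCloud` — the segmented berry body, origin-centred, millimetre-scaled,
  growth axis on +z, with the applied rotation, the unit-to-mm scale factor
  and quality flags.

## Pre-processing

1. **Colour conversion.** RGB → HSV (hexcone model), hue in degrees on
   [0, 360). Note that some imaging stacks report hue on [0, 180]; all hue
   thresholds here are configuration values on the 360° convention.
2. **Denoising.** Keep points whose hue falls in the union of the berry and
   holder bands (`noise_hue_keep`, default red (330°, 30°) ∪ blue
   (200°, 260°), intervals may wrap through 0). SfM clouds routinely contain
   stray vertices; rows with non-finite coordinates are likewise dropped and
   counted rather than treated as errors.
3. **Centring.** Translate the cloud moment (unweighted mean of
   coordinates) to the origin. Covariances throughout use 1/N
   normalisation — irrelevant to eigenvectors, fixed for reproducibility.
4. **Axis alignment.** The main orientation is the eigenvector of the
   largest eigenvalue of the point covariance of the *whole* denoised cloud
   (berry + holder). The holder anchors this axis: the body alone has
   comparable vertical and horizontal variances for squat berries — and a
   strongly lobed berry's body-only principal axis can even be horizontal —
   so a body-only estimate is noisy (∼1°) or outright wrong, while the
   berry+holder column is unambiguous. The sign is chosen so the
   holder-coloured points end at negative z (nose up); without holder
   colours, the fuller hemisphere goes down. A near-isotropic covariance
   (largest/second eigenvalue below 1 + 1e-6) yields the identity rotation
   and a `degenerate-axis` flag.
5. **Segmentation.** Holder = points with hue in `holder_hue_range`; body =
   complement. Either segment under `min_segment_points` (default 500) is a
   hard error. Calyx-green points are already gone after step 2 under the
   default bands.
6. **Scale standardisation.** `scale = 38 mm / holder z-extent`; the 38 mm
   dimension is listed as the holder's height (the value is configurable in
   case a different holder is used). The body is then re-centred on its own
   centroid (the drift from the whole-cloud centroid is recorded, not
   hidden) and its **azimuth is canonicalised**: the body's larger x–y
   principal axis is rotated onto x, up to an intrinsic 180° ambiguity.
   Without this, the azimuth after axis alignment is arbitrary, and the two
   discretely sampled metric families (side views every 3.6°, 16 curvature
   patches) would vary by up to tens of percent under an input rotation;
   with it, all eight metrics are reproducible to machine precision under
   rigid motion + uniform rescaling of the input (verified for 20 random
   transforms per fixture). Solids of revolution have no x–y anisotropy and
   skip the spin — harmlessly, since their metrics do not depend on azimuth.

## Side-view metrics (CV_A, Max_A/Min_A, CV_D)

The equatorial band (points within the middle 50 % of body height, which
excludes calyx and nose artefacts) is rotated about z in 100 steps of 3.6°
and projected onto the x–z plane. Each view contributes the area of the 2D
convex hull of the projected points — a geometric hull rather than a
rasterised silhouette, so the measure is resolution-independent
(concavities are bridged in either formulation) — and the axial angle of
its first principal direction. Since a projection is invariant to viewing a
point set from behind, view i + 50 mirrors view i; areas of the second half
are taken from the first by construction, making the 180° symmetry exact.

CV_A = population σ/μ of the areas; Max_A/Min_A = max/min. Population
(1/N) standard deviations are used in every CV for consistency.

**CV_D convention.** Per-view orientations are axial quantities (defined
mod 180°, eigenvector sign-free), and their CV is ill-posed if taken
naively: for wide berries the band projects wider than tall, the major axis
is horizontal, and angles measured from vertical flip between ±90°. The
implemented convention: compute the circular-mean axis by angle doubling,
express each view as its signed deviation from that mean (in (−90°, 90°]),
add 90° so the mean sits near 90, and take σ/μ. Views at 80° and 100° give
CV_D = 10/90 ≈ 0.111; any solid of revolution scores ≈ 0 in any pose.

## Slice metrics (L/W, CIR, STR)

100 slice planes sit at the centres of equal sub-intervals of the body
height; a slice collects points within a slab of half-width H/200 (adjacent
slabs tile the height; a true plane would intersect no sample points).
Slices with fewer than 3 non-collinear points are invalid and excluded.
Per valid slice: convex hull in x–y, its area, perimeter, and area centroid
(the contour moment — density-independent, unlike the mean of member
points). The largest slice is the valid one with maximal hull area, ties
going to the lower (holder-side) index.

* **L/W**: extents of the largest slice's points along its two 2D principal
  directions, longer over shorter.
* **CIR** = 4πA/p² of the largest slice's hull; ≤ 1 by the isoperimetric
  inequality, exactly π/4 for a square and π√3/6 for a regular hexagon
  (used as oracles).
* **STR**: 3D centroids (hull centroid + slice z) of the slices in the
  middle 80 % of body height — exactly 80 of the 100 with the
  interval-centre levels — joined into a polyline; STR = polyline length /
  end-to-end distance. Invalid slices inside the window are bridged.
  Including z in the centroid distance makes 1 the exact floor for a
  straight axis.

A slice-centroid path systematically reflects both the bent axis and the
profile taper, so STR on bent synthetic berries is compared against an
independent arc-length/chord quadrature of the generator's axis function at
the 2 % level (closed berry-like profiles; an open bent cylinder's tilted
end rings bias the end centroids and are not a realistic berry).

## Curvature metrics (CV_C, Max_C/Min_C)

Curvature is noise-sensitive, so the body is first smoothed by **moving
least squares**: each point is projected onto a degree-2 polynomial surface
fitted over its radius neighbourhood (Gaussian weights of bandwidth
radius/2, cut off at the radius) in the frame of the local tangent plane
(normal = smallest-eigenvector of the local weighted covariance). The
default radius is 4× the mean nearest-neighbour spacing: on a
Poisson-sampled surface this captures ≈ 12 points, comfortably above the 6
unknowns of the quadric; at 2.5× only ≈ 5 fall inside and half the cloud
cannot be fitted. Points with fewer than 6 neighbours are copied unsmoothed
and counted; above 10 % unsmoothed the record is flagged.

Principal curvatures come from an unweighted quadric fit over the 30
nearest neighbours in the local tangent frame, with the frame's z-axis
along the inward normal so that convex regions are positive: k₁ ≥ k₂ are
the eigenvalues of [[2a, b], [b, 2c]] from
z' = ax'² + bx'y' + cy'² + dx' + ey' + f. On samples of a sphere of radius
R this recovers 1/R within 5 %, on a cylinder (1/r, 0) within 10 %, and the
estimate scales exactly as 1/c under uniform dilation by c (the
neighbourhood graph is scale-invariant).

Sixteen patches are seeded at 22.5° spacing around the largest-slice
centroid; each seed is the slice contour point nearest its direction and
its patch the 200 valid-curvature body points nearest the seed (a k-NN
stand-in for the vertical stripe a fixed angular sector would cut). The
patch curvature is the mean of the upper half of the members' average
curvatures (midpoint joining the upper half for odd counts: {1,2,3,4} →
mean{3,4} = 3.5). CV_C and Max_C/Min_C summarise the 16 values; if the
smallest patch curvature is not positive (flat/saddle patch) the ratio is
reported missing with a flag rather than as a meaningless negative number.

## Synthetic berries

The generator emulates the acquisition scene: a berry surface of revolution
r(z) — cylinder, cone, sphere, or a smooth conic-berry spline widest ≈ 40 %
up the fruit (defaults 30 mm tall, 12.5 mm maximum radius, typical of ripe
dessert strawberries) — sampled in proportion to surface area
(r·√(1+r'²) in z, circumference factor in θ), plus the 38 × 19 × 19 mm
holder box sampled at matching surface density, at 50 000 berry points by
default. Controlled deformations with recorded ground truth:

* angular lobes r(z,θ) = r(z)(1 + a·cos mθ);
* a bent axis — C-shaped (`sine`), S-shaped (`s_curve`) or circular-arc
  lateral offset. An S-bend is what CV_D responds to: a C-bend's symmetric
  bulge leaves every view's principal axis near vertical;
* Gaussian surface jitter and a configurable fraction of stray points with
  green-to-cyan hues (disjoint from the berry/holder bands, so part labels
  remain an exact oracle for denoising and segmentation);
* rigid tilt, arbitrary global scale, and a random translation, all
  recorded.

Same spec + seed → byte-identical output (one RNG stream per call).

What the generator does **not** emulate — and what passing tests therefore
do not certify on real data: achene pits and surface texture, occlusion
holes (especially the under-reconstructed nose of globose fruit),
SfM-correlated (non-isotropic) noise, calyx remnants overlapping the berry
hue band, and non-Lambertian colour variation. Tests establish that the
geometry engine is correct; threshold choices for real imagery remain a
per-rig calibration.

## Numerical choices and degeneracies

* Hull extraction via Qhull (`scipy.spatial.ConvexHull`), polygon measures
  via shapely; verified exactly against an O(N³) extreme-edge oracle on
  small instances.
* Eigen-decompositions are the only tie-prone steps; thresholds of 1 + 1e-6
  on eigenvalue ratios decide degeneracy (axis, azimuth, collinear slices),
  and every degenerate path is flagged, not guessed.
* The measurement path contains no randomness: identical input and
  configuration give identical records, and batch output is independent of
  file order.
* Problem sizes in the test-suite: 15–50 k points per cloud. Ideal-solid
  limits are asserted at 50 k (CV_A, CV_D within 0.005 of 0; Max_A/Min_A,
  L/W within 0.005 of 1); rigid-motion invariance is asserted on deformed
  fixtures, where every metric carries signal — a relative comparison on a
  solid of revolution's CV would only measure the sampling-noise floor,
  which the ideal-limit test already bounds absolutely.

## Known limitations

* PCA alignment assumes the berry+holder column is the longest direction of
  the scene; a berry much wider than the combined column height would
  mis-align (not reachable with the standard holder).
* The equatorial band and slice windows are fractions of measured body
  height, so severe nose occlusion in real reconstructions shifts all
  windows slightly; STR is the most affected metric.
* Patch curvature depends on `patch_k` (default 200) and the smoothing
  radius; CV_C/Max_C/Min_C are comparable only across runs with the same
  configuration (the per-row config hash exists for exactly this reason).
* Hue thresholds are nominal for the synthetic palette and must be
  re-calibrated per imaging rig (`berry3d dump-config` emits the full
  configuration for editing).
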