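# Methods

`grain3d` measures wheat grains from merged structured-light surface
scans: a point cloud (mm) of many grains resting on a planar stage is
segmented into single grains, 32 shape and ventral-sulcus traits are
extracted per grain, and cross-validated regression models predict
single-grain weight from the traits.  This note records the models,
parameter choices and numerical decisions, and what the synthetic-data
tests do and do not establish.

## Measurement chain

**Preprocessing.**  The merged cloud is thinned on a voxel grid (default
0.1 mm, one centroid per occupied cell; the grid origin is snapped to
the voxel lattice so a second pass is a no-op), cleared of statistical
outliers (mean distance to k = 20 nearest neighbours beyond the global
mean + 2 SD), and rotated into its principal frame: with centroid A and
covariance eigenvectors e1, e2, e3 (descending eigenvalue), points map
as x -> M (x - A) with M = {e1, e2, e3}.  Eigenvector signs are fixed
(largest-magnitude component positive for e1 and e2, e3 = e1 x e2) so
the output frame is deterministic and right-handed.

**Stage removal.**  The stage is the dominant plane, found by RANSAC
over 3-point hypotheses (default threshold 0.15 mm, 1000 iterations,
fixed seed) and refined by least squares on its inliers.  Everything
within the threshold of the plane or below it is dropped.  A best
inlier fraction under 0.2 raises "no dominant plane".

**Segmentation.**  Region growing over a 30-nearest-neighbour graph:
normals and curvature come from local PCA; growth starts at
minimum-curvature seeds and crosses an edge when unoriented normals
deviate by less than 12°.  Clusters outside [500, 20000] points are
discarded.  The minimum is set for the emulated scanner density
(point distance ~0.16 mm, so a 6 mm grain carries well over 1500
points); smaller clusters are fragments — typically crease-wall strips
that the normal-angle barrier detaches, since no angle threshold short
of 90° crosses a fold whose curvature radius (~0.1 mm) is below the
point spacing.  Touching grains are not split further (no watershed);
grains must be laid out with >= 2 mm gaps for reliable counts.

**Per-grain geometry.**  Each segment is PCA-aligned (X = length axis);
length/width/thickness are the axis-aligned extents l = x_max - x_min
etc.  The surface is triangulated by projecting points radially onto a
unit sphere about a star centre and re-using the convex-hull
connectivity of the directions: watertight, consistently oriented, and
every vertex is an input point.  Among candidate centres along the
minor axis the triangulation with the smallest area is kept — a centre
that cannot see part of the surface radially (into the ventral crease)
folds the triangulation, which only inflates area, so the minimum
identifies the best star centre; for convex clouds all candidates tie.
Surface area is the sum of per-triangle Heron areas
s = sqrt(p(p-a)(p-b)(p-c)) (radicands driven negative by rounding clamp
to zero); it agrees with the cross-product formula to 1e-9.  Volume is
the signed-tetrahedron (divergence-theorem) sum over the closed,
consistently re-oriented mesh, algebraically equal to prism
decompositions against any reference plane; boundary loops of <= 30
edges are fan-filled first and larger holes are an error.

**Projections.**  The aligned cloud is projected along each axis and
triangulated by a locally adaptive alpha complex: every point gets a
local scale (8th-neighbour distance) and a Delaunay edge survives when
it is at most 2x the larger endpoint scale.  A global edge limit fails
here because silhouette edges collect points from the whole depth range
and are ~10x denser than face interiors.  Section area is the summed
triangle area, perimeter the summed length of edges used by exactly one
triangle; concave outlines (the crease notch in the cross-section) are
respected rather than convexified.  Roundness is c = 4*pi*S/C^2 per
section; sphericity E = pi^(1/3) (6V)^(2/3) / S_a.

**Ventral sulcus.**  Nine slabs, 0.4 mm apart, centred on the grain
centre; slab thickness defaults to the full 0.4 mm interval, mirroring
the destructive protocol this measurement replaces (grains cut into
contiguous 0.4 mm slices) and keeping ~150+ points per section at
scanner density.  The slab's points project to (y, z); the profile with
the largest convex-hull area is measured.  The two farthest hull
vertices are the sulcus edge points; a RANSAC circle (threshold 0.3 mm,
500 iterations, fixed seed, minimum inlier fraction 0.25) supplies a
central reference point, and the profile point nearest the circle
centre is the deepest point.  Depth D is its perpendicular distance to
the edge-point chord.  The circle threshold is deliberately coarse: its
role is to locate a centre for the whole section, and a tight threshold
lets the consensus set collapse onto a partial arc whose centre drifts
toward one side, occasionally electing the dorsal apex as "deepest".
The minimum inlier fraction is 0.25 because no single circle tracks
more than ~half of a section with aspect ratio ~1.2 at tight tolerance.
Slice perimeter C_c and area S_c come from the profile polygon ordered
by polar angle about its centroid (star-shapedness about the centroid
is assumed; violations warn); the fan area is a signed shoelace sum so
concave crease wedges subtract correctly; sulcus area S_s is hull area
minus S_c.  The ventral side is never identified explicitly — the
measures are orientation-free.

**Traits.**  16 basic values (l, w, h, V, S, D, three section
perimeters/areas, C_c, S_c, S_s, l/w) and 16 derived (dimension ratios,
box volume l*w*h, surface/volume ratios, section roundness, sphericity)
form the 32-trait record.  Accuracy metrics: MAPE (percent),
RMSE, and R^2 = 1 - sum (x_i - y_i)^2 / sum (x_i - mean(y))^2 with x the
reference and y the system measurement — note the centring on the
*system* mean; a `r2_definition="standard"` switch restores the
textbook form.  The L9 range analysis computes K[f][i] as the mean
response of the three tests at level i of factor f (the published
table's K values are level means), R[f] as the range of K, and the best
level as argmin K.

**Weight models.**  LR, Bayesian ridge, KNN, random forest and gradient
boosting regressors (scikit-learn) under 10-fold cross-validation:
features standardized on each training fold only; KNN/RF/GBR
hyperparameters grid-searched inside each training fold (3-fold inner
CV; grids: k in {3,5,7,9,11}; trees in {100,300,500} x depth
{None,5,10}; learning rate {0.05,0.1} x trees {100,300} x depth {2,3}),
so reported fold metrics see no leakage.  Fold metrics use the same
MAPE/RMSE/R^2 implementation as the trait evaluation.  Weights outside
the 25-50 mg band typical of single wheat grains warn but do not fail.

## Synthetic data

The generator emulates the scanner output so every stage is testable
without scan data.  A grain is a superellipsoid (exponent 2 by default;
semi-axes default (4, 1.6, 1.4) mm, length 6-10 mm across the sampled
ranges) with two wheat-specific features:

* a **cheek bulge** — width scaled by 1 + 0.10 exp(-(z/0.25 mm)^2) —
  because real wheat sections are rounded-triangular with a localized
  width maximum; on a pure ellipse the farthest-point direction is
  degenerate over +-20°, an artifact no real grain shares;
* a **ventral crease**: material below
  z = -c + (c - d) exp(-(y/sigma)^(2m)) is removed (sigma = half the
  1.0 mm groove width, m = 2), giving Gaussian-like walls and a gently
  rounded U floor whose ridge sits exactly `groove_depth` = d mm below
  the mid-width chord.  `groove_depth` is therefore defined as the
  quantity the slicing procedure measures (deepest point to the
  farthest-points chord, the same definition used for manual ground
  truth on slice images), not as an indentation magnitude;
  `groove_depth=None` disables the crease, and d = 0 means a crease
  reaching the chord plane.  The flat floor (m = 2) reflects a real
  crease fold at 0.16 mm sampling and makes the deepest point robust to
  lateral scatter of the circle centre, which a knife-edge floor is not.

Points are sampled area-weighted by rejection (numerical surface
Jacobian; no pole clustering), split between shell and crease wall in
proportion to their areas, with isotropic Gaussian jitter of 0.01 mm —
the residual noise plausible after merging ~12 views from a scanner
with 0.05 mm single-view accuracy.  Default 2500 points per grain
matches the scanner's 0.16 mm point distance on a ~60 mm^2 grain.
Ground truth (l, w, h, V, S_a, D, sulcus cross-section area) comes from
numeric quadrature of the same analytic solid (midpoint grids for
volume and wall area, spherical quadrature for shell area, dense
boundary polygon for the section), independent of the measurement path;
it agrees with Monte-Carlo point-in-solid estimates to well under 1%.

Scenes place grains on a 12 mm grid above a z = 0 stage sample
(0.3 mm spacing, 0.02 mm roughness) with random yaw and size jitter;
per-point labels record the truth.  The weight dataset draws shapes
across the wheat range (a in [3.2, 4.8], b in [1.40, 1.62] mm,
c/b in [0.86, 0.94], d in [0.3, 0.8] mm), measures traits with the real
pipeline, and sets weight = 1.05 mg/mm^3 x true volume + N(0, 0.5 mg),
landing in the 25-50 mg band.

What passing tests show — and do not.  The generator has no occlusion,
no view-merging artifacts, no specular dropouts, no touching grains and
no stage-colour effects; recovery numbers quantify the algorithmic
chain under clean scanner-like sampling, not field performance.

## Observed accuracy and known limitations

* Length/width/thickness recover with MAPE ~0.2/0.4/1.5% over 50 random
  grains; thickness is the worst because the width-thickness covariance
  gap is smallest, so the principal frame wobbles by a degree or two at
  2500 points per grain — an intrinsic property of PCA-based oriented
  bounding boxes on near-round sections.
* Sulcus depth recovers with MAPE ~5-8% (seed-dependent).  The floor is
  set by the edge chord: slice points near the width extremes space
  ~0.06 mm apart, so the chord through the two farthest hull points
  carries a vertical offset of +-0.03 mm — about 6% of a typical
  0.55 mm depth.  This is a property of the farthest-points definition
  at scanner density, not of the implementation; published accuracies
  for this procedure were measured against manual references that share
  the same edge-point definition and hence part of the error.
* On grooveless convex sections the deepest-point definition is
  ill-posed (every boundary point is roughly equidistant from the
  centre); depth values for grains without a crease are not meaningful.
* Scene-level (segmented) grains lose their crease-wall strips to the
  normal-angle barrier, so sulcus traits from full-scene runs are less
  reliable than from isolated grain clouds; dimensional traits are
  unaffected.
* Mesh area inflates ~1-3% under point noise (jagged triangulation);
  volume is unbiased.  Star-shaped reconstruction assumes grains without
  severe overhangs; the crease walls are near the limit, which the
  area-minimizing centre selection mitigates but does not remove.
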