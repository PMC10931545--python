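# Methods

## Scope and coordinate conventions

`kneeval` quantifies how well an X-ray-derived 3D knee bone model matches a
CT-derived ground truth, in the terms a TKA planning workflow cares about:
whole-surface error, error at bony landmarks, error along simulated
resection cuts, and angular error of the anatomical axes relative to what
human observers themselves disagree by.

All geometry lives in a right-handed patient frame in millimetres: +x
left→right (lateral for a right knee), +y posterior→anterior, +z
distal→proximal. Left knees are mirrored through x = 0 on ingest (face
winding flipped, `mirrored` flag recorded), so "medial" is always −x
internally. This removes the sign ambiguity from every side-dependent rule
(valgus rotation direction, medial-condyle search) at the cost of one
explicit, recorded convention.

## Surface RMSE

The global metric is deliberately literal: after registration, the distance
from **each vertex of the predicted mesh** to the **closest vertex of the
ground-truth mesh**, root-mean-squared. N is counted on the prediction side.
Vertex-to-vertex (rather than point-to-surface) distance is the defining
choice of the metric, so it is the default; it makes the measured value
depend mildly on the reference mesh's sampling density, which is acceptable
when both meshes are dense relative to the error magnitude (tens of
thousands of vertices at sub-millimetre errors). A point-to-surface
alternative (exact point-triangle distance, KD-tree candidate faces) exists
for analyses where the reference is coarse — the voxelization round-trip
test uses it, because a one-voxel fidelity bound is meaningless when the
vertex spacing of the reference exceeds the voxel size.

Registration is point-to-point ICP: nearest-neighbour correspondences
(gated at `max_correspondence`, default 10 mm), closed-form least-squares
rigid update (SVD/Kabsch), stopping when the mean correspondence distance
improves by less than `tolerance` (default 1e-6 mm) or after
`max_iterations` (default 100). Initialization is deterministic: centroid
alignment plus the four proper principal-axes alignments are scored by
initial mean closest-point distance on a uniform 1000-vertex subsample and
the best is kept. Point-to-point (not point-to-plane) matches the
vertex-to-vertex definition of the metric; trimming and point-to-plane
variants are intentionally not guessed at.

## Mask to mesh

Ground-truth segmentations arrive as binary volumes (NIfTI via nibabel,
NRRD via SimpleITK; header spacing/origin/direction honoured, never
assumed). Marching cubes on a *raw* binary grid produces a staircase
surface whose area overestimates a smooth object's by ~9%; the enclosed
volume is essentially exact. `mask_to_mesh` therefore anti-aliases the
binarized grid with a Gaussian of σ = 1 voxel before extracting the 0.5
iso-surface, which recovers both area and volume of a 20-voxel-radius
sphere to better than 1%. `smooth_sigma_vox=0` restores the raw binary
surface; if the filtered field never reaches the iso level (structures a
couple of voxels across), the raw field is used automatically so tiny masks
still mesh. The volume is padded with background so surfaces close at the
boundary.

## Landmark regions

Each landmark is annotated as single points by several observers over
several repeats (the emulated design: 3 observers × 2 repeats = 6 points).
Region construction:

1. **Outlier rejection** — iteratively discard the annotation farthest from
   the centroid of the others while that distance exceeds
   max(2 mm, 2 × median pairwise distance), never dropping below
   max(3, ⌈n/2⌉) inliers. The rule is deterministic and scale-aware; the
   2 mm floor prevents discarding points in a tight, sub-millimetre
   cluster.
2. **Center** — the inlier centroid snapped to the nearest mesh vertex.
3. **Membership** — all mesh vertices within `landmark_radius_mm`
   (default 5 mm, configurable per run) of the center. Euclidean distance
   by default; a geodesic (edge-graph shortest path) option exists for
   strongly curved regions. At the 5 mm scale on locally convex knee
   regions the two nearly coincide.

The radius is not a measured quantity — it sets how much surface around the
consensus point counts as "the landmark region" — and 5 mm is chosen as the
typical feature scale of condylar/plateau landmarks. Local RMSE is the
global metric restricted to the region's vertices (prediction-side region,
distances to the ground-truth mesh, mirroring the global direction).

## Resection-plane simulation

* **Femoral anatomical axis** — the mesh is sliced perpendicular to its
  principal long axis every 2 mm within a configurable shaft band (default
  35–90% of the longitudinal extent, excluding the condylar mass), each
  slice's perimeter-weighted section centroid is taken, and a least-squares
  3D line is fitted through the centroids, oriented distal→proximal.
* **Mechanical-axis estimate** — the anatomical axis rotated by the valgus
  angle (default 5°) in the coronal plane about the distal endpoint. The
  rotation axis is the component of the AP direction orthogonal to the
  shaft direction, which makes the anatomical-to-mechanical angle *exactly*
  the requested angle even when the fitted shaft axis carries a small AP
  tilt; the sign tips the proximal end medially (toward the femoral head).
* **Femoral cut plane** — normal along the mechanical estimate, through the
  most distal vertex of the medial half / distal quarter of the bounding
  extent, offset 9 mm proximally (both the search region and offset
  configurable). Axes more than 45° from the longitudinal direction are
  rejected as implausible rather than silently producing a sideways cut.
* **Tibial cut plane** — normal along the tibial shaft axis tilted
  posteriorly by the slope (default 3°, a mid-range surgical value — the
  slope magnitude is a simulation parameter, not a measured one), through
  the centroid of the proximal 5 mm vertex band, offset 9 mm distally. The
  same orthogonal-component rotation trick keeps the tilt exact.

**Contours.** The plane-mesh intersection (triangle-plane segments chained
into closed loops) is projected into the plane's deterministic (u, v) basis
and each loop resampled at uniform arc length, 0.1 mm by default,
interpreted as contour resolution. Resampling starts at the minimal-u point
and proceeds counter-clockwise, making contours reproducible. Loops shorter
than three spacing steps are dropped as degenerate; remaining loops are
ordered by descending enclosed area and the largest is used for RMSE (all
are returned). Contour RMSE mirrors the surface metric: nearest-point
distances from each predicted contour point to the ground-truth contour.

## Axis statistics

TEA, PCA and MLTA are built per observer-repeat from their defining
landmark pairs (epicondyles; posterior condyles; plateau points), projected
endpoint-wise onto the relevant cut plane (TEA/PCA femoral, MLTA tibial),
and treated as **undirected** 2D lines — angles live in [0°, 90°], computed
with an atan2 formulation that is exact at zero. Baseline statistics
enumerate all unordered ground-truth pairs (15 for 6 annotations); cross
statistics all ground-truth × prediction pairs (36 for 6 × 6). Study-level
tables pool raw pairwise angles across bones before taking mean and sample
SD (rather than averaging per-bone means); per-bone averaging is available
as an option. All SDs in the package use the n−1 denominator — this is also
what reproduces the reference cohort table's printed mean ± SD row from its
18 per-patient values.

## Synthetic data: what it does and does not show

Bones are unions of analytic signed-distance primitives — a femur is a
shaft cylinder, two posterior-distal condylar spheres (medial slightly
larger and more distal, so the distal-most point is medial, as in anatomy)
and an anterior trochlear lobe; a tibia is a shaft, a flattened plateau
ellipsoid and an anterior tuberosity bump. Sampling the field at the
`mesh_density` voxel size (default 1.5 mm → ~12k femur vertices) and
marching-cubes at level 0 gives closed genus-0 meshes whose landmark
coordinates are known in closed form. The stylization is deliberate: the
pipeline's metrics are geometry-agnostic, and recovery tests need exact
truth, which a statistical-shape-model bone would not provide.

The emulated reconstruction error is a smooth random normal-direction
offset field — a truncated random plane-wave expansion with wavelengths
drawn around the correlation length (default 25 mm, guarded to stay above
twice the mesh edge length) — rescaled so its realized RMS equals the
requested value exactly, followed by a rigid misalignment. Defaults target
the sub-millimetre regime of real X-ray-to-CT validation (0.9 mm scale,
with ±30% per-patient variation in the cohort generator, small random
rigid offsets of a few mm/degrees). Observer annotations add a fixed
per-observer-per-landmark bias and fresh per-repeat noise (both 1 mm SD by
default, the repeatability scale reported for human landmark annotation on
knee CT), then snap to the nearest mesh vertex as a click on a rendered
surface would.

What passing tests show: the metrics recover known error magnitudes
(offset RMS to within 10%, rigid misalignment to effectively zero), the
statistics match brute-force enumeration exactly, and the geometric
constructions satisfy their defining constraints exactly. What they do not
show: performance on real bone shape variation (osteophytes, strong
asymmetry), real observer behaviour (biases correlated with surface
features rather than isotropic), or segmentation errors that are not
smooth fields — conclusions about a real reconstruction method still
require real paired data.

## Numerical and determinism choices

* One master seed per generator run; per-stage child seeds derived via
  `SeedSequence.spawn` and recorded in the cohort manifest.
* ICP, initialization, outlier rejection, contour resampling and region
  membership are all deterministic for fixed inputs; regression tests
  assert bitwise repeatability where meaningful.
* STL vertices are de-duplicated deterministically (lexicographic order) on
  read; truncated binary STL files are rejected with the byte offset, not
  parsed partially.
* Degenerate inputs fail loudly: empty masks, empty intersections, planes
  missing the bone, axes parallel to projection planes, non-consensus
  annotation sets.
* Problem sizes in the shipped tests and acceptance script: ~12k-vertex
  femora / ~7k-vertex tibiae, 6-patient simulated cohorts, 20-bone axis
  simulations, brute-force oracles at ≤500 points — sizes at which every
  tested property is already stable.

## Known limitations

* The vertex-to-vertex metric inherits a dependence on reference mesh
  density; report vertex counts alongside RMSE values.
* The anatomical-axis fit assumes the mesh includes a usable shaft segment;
  very short distal fragments will be rejected (fewer than 5 slices).
* Geodesic region membership uses edge-graph shortest paths, an upper bound
  on true geodesic distance that slightly under-fills regions on coarse
  meshes.
* The synthetic cohort's inter-patient variation is parametric scaling, not
  shape variation; cohort-level SDs from synthetic runs characterize the
  generator, not anatomy.
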