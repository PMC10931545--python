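"""Simulated TKA resection planes and cut-contour RMSE.

The distal femoral resection is simulated by (1) fitting the femoral
anatomical axis to shaft cross-section centers, (2) rotating it by a fixed
valgus angle (default 5 degrees) in the coronal plane to estimate the
mechanical axis, and (3) placing the cutting plane perpendicular to that
mechanical axis, offset 9 mm proximally from the most distal point of the
medial condyle.  The proximal tibial resection plane is perpendicular to the
tibial shaft axis tilted posteriorly by the tibial slope, offset 9 mm
distally from the proximal plateau center.

Each plane's intersection with a bone mesh yields closed cross-section
contours, resampled at uniform arc length (default 0.1 mm); predicted and
ground-truth contours on the same plane are compared with nearest-point
RMSE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .geometry import (
    ANTERIOR_DIRECTION,
    CutPlane,
    MEDIAL_DIRECTION,
    PROXIMAL_DIRECTION,
    TriangleMesh,
    make_plane,
    project_to_plane,
)
from .registration import RmseResult

log = logging.getLogger(__name__)

AXIS_NAMES = ("anatomical", "mechanical", "TEA", "PCA", "MLTA")


@dataclass
class Axis3D:
    """A 3D line through two endpoints, used both for shaft axes and for
    annotated anatomical axes (TEA/PCA/MLTA)."""

    name: str
    p0: np.ndarray
    p1: np.ndarray
    provenance: tuple | None = None  # (model_source, observer_id, repeat_index)

    def __post_init__(self) -> None:
        if self.name not in AXIS_NAMES:
            raise ValueError(f"axis name must be one of {AXIS_NAMES}")
        self.p0 = np.asarray(self.p0, dtype=np.float64).reshape(3)
        self.p1 = np.asarray(self.p1, dtype=np.float64).reshape(3)
        if np.linalg.norm(self.p1 - self.p0) <= 1.0:
            raise ValueError("axis endpoints closer than 1 mm")

    @property
    def direction(self) -> np.ndarray:
        d = self.p1 - self.p0
        return d / np.linalg.norm(d)


@dataclass
class Contour2D:
    """Closed cross-section polyline in cut-plane (u, v) coordinates.

    ``points`` stores the loop without repeating the first point; closure is
    implied.  After resampling, consecutive spacing is uniform to within 10%
    of ``spacing``.
    """

    points: np.ndarray
    spacing: float
    plane: CutPlane | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        if len(self.points) < 3:
            raise ValueError("contour needs at least 3 points")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def perimeter(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())

    @property
    def area(self) -> float:
        """Enclosed (shoelace) area, positive for counter-clockwise loops."""
        x, y = self.points[:, 0], self.points[:, 1]
        return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


# ---------------------------------------------------------------------------
# axes
# ---------------------------------------------------------------------------


def fit_anatomical_axis(
    mesh: TriangleMesh,
    shaft_fraction_range: tuple[float, float] = (0.35, 0.9),
    slice_step: float = 2.0,
) -> Axis3D:
    """Fit the anatomical (shaft) axis of a long bone.

    The mesh is sliced perpendicular to its principal long axis at
    ``slice_step`` mm intervals within ``shaft_fraction_range`` of the
    longitudinal extent (measured distal to proximal, so the default skips
    the distal 35% where the condyles or plateau live); each slice's
    cross-section centroid is taken and a least-squares 3D line is fitted
    through the centroids.  The direction is oriented distal -> proximal.
    """
    v = mesh.vertices
    centroid = v.mean(axis=0)
    _, _, Vt = np.linalg.svd(v - centroid, full_matrices=False)
    long_axis = Vt[0]
    if long_axis @ PROXIMAL_DIRECTION < 0:
        long_axis = -long_axis
    t = (v - centroid) @ long_axis
    t0, t1 = t.min(), t.max()
    extent = t1 - t0
    lo = t0 + shaft_fraction_range[0] * extent
    hi = t0 + shaft_fraction_range[1] * extent
    tm = mesh.to_trimesh()
    centers = []
    for s in np.arange(lo, hi, slice_step):
        sec = tm.section(plane_origin=centroid + s * long_axis, plane_normal=long_axis)
        if sec is None:
            continue
        loops = sec.discrete
        if not loops:
            continue
        loop = max(loops, key=len)[:-1]  # drop duplicated closing point
        # perimeter-weighted centroid of the slice polygon
        nxt = np.roll(loop, -1, axis=0)
        seg_len = np.linalg.norm(nxt - loop, axis=1)
        mid = 0.5 * (loop + nxt)
        centers.append((mid * seg_len[:, None]).sum(axis=0) / seg_len.sum())
    if len(centers) < 5:
        raise ValueError(f"only {len(centers)} usable shaft slices (need >= 5)")
    centers = np.array(centers)
    c0 = centers.mean(axis=0)
    _, _, Vt = np.linalg.svd(centers - c0, full_matrices=False)
    d = Vt[0]
    if d @ long_axis < 0:
        d = -d
    proj = (centers - c0) @ d
    p0, p1 = c0 + proj.min() * d, c0 + proj.max() * d
    log.info("anatomical axis: %d slices, direction %s", len(centers), np.round(d, 4))
    return Axis3D("anatomical", p0, p1)


def estimate_mechanical_axis(
    anatomical: Axis3D,
    angle_deg: float = 5.0,
    side: str = "right",
) -> Axis3D:
    """Estimate the femoral mechanical axis by rotating the anatomical axis
    in the coronal plane.

    The rotation is in the coronal plane — about the component of the AP
    (anterior-posterior) direction orthogonal to the shaft axis, through the
    distal endpoint — by ``angle_deg`` (default 5), with the sign chosen so
    the proximal end moves medially, approximating the femoral head's medial
    position relative to the shaft.  Rotating about an axis perpendicular to
    the shaft direction makes the anatomical-to-mechanical angle exactly
    ``angle_deg``.  Input is assumed in right-knee convention; left knees
    are mirrored on ingest so the sign needs no side handling.
    """
    if not 0.0 <= angle_deg <= 15.0:
        raise ValueError(f"valgus angle must be within [0, 15] degrees, got {angle_deg}")
    if angle_deg == 0.0:
        return Axis3D("mechanical", anatomical.p0, anatomical.p1)
    # distal endpoint = lower projection on the proximal direction
    if anatomical.p0 @ PROXIMAL_DIRECTION <= anatomical.p1 @ PROXIMAL_DIRECTION:
        distal, proximal = anatomical.p0, anatomical.p1
    else:
        distal, proximal = anatomical.p1, anatomical.p0
    d = proximal - distal
    d_hat = d / np.linalg.norm(d)
    rot_axis = ANTERIOR_DIRECTION - (ANTERIOR_DIRECTION @ d_hat) * d_hat
    rot_axis /= np.linalg.norm(rot_axis)
    # choose the sign that tips the proximal end toward -x (medial)
    for sign in (1.0, -1.0):
        R = Rotation.from_rotvec(np.radians(sign * angle_deg) * rot_axis)
        d_rot = R.apply(d)
        if (d_rot - d) @ MEDIAL_DIRECTION >= 0:
            break
    return Axis3D("mechanical", distal, distal + d_rot)


# ---------------------------------------------------------------------------
# cut planes
# ---------------------------------------------------------------------------


def _check_axis_plausible(direction: np.ndarray) -> None:
    ang = np.degrees(np.arccos(np.clip(abs(direction @ PROXIMAL_DIRECTION), 0, 1)))
    if ang > 45.0:
        raise ValueError(f"implausible axis: {ang:.1f} degrees from the longitudinal direction")


def find_distal_medial_condyle_vertex(mesh: TriangleMesh) -> int:
    """Index of the most distal vertex within the medial half and distal
    quarter of the femur's bounding extent."""
    v = mesh.vertices
    zmin, zmax = v[:, 2].min(), v[:, 2].max()
    x_mid = 0.5 * (v[:, 0].min() + v[:, 0].max())
    cand = np.flatnonzero((v[:, 2] <= zmin + 0.25 * (zmax - zmin)) & (v[:, 0] <= x_mid))
    if len(cand) == 0:
        raise ValueError("no vertices in the distal-medial search region")
    return int(cand[np.argmin(v[cand, 2])])


def femoral_cut_plane(
    mechanical: Axis3D,
    mesh: TriangleMesh,
    offset: float = 9.0,
) -> CutPlane:
    """Distal femoral resection plane: perpendicular to the estimated
    mechanical axis, ``offset`` mm proximal to the most distal point of the
    medial condyle."""
    n = mechanical.direction
    if n @ PROXIMAL_DIRECTION < 0:
        n = -n
    _check_axis_plausible(n)
    v_idx = find_distal_medial_condyle_vertex(mesh)
    v = mesh.vertices[v_idx]
    plane = make_plane(v + offset * n, n)
    log.info("femoral cut plane: reference vertex %d at %s, offset %.1f mm",
             v_idx, np.round(v, 2), offset)
    return plane


def find_plateau_center(mesh: TriangleMesh, band: float = 5.0) -> np.ndarray:
    """Centroid of the most proximal ``band`` mm of tibial vertices."""
    v = mesh.vertices
    zmax = v[:, 2].max()
    sel = v[v[:, 2] >= zmax - band]
    return sel.mean(axis=0)


def tibial_cut_plane(
    tibial_axis: Axis3D,
    mesh: TriangleMesh,
    slope_deg: float = 3.0,
    offset: float = 9.0,
) -> CutPlane:
    """Proximal tibial resection plane.

    The plane normal is the tibial shaft axis tilted posteriorly by
    ``slope_deg`` about the medial-lateral direction; the origin sits
    ``offset`` mm distal to the proximal plateau center along that normal.
    """
    n = tibial_axis.direction
    if n @ PROXIMAL_DIRECTION < 0:
        n = -n
    _check_axis_plausible(n)
    if slope_deg != 0.0:
        # posterior tilt about the medial-lateral direction; rotating about
        # the component of +x orthogonal to the axis makes the tilt exact
        ml = np.array([1.0, 0.0, 0.0])
        rot_axis = ml - (ml @ n) * n
        rot_axis /= np.linalg.norm(rot_axis)
        # about +x, +slope tips a proximal-pointing normal toward -y (posterior)
        n = Rotation.from_rotvec(np.radians(slope_deg) * rot_axis).apply(n)
    center = find_plateau_center(mesh)
    plane = make_plane(center - offset * n, n)
    log.info("tibial cut plane: plateau center %s, slope %.1f deg, offset %.1f mm",
             np.round(center, 2), slope_deg, offset)
    return plane


# ---------------------------------------------------------------------------
# contours
# ---------------------------------------------------------------------------


def _resample_closed(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a closed 2D polyline at uniform arc length.

    The output starts at the input point with minimal u (ties broken on v)
    and proceeds counter-clockwise, so resampling is deterministic.
    """
    # enforce counter-clockwise orientation
    x, y = points[:, 0], points[:, 1]
    if 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y) < 0:
        points = points[::-1]
    start = np.lexsort((points[:, 1], points[:, 0]))[0]
    points = np.roll(points, -start, axis=0)
    closed = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    n = max(3, int(round(total / spacing)))
    s = np.linspace(0.0, total, n, endpoint=False)
    u = np.interp(s, arc, closed[:, 0])
    v = np.interp(s, arc, closed[:, 1])
    return np.column_stack([u, v])


def extract_cut_contour(
    mesh: TriangleMesh,
    plane: CutPlane,
    spacing: float = 0.1,
) -> list[Contour2D]:
    """Intersect a mesh with a cutting plane and return its closed
    cross-section contours.

    Triangle-plane segments are chained into closed loops, projected into
    the plane's (u, v) frame, and resampled at uniform arc length
    (``spacing``, default 0.1 mm).  Loops are returned sorted by descending
    enclosed area; degenerate loops (perimeter < 3 * spacing) are dropped.
    """
    sec = mesh.to_trimesh().section(plane_origin=plane.origin, plane_normal=plane.normal)
    if sec is None:
        raise ValueError("plane misses bone: empty mesh-plane intersection")
    contours = []
    for loop3d in sec.discrete:
        loop = loop3d[:-1] if np.allclose(loop3d[0], loop3d[-1]) else loop3d
        if len(loop) < 3:
            continue
        uv = project_to_plane(loop, plane)
        perim = np.linalg.norm(np.diff(np.vstack([uv, uv[:1]]), axis=0), axis=1).sum()
        if perim < 3 * spacing:
            continue
        contours.append(Contour2D(_resample_closed(uv, spacing), spacing, plane))
    if not contours:
        raise ValueError("plane misses bone: intersection is degenerate")
    contours.sort(key=lambda c: abs(c.area), reverse=True)
    log.info("extracted %d contour loop(s); principal area %.2f mm^2",
             len(contours), abs(contours[0].area))
    return contours


def contour_rmse(pred: Contour2D, gt: Contour2D) -> RmseResult:
    """Nearest-point RMSE between two contours in the same plane frame.

    For each point of the predicted contour, the distance to the closest
    point of the ground-truth contour; RMSE is the root mean square of
    those distances.
    """
    if pred.plane is not None and gt.plane is not None and not pred.plane.same_frame(gt.plane):
        raise ValueError("contour frame mismatch: contours come from different cut planes")
    tree = cKDTree(gt.points)
    d, _ = tree.query(pred.points, k=1)
    return RmseResult(
        rmse=float(np.sqrt(np.mean(d**2))),
        n_points=len(d),
        direction="pred_to_gt",
        per_point_distances=d,
    )


def contours_to_csv(contours: list[Contour2D], path) -> None:
    """Export contour loops as CSV (loop_id, point_index, u_mm, v_mm)."""
    import pandas as pd

    rows = []
    for i, c in enumerate(contours):
        for j, (u, v) in enumerate(c.points):
            rows.append((i, j, u, v))
    pd.DataFrame(rows, columns=["loop_id", "point_index", "u_mm", "v_mm"]).to_csv(
        path, index=False
    )
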