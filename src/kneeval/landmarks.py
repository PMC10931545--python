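"""Landmark annotations, consensus regions, and local RMSE.

Eight clinically relevant bony landmark regions are evaluated — five on the
femur (posterior lateral/medial condyle, lateral/medial distal condyle,
anterior cortex) and three on the tibia (lateral/medial plateau,
tuberosity).  Each landmark is annotated as a single 3D point by several
observers, each presented with the model more than once (the study design is
3 observers x 2 repeats = 6 points per landmark per model).  A consensus
region is built by discarding outlier annotations, snapping the inlier
centroid to the mesh surface, and collecting all mesh vertices within a
predefined radius; the local RMSE is then the surface RMSE restricted to
that region's vertices.

The medial and lateral femoral epicondyles are additionally annotated as
endpoints of the trans-epicondylar axis; they participate in axis analysis
but are not region landmarks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .geometry import SOURCES, TriangleMesh
from .registration import RmseResult, rmse_between_meshes

log = logging.getLogger(__name__)

FEMUR_REGION_LANDMARKS = (
    "posterior_lateral_condyle",
    "posterior_medial_condyle",
    "lateral_distal_condyle",
    "medial_distal_condyle",
    "anterior_cortex",
)
TIBIA_REGION_LANDMARKS = (
    "lateral_plateau",
    "medial_plateau",
    "tuberosity",
)
#: axis-endpoint landmarks (femur only): used for the trans-epicondylar axis
FEMUR_AXIS_LANDMARKS = ("lateral_epicondyle", "medial_epicondyle")

LANDMARKS_BY_BONE = {
    "femur": FEMUR_REGION_LANDMARKS + FEMUR_AXIS_LANDMARKS,
    "tibia": TIBIA_REGION_LANDMARKS,
}
REGION_LANDMARKS_BY_BONE = {
    "femur": FEMUR_REGION_LANDMARKS,
    "tibia": TIBIA_REGION_LANDMARKS,
}
ALL_LANDMARKS = LANDMARKS_BY_BONE["femur"] + LANDMARKS_BY_BONE["tibia"]


@dataclass(frozen=True)
class LandmarkAnnotation:
    """One observer's single-repeat 3D point for a named landmark."""

    landmark: str
    observer_id: str
    repeat_index: int
    point: np.ndarray
    model_source: str
    patient_id: str = ""
    bone: str = ""
    side: str = "right"

    def __post_init__(self) -> None:
        if self.landmark not in ALL_LANDMARKS:
            raise ValueError(f"unknown landmark {self.landmark!r}")
        if self.bone and self.landmark not in LANDMARKS_BY_BONE[self.bone]:
            raise ValueError(f"landmark {self.landmark!r} is not valid for bone {self.bone!r}")
        if self.model_source not in SOURCES:
            raise ValueError(f"model_source must be one of {SOURCES}")
        object.__setattr__(self, "point", np.asarray(self.point, dtype=np.float64).reshape(3))
        if not np.isfinite(self.point).all():
            raise ValueError("annotation point is not finite")


@dataclass
class LandmarkRegion:
    """Consensus surface region for one landmark on one mesh."""

    landmark: str
    center: np.ndarray
    radius: float
    inlier_annotations: list[LandmarkAnnotation]
    member_vertices: np.ndarray
    host_mesh: TriangleMesh
    metric: str = "euclidean"
    outliers: list[LandmarkAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=np.float64).reshape(3)
        self.member_vertices = np.asarray(self.member_vertices, dtype=np.int64)


# ---------------------------------------------------------------------------
# outlier rejection and region construction
# ---------------------------------------------------------------------------


def _discard_outliers(points: np.ndarray) -> np.ndarray:
    """Iteratively drop the point farthest from the centroid of the others
    while that distance exceeds ``max(2 mm, 2 x median pairwise distance)``
    of the remaining set.  Never drops below ``max(3, ceil(n/2))`` inliers.
    Returns the boolean inlier mask (order-independent)."""
    n = len(points)
    keep = np.ones(n, dtype=bool)
    min_keep = max(3, int(np.ceil(n / 2)))
    while keep.sum() > min_keep:
        idx = np.flatnonzero(keep)
        pts = points[idx]
        # distance of each point to the centroid of the *other* inliers
        total = pts.sum(axis=0)
        m = len(pts)
        others_centroid = (total[None, :] - pts) / (m - 1)
        d = np.linalg.norm(pts - others_centroid, axis=1)
        pair_d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        med = float(np.median(pair_d[np.triu_indices(m, k=1)]))
        threshold = max(2.0, 2.0 * med)
        worst = int(np.argmax(d))
        # deterministic tie-break: lowest original index among maxima
        if d[worst] > threshold:
            keep[idx[worst]] = False
        else:
            break
    return keep


def build_region(
    annotations: list[LandmarkAnnotation],
    mesh: TriangleMesh,
    radius: float = 5.0,
    metric: str = "euclidean",
) -> LandmarkRegion:
    """Build the consensus region for one landmark from repeated annotations.

    Outlier annotations are discarded (see :func:`_discard_outliers`), the
    inlier centroid is snapped to the nearest mesh vertex, and all mesh
    vertices within ``radius`` mm of that center become region members.
    ``metric`` selects Euclidean (default) or geodesic (edge-graph shortest
    path) membership distance.

    Raises ``ValueError`` with fewer than 3 annotations, on mixed landmarks,
    or when no pair of annotations is mutually closer than ``2 * radius``
    (no consensus).
    """
    if len(annotations) < 3:
        raise ValueError(f"need at least 3 annotations, got {len(annotations)}")
    names = {a.landmark for a in annotations}
    if len(names) != 1:
        raise ValueError(f"annotations mix landmarks: {sorted(names)}")
    sources = {a.model_source for a in annotations}
    if len(sources) != 1:
        raise ValueError("annotations mix model sources")
    pts = np.array([a.point for a in annotations])
    pair_d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    iu = np.triu_indices(len(pts), k=1)
    if pair_d[iu].min() > 2.0 * radius:
        raise ValueError("no consensus region: all annotations mutually farther than 2*radius")

    keep = _discard_outliers(pts)
    inliers = [a for a, k in zip(annotations, keep) if k]
    outliers = [a for a, k in zip(annotations, keep) if not k]
    centroid = pts[keep].mean(axis=0)
    tree = cKDTree(mesh.vertices)
    _, center_idx = tree.query(centroid)
    center = mesh.vertices[center_idx]

    if metric == "euclidean":
        member = np.array(sorted(tree.query_ball_point(center, radius)), dtype=np.int64)
    elif metric == "geodesic":
        member = _geodesic_ball(mesh, int(center_idx), radius)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    region = LandmarkRegion(
        landmark=annotations[0].landmark,
        center=center,
        radius=radius,
        inlier_annotations=inliers,
        member_vertices=member,
        host_mesh=mesh,
        metric=metric,
        outliers=outliers,
    )
    log.info("region %s: %d/%d inliers, %d member vertices (r=%.1f mm, %s)",
             region.landmark, len(inliers), len(annotations), len(member), radius, metric)
    return region


def _geodesic_ball(mesh: TriangleMesh, center_idx: int, radius: float) -> np.ndarray:
    """Vertex indices within geodesic (edge-graph shortest-path) radius."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import dijkstra

    f = mesh.faces
    edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    w = np.linalg.norm(mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1)
    n = mesh.n_vertices
    g = coo_matrix((np.concatenate([w, w]),
                    (np.concatenate([edges[:, 0], edges[:, 1]]),
                     np.concatenate([edges[:, 1], edges[:, 0]]))), shape=(n, n))
    dist = dijkstra(g.tocsr(), directed=False, indices=center_idx, limit=radius)
    return np.flatnonzero(np.isfinite(dist)).astype(np.int64)


def local_rmse(region: LandmarkRegion, gt_mesh: TriangleMesh) -> RmseResult:
    """Surface RMSE restricted to a landmark region.

    The region lives on the (registered) prediction mesh; distances run from
    its member vertices to the nearest ground-truth vertices, mirroring the
    global metric's prediction-side direction.
    """
    if len(region.member_vertices) == 0:
        raise ValueError(f"region {region.landmark!r} has no member vertices")
    sub = TriangleMesh(
        region.host_mesh.vertices[region.member_vertices],
        np.empty((0, 3), dtype=np.int64),
    )
    return rmse_between_meshes(sub, gt_mesh, direction="pred_to_gt")


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------


def save_annotations_json(annotations: list[LandmarkAnnotation], path: str | Path) -> None:
    records = [
        {
            "patient_id": a.patient_id,
            "bone": a.bone,
            "side": a.side,
            "model_source": a.model_source,
            "landmark": a.landmark,
            "observer_id": a.observer_id,
            "repeat_index": a.repeat_index,
            "point_mm": [float(x) for x in a.point],
        }
        for a in annotations
    ]
    Path(path).write_text(json.dumps(records, indent=1))
    log.info("wrote %d annotations to %s", len(records), path)


def load_annotations_json(path: str | Path) -> list[LandmarkAnnotation]:
    """Read the package's annotation JSON schema (a list of records with
    ``patient_id, bone, side, model_source, landmark, observer_id,
    repeat_index, point_mm``)."""
    records = json.loads(Path(path).read_text())
    return [
        LandmarkAnnotation(
            landmark=r["landmark"],
            observer_id=str(r["observer_id"]),
            repeat_index=int(r["repeat_index"]),
            point=r["point_mm"],
            model_source=r["model_source"],
            patient_id=r.get("patient_id", ""),
            bone=r.get("bone", ""),
            side=r.get("side", "right"),
        )
        for r in records
    ]


def load_annotations_mps(
    path: str | Path,
    landmark: str,
    observer_id: str,
    repeat_index: int,
    model_source: str,
    **meta,
) -> list[LandmarkAnnotation]:
    """Read an MITK point-set file (``.mps`` XML) as annotations of a single
    landmark.  MITK stores one ``<point>`` element per annotated point with
    ``<x>/<y>/<z>`` coordinates in mm."""
    import xml.etree.ElementTree as ET

    root = ET.parse(str(path)).getroot()
    out = []
    for pt in root.iter("point"):
        coords = [float(pt.findtext(c)) for c in ("x", "y", "z")]
        out.append(
            LandmarkAnnotation(
                landmark=landmark,
                observer_id=observer_id,
                repeat_index=repeat_index,
                point=coords,
                model_source=model_source,
                **meta,
            )
        )
    if not out:
        raise ValueError(f"no <point> elements found in {path}")
    return out


def group_annotations(
    annotations: list[LandmarkAnnotation],
) -> dict[tuple[str, str], list[LandmarkAnnotation]]:
    """Group annotations by ``(model_source, landmark)``."""
    groups: dict[tuple[str, str], list[LandmarkAnnotation]] = {}
    for a in annotations:
        groups.setdefault((a.model_source, a.landmark), []).append(a)
    return groups
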