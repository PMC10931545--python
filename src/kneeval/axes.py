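"""Anatomical-axis construction, projection, and angular statistics.

Three anatomical axes are analyzed: the trans-epicondylar axis (TEA,
connecting the femoral epicondyles), the posterior condylar axis (PCA,
connecting the posterior condyle points) and the medial-lateral transverse
axis of the tibia (MLTA, connecting the plateau points).  Each observer's
repeat produces one 3D axis per model; axes are projected onto the relevant
resection plane (TEA/PCA onto the femoral cut plane, MLTA onto the tibial
one) and compared as undirected 2D lines.

Two statistics are computed per axis:

* *baseline* — mean/SD of the angles between all C(n, 2) pairs of
  ground-truth (CT-based) annotations: the inter-/intra-observer
  human-level variability (15 pairs for 6 annotations);
* *cross* — mean/SD of the angles between all n x m ground-truth/predicted
  pairs (36 for 6 x 6): the reconstruction's angular deviation, to be read
  against the baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import pandas as pd

from .cuts import Axis3D
from .geometry import CutPlane, project_to_plane
from .landmarks import LandmarkAnnotation, group_annotations

log = logging.getLogger(__name__)

AXIS_2D_NAMES = ("TEA", "PCA", "MLTA")
STATS_KINDS = ("baseline_ct_ct", "cross_ct_xray")

#: landmark pair defining each annotated axis, in (lateral, medial) order
AXIS_LANDMARK_PAIRS = {
    "TEA": ("lateral_epicondyle", "medial_epicondyle"),
    "PCA": ("posterior_lateral_condyle", "posterior_medial_condyle"),
    "MLTA": ("lateral_plateau", "medial_plateau"),
}
#: which bone's resection plane each axis is projected onto
AXIS_PLANE_BONE = {"TEA": "femur", "PCA": "femur", "MLTA": "tibia"}


@dataclass
class Axis2D:
    """An undirected 2D line in a cut plane's (u, v) frame."""

    name: str
    point: np.ndarray
    direction: np.ndarray
    provenance: tuple | None = None
    plane: CutPlane | None = None

    def __post_init__(self) -> None:
        if self.name not in AXIS_2D_NAMES:
            raise ValueError(f"2D axis name must be one of {AXIS_2D_NAMES}")
        self.point = np.asarray(self.point, dtype=np.float64).reshape(2)
        d = np.asarray(self.direction, dtype=np.float64).reshape(2)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise ValueError("2D axis direction has zero length")
        self.direction = d / n


@dataclass
class AngleStats:
    """Mean/SD of pairwise undirected line angles for one axis."""

    axis_name: str
    mean_deg: float
    sd_deg: float
    n_pairs: int
    kind: str
    angles_deg: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in STATS_KINDS:
            raise ValueError(f"kind must be one of {STATS_KINDS}")
        if not 0.0 <= self.mean_deg <= 90.0:
            raise ValueError("mean undirected line angle must lie in [0, 90] degrees")
        if self.angles_deg is not None:
            self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)


# ---------------------------------------------------------------------------
# axis construction and projection
# ---------------------------------------------------------------------------


def build_axis3d(a: LandmarkAnnotation, b: LandmarkAnnotation) -> Axis3D:
    """Build an annotated 3D axis from its two endpoint annotations.

    The pair must belong to the same observer, repeat and model, and must be
    the two landmarks defining one of TEA/PCA/MLTA (either order).
    """
    if (a.observer_id, a.repeat_index, a.model_source) != (
        b.observer_id,
        b.repeat_index,
        b.model_source,
    ):
        raise ValueError("axis endpoints must come from the same observer/repeat/model")
    pair = frozenset((a.landmark, b.landmark))
    for name, lm_pair in AXIS_LANDMARK_PAIRS.items():
        if pair == frozenset(lm_pair):
            return Axis3D(
                name,
                a.point,
                b.point,
                provenance=(a.model_source, a.observer_id, a.repeat_index),
            )
    raise ValueError(f"landmarks {sorted(pair)} do not define a known axis")


def axes_from_annotations(
    annotations: list[LandmarkAnnotation], axis_name: str
) -> list[Axis3D]:
    """Collect all (observer, repeat) instances of one axis from an
    annotation set for a single model."""
    lat_name, med_name = AXIS_LANDMARK_PAIRS[axis_name]
    groups = group_annotations(annotations)
    axes = []
    for (source, landmark), anns in sorted(groups.items()):
        if landmark != lat_name:
            continue
        med = {
            (m.observer_id, m.repeat_index): m
            for m in groups.get((source, med_name), [])
        }
        for a in sorted(anns, key=lambda x: (x.observer_id, x.repeat_index)):
            key = (a.observer_id, a.repeat_index)
            if key in med:
                axes.append(build_axis3d(a, med[key]))
    return axes


def project_axis(axis: Axis3D, plane: CutPlane) -> Axis2D:
    """Project a 3D axis onto a cut plane by projecting its endpoints."""
    p0 = project_to_plane(axis.p0, plane)
    p1 = project_to_plane(axis.p1, plane)
    if np.linalg.norm(p1 - p0) < 1e-6:
        raise ValueError(f"axis {axis.name} degenerate in plane (parallel to normal)")
    name = axis.name if axis.name in AXIS_2D_NAMES else None
    if name is None:
        raise ValueError(f"axis {axis.name!r} has no 2D counterpart")
    return Axis2D(name, p0, p1 - p0, provenance=axis.provenance, plane=plane)


# ---------------------------------------------------------------------------
# angles and statistics
# ---------------------------------------------------------------------------


def angle_between(a: Axis2D, b: Axis2D) -> float:
    """Undirected line angle between two 2D axes, in [0, 90] degrees.

    Symmetric and invariant to flipping either direction.
    """
    if a.plane is not None and b.plane is not None and not a.plane.same_frame(b.plane):
        raise ValueError("axes live in different plane frames")
    # atan2 form: numerically exact near 0 (identical lines give exactly 0)
    dot = float(a.direction @ b.direction)
    cross = float(a.direction[0] * b.direction[1] - a.direction[1] * b.direction[0])
    return float(np.degrees(np.arctan2(abs(cross), abs(dot))))


def _check_unique_provenance(axes: list[Axis2D], expected_source: str | None) -> None:
    seen = set()
    for ax in axes:
        if ax.provenance is None:
            raise ValueError("axis lacks provenance (model_source, observer, repeat)")
        source, obs, rep = ax.provenance
        if expected_source is not None and source != expected_source:
            raise ValueError(f"expected {expected_source} axes, got {source}")
        key = (obs, rep)
        if key in seen:
            raise ValueError(f"duplicate (observer, repeat) entry {key}")
        seen.add(key)


def baseline_stats(ct_axes: list[Axis2D]) -> AngleStats:
    """Inter-/intra-observer baseline: mean/SD of the angles over all
    unordered pairs of ground-truth axis annotations (C(6, 2) = 15 pairs in
    the 3-observer x 2-repeat design)."""
    if len(ct_axes) < 2:
        raise ValueError("need at least 2 annotations for baseline statistics")
    names = {ax.name for ax in ct_axes}
    if len(names) != 1:
        raise ValueError(f"axes mix names: {sorted(names)}")
    _check_unique_provenance(ct_axes, "ground_truth")
    angles = np.array([angle_between(a, b) for a, b in combinations(ct_axes, 2)])
    return AngleStats(
        axis_name=ct_axes[0].name,
        mean_deg=float(angles.mean()),
        sd_deg=float(angles.std(ddof=1)) if len(angles) > 1 else 0.0,
        n_pairs=len(angles),
        kind="baseline_ct_ct",
        angles_deg=angles,
    )


def cross_stats(ct_axes: list[Axis2D], xray_axes: list[Axis2D]) -> AngleStats:
    """Cross-modality deviation: mean/SD of the angles over all ground-truth
    x predicted axis pairs (6 x 6 = 36 in the study design)."""
    if not ct_axes or not xray_axes:
        raise ValueError("need annotations on both models for cross statistics")
    names = {ax.name for ax in ct_axes} | {ax.name for ax in xray_axes}
    if len(names) != 1:
        raise ValueError(f"axes mix names: {sorted(names)}")
    _check_unique_provenance(ct_axes, "ground_truth")
    _check_unique_provenance(xray_axes, "prediction")
    angles = np.array([angle_between(a, b) for a, b in product(ct_axes, xray_axes)])
    return AngleStats(
        axis_name=ct_axes[0].name,
        mean_deg=float(angles.mean()),
        sd_deg=float(angles.std(ddof=1)) if len(angles) > 1 else 0.0,
        n_pairs=len(angles),
        kind="cross_ct_xray",
        angles_deg=angles,
    )


def study_axis_report(stats: list[AngleStats], pool: bool = True) -> pd.DataFrame:
    """Aggregate per-bone angle statistics into a study-level table.

    One row per axis with baseline and cross-modality mean/SD.  With
    ``pool=True`` (default) the raw pairwise angles of all bones are pooled
    before taking mean/SD; otherwise per-bone means are averaged.
    """
    rows = []
    for axis_name in AXIS_2D_NAMES:
        row: dict = {"axis": axis_name}
        for kind, prefix in (("baseline_ct_ct", "baseline"), ("cross_ct_xray", "cross")):
            sel = [s for s in stats if s.axis_name == axis_name and s.kind == kind]
            if not sel:
                continue
            if pool:
                if any(s.angles_deg is None for s in sel):
                    raise ValueError("pooling requires AngleStats with raw angles attached")
                angles = np.concatenate([s.angles_deg for s in sel])
                row[f"{prefix}_mean"] = float(angles.mean())
                row[f"{prefix}_sd"] = float(angles.std(ddof=1)) if len(angles) > 1 else 0.0
                row[f"{prefix}_n_pairs"] = int(len(angles))
            else:
                means = np.array([s.mean_deg for s in sel])
                row[f"{prefix}_mean"] = float(means.mean())
                row[f"{prefix}_sd"] = float(means.std(ddof=1)) if len(means) > 1 else 0.0
                row[f"{prefix}_n_pairs"] = int(sum(s.n_pairs for s in sel))
        if len(row) > 1:
            rows.append(row)
    return pd.DataFrame(rows)
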