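"""Core geometric types and conversions.

Coordinate convention
---------------------
All meshes and masks live in a right-handed patient frame in millimetres:

* ``+x`` — patient left→right (lateral for a right knee),
* ``+y`` — posterior→anterior,
* ``+z`` — distal→proximal.

Left knees are mirrored into this right-knee convention on ingest (the
``mirrored`` flag on :class:`BoneModel` records this), so "medial" is always
the ``-x`` direction internally.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import trimesh as _trimesh
from scipy import ndimage
from skimage import measure

log = logging.getLogger(__name__)

FEMUR = "femur"
TIBIA = "tibia"
BONES = (FEMUR, TIBIA)
SIDES = ("right", "left")
SOURCES = ("prediction", "ground_truth")

#: unit medial direction in the internal right-knee frame
MEDIAL_DIRECTION = np.array([-1.0, 0.0, 0.0])
#: unit anterior direction
ANTERIOR_DIRECTION = np.array([0.0, 1.0, 0.0])
#: unit proximal direction
PROXIMAL_DIRECTION = np.array([0.0, 0.0, 1.0])


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class TriangleMesh:
    """A closed triangle surface mesh in millimetres.

    ``vertices`` is an ``(n, 3)`` float array, ``faces`` an ``(m, 3)`` integer
    array of vertex indices.  Faces must reference existing vertices and carry
    three distinct indices; vertex coordinates must be finite.
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_normals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.isfinite(self.vertices).all():
            raise ValueError("mesh vertices contain non-finite coordinates")
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("face index out of range")
            f = self.faces
            if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
                raise ValueError("degenerate face (repeated vertex index)")
        if self.vertex_normals is not None:
            self.vertex_normals = np.asarray(self.vertex_normals, dtype=np.float64).reshape(-1, 3)

    # -- interop ------------------------------------------------------------
    @classmethod
    def from_trimesh(cls, tm: _trimesh.Trimesh) -> "TriangleMesh":
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces))

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    # -- geometry helpers ---------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def bounds(self) -> np.ndarray:
        """``(2, 3)`` min/max corner of the axis-aligned bounding box."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def compute_vertex_normals(self) -> np.ndarray:
        """Area-weighted outward vertex normals (cached on the instance)."""
        if self.vertex_normals is None:
            self.vertex_normals = np.asarray(self.to_trimesh().vertex_normals, dtype=np.float64)
        return self.vertex_normals

    def transformed(self, transform: "RigidTransform") -> "TriangleMesh":
        return TriangleMesh(transform.apply(self.vertices), self.faces.copy())

    def mirrored_x(self) -> "TriangleMesh":
        """Mirror through the x = 0 plane, flipping face winding to keep
        outward orientation."""
        v = self.vertices.copy()
        v[:, 0] *= -1.0
        return TriangleMesh(v, self.faces[:, ::-1].copy())


@dataclass
class VolumetricMask:
    """A binary voxel grid with physical geometry.

    ``grid[i, j, k]`` is foreground/background; ``spacing`` is the per-axis
    voxel size in mm, ``origin`` the physical position of voxel (0, 0, 0) and
    ``direction`` a 3x3 matrix mapping grid axes to patient axes.
    """

    grid: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)
        if self.grid.ndim != 3:
            raise ValueError("mask grid must be 3-dimensional")
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        if np.any(self.spacing <= 0) or not np.isfinite(self.spacing).all():
            raise ValueError(f"voxel spacing must be positive and finite, got {self.spacing}")
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.direction = np.asarray(self.direction, dtype=np.float64).reshape(3, 3)

    @property
    def n_foreground(self) -> int:
        return int(self.grid.sum())


@dataclass(frozen=True)
class BoneModel:
    """A bone surface mesh plus its identity within a patient dataset."""

    mesh: TriangleMesh
    bone: str
    side: str
    source: str
    patient_id: str
    mirrored: bool = False

    def __post_init__(self) -> None:
        if self.bone not in BONES:
            raise ValueError(f"bone must be one of {BONES}, got {self.bone!r}")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}, got {self.source!r}")

    def with_mesh(self, mesh: TriangleMesh) -> "BoneModel":
        return replace(self, mesh=mesh)


def mirror_to_right(model: BoneModel) -> BoneModel:
    """Mirror a left-side model into the right-knee convention.

    Right-side models pass through unchanged.  The returned model keeps
    ``side`` but sets ``mirrored`` so reports can recover the original
    handedness.
    """
    if model.side == "right":
        return model
    return replace(model, mesh=model.mesh.mirrored_x(), mirrored=True)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``p -> R p + t`` (rotation + translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation matrix determinant must be +1 (no reflection)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first,
        then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m


@dataclass(frozen=True)
class CutPlane:
    """An oriented plane with an in-plane 2D basis.

    ``{u_axis, v_axis, normal}`` form a right-handed orthonormal triad;
    2D plane coordinates of a point ``p`` are
    ``(dot(p - origin, u_axis), dot(p - origin, v_axis))``.
    """

    origin: np.ndarray
    normal: np.ndarray
    u_axis: np.ndarray
    v_axis: np.ndarray

    def __post_init__(self) -> None:
        for name in ("origin", "normal", "u_axis", "v_axis"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.float64).reshape(3))
        n, u, v = self.normal, self.u_axis, self.v_axis
        for vec, name in ((n, "normal"), (u, "u_axis"), (v, "v_axis")):
            if abs(np.linalg.norm(vec) - 1.0) > 1e-10:
                raise ValueError(f"{name} is not unit length")
        if max(abs(n @ u), abs(n @ v), abs(u @ v)) > 1e-10:
            raise ValueError("plane basis is not orthogonal")
        if np.linalg.norm(np.cross(u, v) - n) > 1e-8:
            raise ValueError("plane basis is not right-handed (u x v != normal)")

    def same_frame(self, other: "CutPlane", atol: float = 1e-9) -> bool:
        return (
            np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.normal, other.normal, atol=atol)
            and np.allclose(self.u_axis, other.u_axis, atol=atol)
        )


# ---------------------------------------------------------------------------
# mask I/O
# ---------------------------------------------------------------------------


def load_mask(path: str | Path) -> VolumetricMask:
    """Read a binary segmentation mask from NIfTI (``.nii``/``.nii.gz``)
    or NRRD (``.nrrd``/``.nhdr``).

    Voxel spacing, origin and axis orientation are taken from the file
    header; nonzero voxels become foreground.  Files without valid spacing
    information are rejected rather than assumed isotropic.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"mask file not found: {path}")
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        try:
            img = nib.load(str(path))
        except Exception as exc:  # pragma: no cover - nibabel error classes vary
            raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
        data = np.asanyarray(img.dataobj)
        affine = np.asarray(img.affine, dtype=np.float64)
        spacing = np.linalg.norm(affine[:3, :3], axis=0)
        if np.any(spacing <= 0) or not np.isfinite(spacing).all():
            raise ValueError(f"NIfTI header of {path} lacks valid voxel spacing: {spacing}")
        direction = affine[:3, :3] / spacing
        origin = affine[:3, 3]
    elif name.endswith((".nrrd", ".nhdr")):
        import SimpleITK as sitk

        try:
            img = sitk.ReadImage(str(path))
        except Exception as exc:
            raise IOError(f"cannot read NRRD file {path}: {exc}") from exc
        data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
        spacing = np.asarray(img.GetSpacing(), dtype=np.float64)
        if np.any(spacing <= 0):
            raise ValueError(f"NRRD header of {path} lacks valid voxel spacing: {spacing}")
        origin = np.asarray(img.GetOrigin(), dtype=np.float64)
        direction = np.asarray(img.GetDirection(), dtype=np.float64).reshape(3, 3)
    else:
        raise IOError(f"unrecognized mask format: {path} (expected .nii/.nii.gz/.nrrd/.nhdr)")
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    mask = VolumetricMask(grid=data != 0, spacing=spacing, origin=origin, direction=direction)
    log.info("loaded mask %s: shape=%s spacing=%s foreground=%d",
             path, mask.grid.shape, tuple(np.round(mask.spacing, 4)), mask.n_foreground)
    return mask


def save_mask_nifti(mask: VolumetricMask, path: str | Path) -> None:
    """Write a mask as NIfTI, preserving spacing/origin/direction."""
    import nibabel as nib

    affine = np.eye(4)
    affine[:3, :3] = mask.direction * mask.spacing
    affine[:3, 3] = mask.origin
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), affine)
    nib.save(img, str(path))
    log.info("wrote mask %s: foreground=%d", path, mask.n_foreground)


# ---------------------------------------------------------------------------
# mask -> mesh
# ---------------------------------------------------------------------------


def mask_to_mesh(
    mask: VolumetricMask,
    iso_level: float = 0.5,
    smooth_sigma_vox: float = 1.0,
) -> TriangleMesh:
    """Convert a binary mask to a closed surface mesh via marching cubes.

    The binarized grid is anti-aliased with a small Gaussian filter
    (``smooth_sigma_vox`` voxels, default 1.0) before extracting the
    ``iso_level`` surface; this removes the voxel staircase so that surface
    area and enclosed volume of smooth objects are recovered to well under
    1% at adequate resolution.  Set ``smooth_sigma_vox=0`` for the raw
    binary iso-surface.  If the filtered field never reaches ``iso_level``
    (possible for structures only a couple of voxels across), the raw
    binary grid is used so small masks still produce a closed mesh.

    Output vertices are in physical mm (spacing, direction and origin
    applied).
    """
    if mask.n_foreground == 0:
        raise ValueError("empty segmentation: mask has no foreground voxels")
    # pad with background so the iso-surface closes at the volume boundary
    pad = max(2, int(np.ceil(3 * smooth_sigma_vox)))
    grid = np.pad(mask.grid, pad).astype(np.float32)
    if smooth_sigma_vox > 0:
        field_ = ndimage.gaussian_filter(grid, smooth_sigma_vox)
        if field_.max() <= iso_level:
            field_ = grid  # tiny structure: fall back to the raw binary field
    else:
        field_ = grid
    verts, faces, _, _ = measure.marching_cubes(
        field_, level=iso_level, spacing=tuple(mask.spacing)
    )
    verts = verts - pad * mask.spacing  # undo padding offset (index space)
    verts = verts @ mask.direction.T + mask.origin
    mesh = TriangleMesh(verts, faces)
    log.info("mask_to_mesh: %d foreground voxels -> %d vertices, %d faces",
             mask.n_foreground, mesh.n_vertices, len(mesh.faces))
    return mesh


# ---------------------------------------------------------------------------
# STL I/O
# ---------------------------------------------------------------------------


def _dedup_vertices(vertices: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministically merge exactly-coincident vertices and drop the
    degenerate faces this may create."""
    uniq, inverse = np.unique(vertices, axis=0, return_inverse=True)
    faces = inverse[faces]
    ok = (faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2]) & (faces[:, 0] != faces[:, 2])
    return uniq, faces[ok]


def read_stl(path: str | Path) -> TriangleMesh:
    """Read an STL file (binary or ASCII).

    STL stores one vertex triple per facet; coincident vertices are merged
    deterministically (lexicographic coordinate order) on load.  Malformed
    binary files are rejected with the byte offset at which the file is
    truncated.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"STL file not found: {path}")
    raw = path.read_bytes()
    if len(raw) >= 84 and not raw.lstrip()[:5].lower().startswith(b"solid"):
        # binary STL: validate declared triangle count against the file size
        (n_tri,) = struct.unpack("<I", raw[80:84])
        expected = 84 + 50 * n_tri
        if len(raw) < expected:
            raise ValueError(
                f"malformed binary STL {path}: header declares {n_tri} facets "
                f"({expected} bytes) but file ends at byte {len(raw)}"
            )
    elif len(raw) < 84 and not raw.lstrip()[:5].lower().startswith(b"solid"):
        raise ValueError(f"malformed STL {path}: file ends at byte {len(raw)}, no header")
    try:
        tm = _trimesh.load(str(path), file_type="stl", process=False)
    except Exception as exc:
        raise ValueError(f"malformed STL {path}: {exc}") from exc
    if not isinstance(tm, _trimesh.Trimesh) or len(tm.faces) == 0:
        raise ValueError(f"malformed STL {path}: no facets parsed")
    verts, faces = _dedup_vertices(np.asarray(tm.vertices, dtype=np.float64), np.asarray(tm.faces))
    mesh = TriangleMesh(verts, faces)
    log.info("read STL %s: %d vertices, %d faces", path, mesh.n_vertices, len(mesh.faces))
    return mesh


def write_stl(mesh: TriangleMesh, path: str | Path, binary: bool = True) -> None:
    """Write a mesh as STL; binary by default, ASCII with ``binary=False``."""
    path = Path(path)
    tm = mesh.to_trimesh()
    data = tm.export(file_type="stl" if binary else "stl_ascii")
    if isinstance(data, str):
        data = data.encode()
    path.write_bytes(data)
    log.info("wrote STL %s: %d vertices, %d faces (%s)",
             path, mesh.n_vertices, len(mesh.faces), "binary" if binary else "ascii")


# ---------------------------------------------------------------------------
# planes and projection
# ---------------------------------------------------------------------------


def make_plane(origin: Sequence[float], normal: Sequence[float]) -> CutPlane:
    """Construct a :class:`CutPlane` with a deterministic in-plane basis.

    ``u_axis`` is the component of a fixed reference direction (``+z``, or
    ``+y`` when the normal is within ~25 degrees of ``+z``) orthogonal to the
    normal; ``v_axis = normal x u_axis`` completes the right-handed triad.
    """
    origin = np.asarray(origin, dtype=np.float64).reshape(3)
    normal = np.asarray(normal, dtype=np.float64).reshape(3)
    nrm = np.linalg.norm(normal)
    if nrm < 1e-12:
        raise ValueError("plane normal has zero length")
    n = normal / nrm
    ref = np.array([0.0, 0.0, 1.0])
    if abs(n @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - (ref @ n) * n
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    v /= np.linalg.norm(v)
    return CutPlane(origin=origin, normal=n, u_axis=u, v_axis=v)


def project_to_plane(points: np.ndarray, plane: CutPlane) -> np.ndarray:
    """Orthogonally project 3D points into the plane's 2D (u, v) coordinates.

    Accepts a single point ``(3,)`` or an array ``(n, 3)``; returns ``(2,)``
    or ``(n, 2)`` accordingly.  The projection is an isometry for in-plane
    point sets and never increases pairwise distances.
    """
    pts = np.asarray(points, dtype=np.float64)
    single = pts.ndim == 1
    rel = pts.reshape(-1, 3) - plane.origin
    uv = np.column_stack([rel @ plane.u_axis, rel @ plane.v_axis])
    return uv[0] if single else uv


def signed_distance_to_plane(points: np.ndarray, plane: CutPlane) -> np.ndarray:
    """Signed normal distance of points from the plane (positive along
    the normal)."""
    pts = np.asarray(points, dtype=np.float64)
    single = pts.ndim == 1
    d = (pts.reshape(-1, 3) - plane.origin) @ plane.normal
    return d[0] if single else d
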