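"""Synthetic bone models, perturbations, and observer annotations.

Real patient meshes cannot be redistributed, so every pipeline stage is
exercised on stylized bone geometry with exactly known ground truth:

* a *femur* is the union of a shaft cylinder, two posterior-distal condylar
  spheres (the medial one slightly larger and more distal, as in anatomy)
  and an anterior trochlear lobe;
* a *tibia* is a shaft cylinder topped by a flattened plateau ellipsoid with
  an anterior tuberosity bump.

Shapes are defined as analytic signed-distance unions and meshed with
marching cubes, so landmark coordinates (condyle extrema, plateau points,
epicondyles, ...) are known in closed form.  A perturbed copy — a smooth
random normal-offset field of controlled RMS plus a rigid misalignment —
stands in for an X-ray-based reconstruction whose error structure the
validation pipeline must recover.  Simulated observers annotate landmarks
with a per-observer bias and per-repeat noise, mirroring a 3-observer x
2-repeat annotation protocol.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from skimage import measure

from .geometry import (
    BoneModel,
    RigidTransform,
    TriangleMesh,
    VolumetricMask,
    save_mask_nifti,
    write_stl,
)
from .landmarks import LANDMARKS_BY_BONE, LandmarkAnnotation, save_annotations_json

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass
class SyntheticBoneSpec:
    """Parameters of one stylized bone.

    ``lobe_radii`` means, for the femur, (lateral condyle, medial condyle,
    trochlear lobe) radii; for the tibia, the plateau ellipsoid semi-axes
    (medial-lateral, antero-posterior, proximal-distal).  ``mesh_density``
    is the marching-cubes voxel size, i.e. the target mesh edge length.
    """

    bone: str = "femur"
    side: str = "right"
    shaft_length: float = 130.0
    shaft_radius: float = 15.0
    lobe_radii: tuple[float, float, float] = (21.0, 23.0, 14.0)
    mesh_density: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shaft_length <= 0 or self.shaft_radius <= 0 or min(self.lobe_radii) <= 0:
            raise ValueError("all bone dimensions must be positive")
        if self.mesh_density > self.shaft_radius / 5.0:
            raise ValueError(
                f"mesh_density {self.mesh_density} too coarse for shaft radius "
                f"{self.shaft_radius} (need <= radius/5)"
            )

    @classmethod
    def femur(cls, **kw) -> "SyntheticBoneSpec":
        return cls(bone="femur", **kw)

    @classmethod
    def tibia(cls, **kw) -> "SyntheticBoneSpec":
        kw.setdefault("shaft_length", 110.0)
        kw.setdefault("shaft_radius", 12.0)
        kw.setdefault("lobe_radii", (30.0, 22.0, 9.0))
        return cls(bone="tibia", **kw)


@dataclass
class PerturbationSpec:
    """Reconstruction-error model applied to a ground-truth bone: a smooth
    random offset field along the surface normals (``offset_rms`` mm RMS,
    correlation length ``offset_correlation_length`` mm) followed by a rigid
    misalignment."""

    rigid: RigidTransform = field(default_factory=RigidTransform.identity)
    offset_rms: float = 0.9
    offset_correlation_length: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.offset_rms < 0:
            raise ValueError("offset_rms must be nonnegative")


@dataclass
class AnnotationNoiseSpec:
    """Observer model: each observer holds a fixed per-landmark bias
    (``observer_bias_sd`` mm per component) and adds fresh per-repeat noise
    (``repeat_sd`` mm per component).  Defaults mirror a 3-observer,
    2-repeat protocol with ~1 mm intra-observer repeatability."""

    n_observers: int = 3
    n_repeats: int = 2
    observer_bias_sd: float = 1.0
    repeat_sd: float = 1.0
    seed: int = 0


# ---------------------------------------------------------------------------
# signed-distance primitives
# ---------------------------------------------------------------------------


def _sd_sphere(p: np.ndarray, center, radius: float) -> np.ndarray:
    return np.linalg.norm(p - np.asarray(center), axis=-1) - radius


def _sd_capped_cylinder(p: np.ndarray, z0: float, z1: float, radius: float) -> np.ndarray:
    d_xy = np.hypot(p[..., 0], p[..., 1]) - radius
    d_z = np.maximum(z0 - p[..., 2], p[..., 2] - z1)
    inner = np.minimum(np.maximum(d_xy, d_z), 0.0)
    outer = np.hypot(np.maximum(d_xy, 0.0), np.maximum(d_z, 0.0))
    return inner + outer


def _sd_ellipsoid(p: np.ndarray, center, radii) -> np.ndarray:
    # standard bound-preserving approximation; adequate for iso-surfacing
    q = (p - np.asarray(center)) / np.asarray(radii)
    k0 = np.linalg.norm(q, axis=-1)
    k1 = np.linalg.norm(q / np.asarray(radii), axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(k1 > 0, k0 * (k0 - 1.0) / np.maximum(k1, 1e-30), -np.min(radii))
    return d


def _femur_geometry(spec: SyntheticBoneSpec):
    sr, L = spec.shaft_radius, spec.shaft_length
    r_lat, r_med, r_tro = spec.lobe_radii
    c_lat = np.array([20.0, -4.0, 21.0])
    c_med = np.array([-20.0, -4.0, 20.0])
    c_tro = np.array([0.0, 10.0, 30.0])

    def sdf(p):
        return np.minimum.reduce(
            [
                _sd_capped_cylinder(p, 20.0, L, sr),
                _sd_sphere(p, c_lat, r_lat),
                _sd_sphere(p, c_med, r_med),
                _sd_sphere(p, c_tro, r_tro),
            ]
        )

    landmarks = {
        "posterior_lateral_condyle": c_lat + [0, -r_lat, 0],
        "posterior_medial_condyle": c_med + [0, -r_med, 0],
        "lateral_distal_condyle": c_lat + [0, 0, -r_lat],
        "medial_distal_condyle": c_med + [0, 0, -r_med],
        "anterior_cortex": np.array([0.0, sr, 0.55 * L]),
        "lateral_epicondyle": c_lat + [r_lat, 0, 0],
        "medial_epicondyle": c_med + [-r_med, 0, 0],
    }
    lo = np.array([c_med[0] - r_med, c_med[1] - r_med, c_med[2] - r_med])
    hi = np.array([c_lat[0] + r_lat, max(sr, c_tro[1] + r_tro), L])
    return sdf, landmarks, (lo, hi)


def _tibia_geometry(spec: SyntheticBoneSpec):
    sr, L = spec.shaft_radius, spec.shaft_length
    a, b, c = spec.lobe_radii
    zc = L - 8.0
    c_pla = np.array([0.0, 0.0, zc])
    c_tub = np.array([3.0, 14.0, L - 32.0])
    r_tub = 7.0

    def sdf(p):
        return np.minimum.reduce(
            [
                _sd_capped_cylinder(p, 0.0, L - 10.0, sr),
                _sd_ellipsoid(p, c_pla, (a, b, c)),
                _sd_sphere(p, c_tub, r_tub),
            ]
        )

    landmarks = {
        "lateral_plateau": np.array([0.8 * a, 0.0, zc + 0.6 * c]),
        "medial_plateau": np.array([-0.8 * a, 0.0, zc + 0.6 * c]),
        "tuberosity": c_tub + [0, r_tub, 0],
    }
    lo = np.array([-a, -b, 0.0])
    hi = np.array([a, max(sr, c_tub[1] + r_tub), zc + c])
    return sdf, landmarks, (lo, hi)


def _bone_geometry(spec: SyntheticBoneSpec):
    if spec.bone == "femur":
        return _femur_geometry(spec)
    if spec.bone == "tibia":
        return _tibia_geometry(spec)
    raise ValueError(f"unknown bone {spec.bone!r}")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_bone(
    spec: SyntheticBoneSpec, patient_id: str = "synthetic"
) -> tuple[BoneModel, dict[str, np.ndarray]]:
    """Generate a ground-truth bone model plus its exact landmark map.

    The analytic signed-distance field is sampled on a ``mesh_density``-
    spaced grid and iso-surfaced at level 0, producing a closed genus-0 mesh
    whose every landmark lies on the analytic surface (within one mesh edge
    of a vertex).  Deterministic: the same spec always yields the identical
    mesh.  Left-side bones are generated in right-knee convention and
    mirrored in x (with their landmarks).
    """
    sdf, landmarks, (lo, hi) = _bone_geometry(spec)
    h = spec.mesh_density
    margin = 3 * h
    lo, hi = lo - margin, hi + margin
    nx, ny, nz = (np.ceil((hi - lo) / h).astype(int) + 1)
    xs = lo[0] + h * np.arange(nx)
    ys = lo[1] + h * np.arange(ny)
    zs = lo[2] + h * np.arange(nz)
    grid = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
    values = sdf(grid).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(values, level=0.0, spacing=(h, h, h))
    verts = verts + lo
    mesh = TriangleMesh(verts, faces)
    landmarks = {k: np.asarray(v, dtype=np.float64) for k, v in landmarks.items()}
    if spec.side == "left":
        mesh = mesh.mirrored_x()
        landmarks = {k: v * np.array([-1.0, 1.0, 1.0]) for k, v in landmarks.items()}
    model = BoneModel(
        mesh=mesh, bone=spec.bone, side=spec.side, source="ground_truth", patient_id=patient_id
    )
    log.info("generated %s (%s): %d vertices, %d faces",
             spec.bone, spec.side, mesh.n_vertices, len(mesh.faces))
    return model, landmarks


def voxelize_bone(spec: SyntheticBoneSpec, spacing: float = 1.0) -> VolumetricMask:
    """Binary voxelization of the analytic bone (the 'CT segmentation' of
    the synthetic world), on an isotropic grid of the given spacing."""
    sdf, _, (lo, hi) = _bone_geometry(spec)
    margin = 3 * spacing
    lo, hi = lo - margin, hi + margin
    n = np.ceil((hi - lo) / spacing).astype(int) + 1
    xs = lo[0] + spacing * np.arange(n[0])
    ys = lo[1] + spacing * np.arange(n[1])
    zs = lo[2] + spacing * np.arange(n[2])
    grid = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
    inside = sdf(grid) <= 0.0
    origin = lo.copy()
    direction = np.eye(3)
    if spec.side == "left":
        inside = inside[::-1, :, :].copy()
        origin = lo.copy()
        origin[0] = -(lo[0] + spacing * (n[0] - 1))
    return VolumetricMask(grid=inside, spacing=np.full(3, spacing), origin=origin,
                          direction=direction)


# ---------------------------------------------------------------------------
# perturbation
# ---------------------------------------------------------------------------


def _smooth_field(points: np.ndarray, correlation_length: float, rng: np.random.Generator,
                  n_waves: int = 48) -> np.ndarray:
    """Smooth scalar field as a truncated random plane-wave expansion with
    wavelengths around ``correlation_length``; unit-RMS normalized."""
    dirs = rng.normal(size=(n_waves, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    wavelengths = correlation_length * rng.uniform(0.7, 1.4, size=n_waves)
    k = 2.0 * np.pi / wavelengths
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_waves)
    amps = rng.normal(size=n_waves)
    f = np.zeros(len(points))
    for i in range(n_waves):
        f += amps[i] * np.cos(k[i] * points @ dirs[i] + phases[i])
    rms = np.sqrt(np.mean(f**2))
    return f / rms if rms > 0 else f


def perturb(gt: BoneModel, p: PerturbationSpec) -> BoneModel:
    """Create the synthetic 'reconstruction' of a ground-truth bone.

    Vertices are displaced along their outward normals by a smooth random
    field whose realized RMS equals ``offset_rms`` exactly (the field is
    rescaled after sampling), then the rigid misalignment is applied.  With
    ``offset_rms=0`` and an identity transform the prediction equals the
    ground truth.
    """
    mesh = gt.mesh
    # correlation length must stay well above the mesh edge length
    edges = mesh.faces[:, [0, 1]]
    med_edge = float(np.median(np.linalg.norm(
        mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1)))
    if p.offset_rms > 0 and p.offset_correlation_length < 2.0 * med_edge:
        raise ValueError(
            f"offset correlation length {p.offset_correlation_length} mm below twice "
            f"the mesh edge length ({med_edge:.2f} mm)"
        )
    verts = mesh.vertices.copy()
    if p.offset_rms > 0:
        rng = np.random.default_rng(p.seed)
        offsets = p.offset_rms * _smooth_field(verts, p.offset_correlation_length, rng)
        normals = mesh.compute_vertex_normals()
        verts = verts + offsets[:, None] * normals
    verts = p.rigid.apply(verts)
    pred_mesh = TriangleMesh(verts, mesh.faces.copy())
    return BoneModel(
        mesh=pred_mesh,
        bone=gt.bone,
        side=gt.side,
        source="prediction",
        patient_id=gt.patient_id,
        mirrored=gt.mirrored,
    )


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


def simulate_annotations(
    landmark_truth: dict[str, np.ndarray],
    mesh: TriangleMesh,
    noise: AnnotationNoiseSpec,
    model_source: str,
    patient_id: str = "",
    bone: str = "",
    side: str = "right",
) -> list[LandmarkAnnotation]:
    """Simulate repeated observer annotations of every landmark.

    Each observer carries a fixed bias vector per landmark (systematic
    disagreement about where the landmark is) plus independent per-repeat
    noise; every annotated point is snapped to the nearest mesh vertex, as a
    human annotator clicking on a rendered surface would be.  Produces
    exactly ``n_observers * n_repeats`` annotations per landmark.
    """
    rng = np.random.default_rng(noise.seed)
    tree = cKDTree(mesh.vertices)
    out: list[LandmarkAnnotation] = []
    for lm_name in sorted(landmark_truth):
        truth = np.asarray(landmark_truth[lm_name], dtype=np.float64)
        for obs in range(noise.n_observers):
            bias = rng.normal(0.0, noise.observer_bias_sd, size=3) if noise.observer_bias_sd > 0 \
                else np.zeros(3)
            for rep in range(1, noise.n_repeats + 1):
                jitter = rng.normal(0.0, noise.repeat_sd, size=3) if noise.repeat_sd > 0 \
                    else np.zeros(3)
                raw = truth + bias + jitter
                _, idx = tree.query(raw)
                out.append(
                    LandmarkAnnotation(
                        landmark=lm_name,
                        observer_id=f"obs{obs + 1}",
                        repeat_index=rep,
                        point=mesh.vertices[idx],
                        model_source=model_source,
                        patient_id=patient_id,
                        bone=bone,
                        side=side,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# cohort fixture generation
# ---------------------------------------------------------------------------


def _random_rigid(rng: np.random.Generator, max_angle_deg: float = 5.0,
                  max_translation: float = 5.0) -> RigidTransform:
    from scipy.spatial.transform import Rotation

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(-max_angle_deg, max_angle_deg))
    R = Rotation.from_rotvec(angle * axis).as_matrix()
    t = rng.uniform(-max_translation, max_translation, size=3)
    return RigidTransform(R, t)


def make_cohort(
    out_dir: str | Path,
    n_patients: int = 18,
    seed: int = 0,
    mesh_density: float = 1.5,
    voxel_spacing: float = 1.0,
    femur_offset_rms: float = 0.93,
    tibia_offset_rms: float = 0.88,
    noise: AnnotationNoiseSpec | None = None,
    overwrite: bool = False,
    write_masks: bool = True,
) -> dict:
    """Write a full synthetic validation cohort to disk.

    Per patient: ground-truth and perturbed STL meshes for femur and tibia,
    a NIfTI voxelization of each ground truth, observer annotations for both
    models, and a manifest recording every true parameter (offset RMS, rigid
    misalignment, bone dimensions, child seeds) for recovery tests.  Bone
    dimensions vary a few percent across patients and per-bone offset RMS is
    drawn around the requested scale, emulating an 18-patient cohort whose
    reconstruction errors average ~0.9 mm.

    Deterministic for a fixed master seed.  Refuses to write into an
    existing non-empty directory unless ``overwrite`` is set.
    """
    if n_patients < 1:
        raise ValueError("need at least one patient")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {out_dir} is not empty (use overwrite)")
    out_dir.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_patients)
    noise = noise or AnnotationNoiseSpec()
    manifest: dict = {"master_seed": seed, "n_patients": n_patients, "patients": {}}

    for i, child in enumerate(children):
        pid = f"patient_{i + 1:02d}"
        rng = np.random.default_rng(child)
        side = "right" if rng.uniform() < 11.0 / 18.0 else "left"
        pdir = out_dir / pid
        pdir.mkdir(exist_ok=True)
        entry: dict = {"side": side, "bones": {}}

        annotations = []
        for bone, base_rms in (("femur", femur_offset_rms), ("tibia", tibia_offset_rms)):
            scale = 1.0 + rng.uniform(-0.05, 0.05)
            if bone == "femur":
                spec = SyntheticBoneSpec.femur(
                    side=side,
                    shaft_length=130.0 * scale,
                    shaft_radius=15.0 * scale,
                    lobe_radii=(21.0 * scale, 23.0 * scale, 14.0 * scale),
                    mesh_density=mesh_density,
                )
            else:
                spec = SyntheticBoneSpec.tibia(
                    side=side,
                    shaft_length=110.0 * scale,
                    shaft_radius=12.0 * scale,
                    lobe_radii=(30.0 * scale, 22.0 * scale, 9.0 * scale),
                    mesh_density=mesh_density,
                )
            offset_rms = float(base_rms * rng.uniform(0.7, 1.3))
            pert_seed = int(rng.integers(0, 2**31 - 1))
            noise_seed_gt = int(rng.integers(0, 2**31 - 1))
            noise_seed_pred = int(rng.integers(0, 2**31 - 1))

            gt, lm = generate_bone(spec, patient_id=pid)
            pert = PerturbationSpec(
                rigid=_random_rigid(rng),
                offset_rms=offset_rms,
                seed=pert_seed,
            )
            pred = perturb(gt, pert)

            write_stl(gt.mesh, pdir / f"{bone}_gt.stl")
            write_stl(pred.mesh, pdir / f"{bone}_pred.stl")
            if write_masks:
                save_mask_nifti(voxelize_bone(spec, voxel_spacing), pdir / f"{bone}_gt.nii.gz")

            ns_gt = AnnotationNoiseSpec(noise.n_observers, noise.n_repeats,
                                        noise.observer_bias_sd, noise.repeat_sd, noise_seed_gt)
            ns_pred = AnnotationNoiseSpec(noise.n_observers, noise.n_repeats,
                                          noise.observer_bias_sd, noise.repeat_sd, noise_seed_pred)
            annotations += simulate_annotations(lm, gt.mesh, ns_gt, "ground_truth",
                                                pid, bone, side)
            annotations += simulate_annotations(lm, pred.mesh, ns_pred, "prediction",
                                                pid, bone, side)
            entry["bones"][bone] = {
                "scale": scale,
                "offset_rms": offset_rms,
                "rigid_matrix": pert.rigid.matrix.tolist(),
                "perturbation_seed": pert_seed,
                "annotation_seeds": {"ground_truth": noise_seed_gt,
                                     "prediction": noise_seed_pred},
                "landmarks_true": {k: v.tolist() for k, v in lm.items()},
                "n_vertices": gt.mesh.n_vertices,
            }
        save_annotations_json(annotations, pdir / "annotations.json")
        manifest["patients"][pid] = entry

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("wrote synthetic cohort of %d patients to %s", n_patients, out_dir)
    return manifest
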