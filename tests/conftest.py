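import numpy as np
import pytest
import trimesh

import kneeval as kv


@pytest.fixture(scope="session")
def femur():
    """Default synthetic femur: (ground-truth model, exact landmark map)."""
    return kv.generate_bone(kv.SyntheticBoneSpec.femur(), patient_id="p1")


@pytest.fixture(scope="session")
def tibia():
    return kv.generate_bone(kv.SyntheticBoneSpec.tibia(), patient_id="p1")


@pytest.fixture()
def unit_tetrahedron():
    verts = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return kv.TriangleMesh(verts, faces)


def make_sphere_mesh(radius: float = 10.0, subdivisions: int = 2) -> kv.TriangleMesh:
    s = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return kv.TriangleMesh.from_trimesh(s)


def random_cloud_mesh(rng: np.random.Generator, n: int) -> kv.TriangleMesh:
    """Vertex cloud wrapped in a valid (dummy) mesh for distance queries."""
    return kv.TriangleMesh(rng.uniform(-20, 20, size=(n, 3)), np.empty((0, 3), dtype=int))
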