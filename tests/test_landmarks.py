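import numpy as np
import pytest

import kneeval as kv
from kneeval.landmarks import _discard_outliers, group_annotations


def ann(point, landmark="tuberosity", obs="obs1", rep=1, source="ground_truth"):
    return kv.LandmarkAnnotation(
        landmark=landmark, observer_id=obs, repeat_index=rep, point=point,
        model_source=source, bone="tibia",
    )


def make_annotation_cluster(center, spread_points):
    return [
        ann(np.asarray(center) + np.asarray(d), obs=f"obs{i % 3 + 1}", rep=i // 3 + 1)
        for i, d in enumerate(spread_points)
    ]


@pytest.fixture(scope="module")
def grid_mesh():
    """Flat dense unit-spacing-0.25 grid in the z=0 plane."""
    xs = np.arange(-15, 15.01, 0.25)
    xx, yy = np.meshgrid(xs, xs)
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
    n = len(xs)
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces.append([a, a + 1, a + n])
            faces.append([a + 1, a + n + 1, a + n])
    return kv.TriangleMesh(verts, np.array(faces))


# ---------------------------------------------------------------------------
# outlier rule
# ---------------------------------------------------------------------------


def brute_force_outlier_rule(points):
    """Literal restatement of the documented rule, used as an oracle."""
    pts = [np.asarray(p, dtype=float) for p in points]
    idx = list(range(len(pts)))
    min_keep = max(3, int(np.ceil(len(pts) / 2)))
    while len(idx) > min_keep:
        sub = [pts[i] for i in idx]
        dists = []
        for k, p in zip(idx, sub):
            others = np.array([q for j, q in zip(idx, sub) if j != k])
            dists.append(np.linalg.norm(p - others.mean(axis=0)))
        pair = [np.linalg.norm(a - b) for i, a in enumerate(sub) for b in sub[i + 1:]]
        thresh = max(2.0, 2.0 * np.median(pair))
        worst = int(np.argmax(dists))
        if dists[worst] > thresh:
            idx.pop(worst)
        else:
            break
    keep = np.zeros(len(pts), dtype=bool)
    keep[idx] = True
    return keep


def test_outlier_rule_matches_brute_force_oracle():
    rng = np.random.default_rng(9)
    for _ in range(30):
        n = rng.integers(3, 9)
        pts = rng.normal(0, 1.0, size=(n, 3))
        if rng.uniform() < 0.5 and n >= 4:
            pts[0] += rng.uniform(10, 40, size=3)  # plant an outlier
        assert np.array_equal(_discard_outliers(pts), brute_force_outlier_rule(pts))


def test_far_point_discarded(grid_mesh):
    center = np.array([0.0, 0.0, 0.0])
    spread = [np.zeros(3), [0.5, 0, 0], [-0.5, 0.3, 0], [0, -0.6, 0], [0.2, 0.2, 0], [30.0, 0, 0]]
    anns = make_annotation_cluster(center, spread)
    region = kv.build_region(anns, grid_mesh, radius=5.0)
    assert len(region.inlier_annotations) == 5
    assert len(region.outliers) == 1
    assert np.linalg.norm(region.outliers[0].point - [30, 0, 0]) < 1e-9
    assert np.linalg.norm(region.center - center) < 0.3  # snapped near the cluster


def test_coincident_annotations(grid_mesh):
    p = np.array([1.1, 2.1, 0.0])
    anns = make_annotation_cluster(p, [np.zeros(3)] * 6)
    region = kv.build_region(anns, grid_mesh, radius=5.0)
    assert len(region.outliers) == 0
    # center snapped to the nearest grid vertex of p
    assert np.linalg.norm(region.center - [1.0, 2.0, 0.0]) < 1e-9


# ---------------------------------------------------------------------------
# region membership
# ---------------------------------------------------------------------------


def test_member_count_matches_disc_area(grid_mesh):
    anns = make_annotation_cluster(np.zeros(3), [np.zeros(3)] * 6)
    region = kv.build_region(anns, grid_mesh, radius=5.0)
    density = 1.0 / 0.25**2  # vertices per mm^2
    expected = np.pi * 25 * density
    assert abs(len(region.member_vertices) - expected) / expected < 0.10


def test_region_permutation_invariant(grid_mesh):
    rng = np.random.default_rng(3)
    spread = [rng.normal(0, 0.8, 3) for _ in range(6)]
    anns = make_annotation_cluster(np.zeros(3), spread)
    r1 = kv.build_region(anns, grid_mesh, radius=5.0)
    r2 = kv.build_region(list(reversed(anns)), grid_mesh, radius=5.0)
    assert np.array_equal(r1.member_vertices, r2.member_vertices)
    assert np.allclose(r1.center, r2.center)


def test_shrinking_radius_never_adds_vertices(grid_mesh):
    anns = make_annotation_cluster(np.zeros(3), [np.zeros(3)] * 6)
    big = kv.build_region(anns, grid_mesh, radius=6.0)
    small = kv.build_region(anns, grid_mesh, radius=3.0)
    assert set(small.member_vertices) <= set(big.member_vertices)


def test_geodesic_ball_subset_of_euclidean(grid_mesh):
    anns = make_annotation_cluster(np.zeros(3), [np.zeros(3)] * 6)
    eu = kv.build_region(anns, grid_mesh, radius=4.0, metric="euclidean")
    ge = kv.build_region(anns, grid_mesh, radius=4.0, metric="geodesic")
    assert set(ge.member_vertices) <= set(eu.member_vertices)
    assert len(ge.member_vertices) > 10


def test_region_error_paths(grid_mesh):
    with pytest.raises(ValueError):
        kv.build_region(make_annotation_cluster(np.zeros(3), [np.zeros(3)] * 2),
                        grid_mesh, radius=5.0)
    spread = [[0, 0, 0], [40, 0, 0], [0, 40, 0], [40, 40, 0], [-40, 0, 0], [0, -40, 0]]
    with pytest.raises(ValueError, match="no consensus"):
        kv.build_region(make_annotation_cluster(np.zeros(3), spread), grid_mesh, radius=5.0)


def test_zero_noise_regions_recover_landmarks(femur):
    gt, lm = femur
    noise = kv.AnnotationNoiseSpec(observer_bias_sd=0.0, repeat_sd=0.0, seed=0)
    anns = kv.simulate_annotations(lm, gt.mesh, noise, "ground_truth", bone="femur")
    groups = group_annotations(anns)
    for name in kv.landmarks.FEMUR_REGION_LANDMARKS:
        region = kv.build_region(groups[("ground_truth", name)], gt.mesh, radius=5.0)
        # center within one mesh edge of the analytic landmark
        assert np.linalg.norm(region.center - lm[name]) < 1.5 * np.sqrt(3)


# ---------------------------------------------------------------------------
# local RMSE
# ---------------------------------------------------------------------------


def test_local_rmse_zero_for_identical(femur):
    gt, lm = femur
    noise = kv.AnnotationNoiseSpec(observer_bias_sd=0.0, repeat_sd=0.0, seed=0)
    anns = kv.simulate_annotations(lm, gt.mesh, noise, "prediction", bone="femur")
    groups = group_annotations(anns)
    region = kv.build_region(groups[("prediction", "anterior_cortex")], gt.mesh, radius=5.0)
    res = kv.local_rmse(region, gt.mesh)
    assert res.rmse == 0.0


def test_local_rmse_recovers_uniform_offset(femur):
    gt, lm = femur
    # displace the whole surface 0.5 mm along the normals: local RMS is 0.5 everywhere
    normals = gt.mesh.compute_vertex_normals()
    pred_mesh = kv.TriangleMesh(gt.mesh.vertices + 0.5 * normals, gt.mesh.faces)
    noise = kv.AnnotationNoiseSpec(observer_bias_sd=0.0, repeat_sd=0.0, seed=0)
    anns = kv.simulate_annotations(lm, pred_mesh, noise, "prediction", bone="femur")
    groups = group_annotations(anns)
    for name in ("anterior_cortex", "medial_distal_condyle"):
        region = kv.build_region(groups[("prediction", name)], pred_mesh, radius=5.0)
        res = kv.local_rmse(region, gt.mesh)
        assert abs(res.rmse - 0.5) / 0.5 < 0.15
        assert res.rmse <= res.per_point_distances.max() + 1e-12


# ---------------------------------------------------------------------------
# annotation I/O and validation
# ---------------------------------------------------------------------------


def test_annotation_json_round_trip(tmp_path):
    anns = make_annotation_cluster([1, 2, 3], [np.zeros(3), [0.1, 0, 0], [0, 0.1, 0]])
    kv.save_annotations_json(anns, tmp_path / "a.json")
    back = kv.load_annotations_json(tmp_path / "a.json")
    assert len(back) == 3
    assert all(np.allclose(a.point, b.point) for a, b in zip(anns, back))
    assert back[0].landmark == "tuberosity"


def test_mps_reader(tmp_path):
    xml = """<?xml version="1.0"?>
    <point_set_file><point_set><time_series>
      <point><id>0</id><x>10.5</x><y>-3.25</y><z>7.0</z></point>
      <point><id>1</id><x>11.0</x><y>-3.0</y><z>7.5</z></point>
    </time_series></point_set></point_set_file>"""
    (tmp_path / "p.mps").write_text(xml)
    anns = kv.load_annotations_mps(tmp_path / "p.mps", "medial_plateau", "obs1", 1,
                                   "ground_truth", bone="tibia")
    assert len(anns) == 2
    assert np.allclose(anns[0].point, [10.5, -3.25, 7.0])


def test_annotation_validation():
    with pytest.raises(ValueError):
        ann([0, 0, 0], landmark="unknown_spot")
    with pytest.raises(ValueError):  # femoral landmark on a tibia
        kv.LandmarkAnnotation("anterior_cortex", "obs1", 1, [0, 0, 0],
                              "ground_truth", bone="tibia")
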