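import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from itertools import combinations, product

import kneeval as kv
from kneeval import axes as kax


def ann(landmark, point, obs="obs1", rep=1, source="ground_truth", bone="femur"):
    return kv.LandmarkAnnotation(landmark, obs, rep, point, source, bone=bone)


def axis2d(angle_deg, name="TEA", obs="obs1", rep=1, source="ground_truth", plane=None):
    th = np.radians(angle_deg)
    return kv.Axis2D(name, (0.0, 0.0), (np.cos(th), np.sin(th)),
                     provenance=(source, obs, rep), plane=plane)


def six_axes(angles, source="ground_truth", name="TEA"):
    provs = [(o, r) for o in ("obs1", "obs2", "obs3") for r in (1, 2)]
    return [axis2d(a, name=name, obs=o, rep=r, source=source)
            for a, (o, r) in zip(angles, provs)]


# ---------------------------------------------------------------------------
# 3D axis construction and projection
# ---------------------------------------------------------------------------


def test_build_tea_from_epicondyles():
    a = ann("lateral_epicondyle", [80, 0, 0])
    b = ann("medial_epicondyle", [0, 0, 0])
    ax = kv.build_axis3d(a, b)
    assert ax.name == "TEA"
    assert np.allclose(np.abs(ax.direction), [1, 0, 0])
    # swapped order gives the same undirected line
    ax2 = kv.build_axis3d(b, a)
    assert abs(abs(ax.direction @ ax2.direction) - 1.0) < 1e-12


def test_build_axis_rejects_bad_pairings():
    a = ann("lateral_epicondyle", [80, 0, 0])
    with pytest.raises(ValueError):  # wrong landmark pair
        kv.build_axis3d(a, ann("anterior_cortex", [0, 0, 0]))
    with pytest.raises(ValueError):  # mismatched observer
        kv.build_axis3d(a, ann("medial_epicondyle", [0, 0, 0], obs="obs2"))


def test_axes_from_annotations_yields_six(femur):
    gt, lm = femur
    anns = kv.simulate_annotations(lm, gt.mesh, kv.AnnotationNoiseSpec(seed=1),
                                   "ground_truth", bone="femur")
    for name in ("TEA", "PCA"):
        axes = kv.axes_from_annotations(anns, name)
        assert len(axes) == 6
        assert len({ax.provenance for ax in axes}) == 6


def test_project_axis_preserves_in_plane_angles():
    plane = kv.make_plane((0, 0, 0), (0, 0, 1))
    a3 = kv.Axis3D("TEA", [0, 0, 0], [10, 0, 0], provenance=("ground_truth", "o", 1))
    b3 = kv.Axis3D("TEA", [0, 0, 0], [10, 10 * np.tan(np.radians(20)), 0],
                   provenance=("ground_truth", "o", 2))
    a2, b2 = kv.project_axis(a3, plane), kv.project_axis(b3, plane)
    assert abs(kv.angle_between(a2, b2) - 20.0) < 1e-9
    # out-of-plane tilt projects endpoints
    c3 = kv.Axis3D("TEA", [0, 0, 0], [10, 0, 30], provenance=("ground_truth", "o", 1))
    c2 = kv.project_axis(c3, plane)
    # its projection is the projection of its endpoints: parallel to a2
    assert abs(abs(c2.direction @ a2.direction) - 1.0) < 1e-12


def test_project_axis_along_normal_degenerate():
    plane = kv.make_plane((0, 0, 0), (0, 0, 1))
    with pytest.raises(ValueError, match="degenerate"):
        kv.project_axis(kv.Axis3D("TEA", [0, 0, 0], [0, 0, 50],
                                  provenance=("ground_truth", "o", 1)), plane)


# ---------------------------------------------------------------------------
# pairwise angles
# ---------------------------------------------------------------------------


def test_angle_between_examples():
    assert kv.angle_between(axis2d(0), axis2d(0)) == 0.0
    assert abs(kv.angle_between(axis2d(0), axis2d(90)) - 90.0) < 1e-12
    # antiparallel invariance: (1,0) vs (-1, tan 5) scaled
    a = kv.Axis2D("TEA", (0, 0), (1.0, 0.0), provenance=("ground_truth", "o", 1))
    b = kv.Axis2D("TEA", (0, 0), (-3.0, 3.0 * np.tan(np.radians(5))),
                  provenance=("ground_truth", "o", 2))
    assert abs(kv.angle_between(a, b) - 5.0) < 1e-9


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.floats(0, 180), st.floats(0, 180))
def test_angle_between_symmetric_flip_invariant(a_deg, b_deg):
    a, b = axis2d(a_deg), axis2d(b_deg)
    ang = kv.angle_between(a, b)
    assert 0.0 <= ang <= 90.0
    assert kv.angle_between(b, a) == ang
    flipped = kv.Axis2D("TEA", a.point, -a.direction, provenance=a.provenance)
    assert abs(kv.angle_between(flipped, b) - ang) < 1e-9


# ---------------------------------------------------------------------------
# baseline / cross statistics
# ---------------------------------------------------------------------------


def test_baseline_identical_axes():
    s = kv.baseline_stats(six_axes([10.0] * 6))
    assert (s.mean_deg, s.sd_deg, s.n_pairs) == (0.0, 0.0, 15)
    assert s.kind == "baseline_ct_ct"


def test_baseline_matches_brute_force_enumeration():
    angles = [0.0, 1.0, 2.0, 3.0, 4.0, 5.0]
    axes = six_axes(angles)
    s = kv.baseline_stats(axes)
    brute = [kv.angle_between(a, b) for a, b in combinations(axes, 2)]
    assert s.n_pairs == 15
    assert np.isclose(s.mean_deg, np.mean(brute))
    assert np.isclose(s.sd_deg, np.std(brute, ddof=1))


def test_baseline_rejects_duplicates_and_wrong_source():
    axes = six_axes([0, 1, 2, 3, 4, 5])
    axes[1] = axis2d(1.0, obs="obs1", rep=1)  # duplicate (observer, repeat)
    with pytest.raises(ValueError, match="duplicate"):
        kv.baseline_stats(axes)
    with pytest.raises(ValueError):
        kv.baseline_stats(six_axes([0, 1, 2, 3, 4, 5], source="prediction"))


def test_cross_rotated_by_phi():
    ct = six_axes([7.0] * 6)
    xr = six_axes([7.0 + 2.0] * 6, source="prediction")
    s = kv.cross_stats(ct, xr)
    assert s.n_pairs == 36
    assert abs(s.mean_deg - 2.0) < 1e-9
    assert s.sd_deg < 1e-9
    assert s.kind == "cross_ct_xray"


def test_cross_of_identical_sets_relates_to_baseline():
    angles = [0.0, 1.5, 3.0, 4.5, 6.0, 7.5]
    ct = six_axes(angles)
    xr = six_axes(angles, source="prediction")
    base = kv.baseline_stats(ct)
    cross = kv.cross_stats(ct, xr)
    # 36 ordered pairs = each of the 15 unordered pairs twice + 6 zero self-pairs
    assert np.isclose(cross.mean_deg, base.mean_deg * 30 / 36)


def test_cross_matches_brute_force_product():
    rng = np.random.default_rng(5)
    ct = six_axes(rng.uniform(0, 10, 6))
    xr = six_axes(rng.uniform(0, 10, 6), source="prediction")
    s = kv.cross_stats(ct, xr)
    brute = [kv.angle_between(a, b) for a, b in product(ct, xr)]
    assert np.isclose(s.mean_deg, np.mean(brute))
    assert np.isclose(s.sd_deg, np.std(brute, ddof=1))


# ---------------------------------------------------------------------------
# annotation-noise behaviour
# ---------------------------------------------------------------------------


def _baseline_tea_mean(femur, noise_sd, seeds):
    gt, lm = femur
    plane = kv.make_plane((0, 0, 0), (0, 0, 1))
    means = []
    for seed in seeds:
        noise = kv.AnnotationNoiseSpec(observer_bias_sd=0.0, repeat_sd=noise_sd, seed=seed)
        anns = kv.simulate_annotations(lm, gt.mesh, noise, "ground_truth", bone="femur")
        axes3d = kv.axes_from_annotations(anns, "TEA")
        axes2d = [kv.project_axis(ax, plane) for ax in axes3d]
        means.append(kv.baseline_stats(axes2d).mean_deg)
    return float(np.mean(means))


def test_baseline_angle_grows_with_endpoint_noise(femur):
    seeds = range(40)
    m = [_baseline_tea_mean(femur, sd, seeds) for sd in (0.5, 1.5, 3.0)]
    assert m[0] < m[1] < m[2]


def test_baseline_mean_matches_monte_carlo_oracle(femur):
    """Measured baseline TEA angle vs direct Monte-Carlo of the same noise
    model (endpoint noise + vertex snap), independent of the stats path."""
    gt, lm = femur
    sd = 1.5
    measured = _baseline_tea_mean(femur, sd, range(200))

    from scipy.spatial import cKDTree

    rng = np.random.default_rng(12345)
    tree = cKDTree(gt.mesh.vertices)
    lat, med = lm["lateral_epicondyle"], lm["medial_epicondyle"]
    n_draws = 8000
    lat_pts = gt.mesh.vertices[tree.query(lat + rng.normal(0, sd, (n_draws, 3)))[1]]
    med_pts = gt.mesh.vertices[tree.query(med + rng.normal(0, sd, (n_draws, 3)))[1]]
    d = (lat_pts - med_pts)[:, :2]  # project to the z-plane
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    # mean pairwise undirected angle over random independent pairs
    i, j = rng.integers(0, n_draws, 50000), rng.integers(0, n_draws, 50000)
    keep = i != j
    cosang = np.abs(np.sum(d[i[keep]] * d[j[keep]], axis=1))
    oracle = float(np.degrees(np.arccos(np.clip(cosang, 0, 1))).mean())
    assert abs(measured - oracle) / oracle < 0.05


# ---------------------------------------------------------------------------
# study-level report
# ---------------------------------------------------------------------------


def test_single_bone_report_equals_bone_stats():
    base = kv.baseline_stats(six_axes([0, 1, 2, 3, 4, 5]))
    cross = kv.cross_stats(six_axes([0, 1, 2, 3, 4, 5]),
                           six_axes([1, 2, 3, 4, 5, 6], source="prediction"))
    df = kv.study_axis_report([base, cross])
    row = df[df.axis == "TEA"].iloc[0]
    assert np.isclose(row.baseline_mean, base.mean_deg)
    assert np.isclose(row.cross_mean, cross.mean_deg)
    assert row.baseline_n_pairs == 15 and row.cross_n_pairs == 36


def test_report_pools_raw_angles_across_bones():
    s1 = kv.baseline_stats(six_axes([0, 1, 2, 3, 4, 5]))
    s2 = kv.baseline_stats(six_axes([10, 11, 12, 13, 14, 15]))
    df = kv.study_axis_report([s1, s2])
    pooled = np.concatenate([s1.angles_deg, s2.angles_deg])
    row = df[df.axis == "TEA"].iloc[0]
    assert np.isclose(row.baseline_mean, pooled.mean())
    assert np.isclose(row.baseline_sd, pooled.std(ddof=1))
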