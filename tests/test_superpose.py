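import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from helixweak.superpose import (
    GeometryError,
    apply_transform,
    iterative_superpose,
    superpose,
)


def _random_points(rng, n=5):
    return rng.normal(0.0, 3.0, (n, 3))


def test_identical_sets_identity():
    rng = np.random.default_rng(0)
    pts = _random_points(rng, 8)
    result = superpose(pts, pts)
    assert result.rmsd == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(result.rotation, np.eye(3), atol=1e-10)


def test_planted_transform_recovered():
    rng = np.random.default_rng(1)
    pts = _random_points(rng, 10)
    rot = Rotation.from_euler("z", 37.0, degrees=True).as_matrix()
    t = np.array([1.0, 2.0, 3.0])
    moved = pts @ rot.T + t
    result = superpose(pts, moved)
    assert result.rmsd < 1e-6
    np.testing.assert_allclose(result.rotation, rot, atol=1e-6)
    np.testing.assert_allclose(result.translation, t, atol=1e-6)


def test_mirrored_set_gets_proper_rotation():
    rng = np.random.default_rng(2)
    pts = _random_points(rng, 7)
    mirrored = pts * np.array([-1.0, 1.0, 1.0])
    result = superpose(pts, mirrored)
    assert np.linalg.det(result.rotation) == pytest.approx(1.0, abs=1e-8)
    assert result.rmsd > 0.1


def test_rotation_always_orthonormal():
    rng = np.random.default_rng(3)
    for _ in range(20):
        a, b = _random_points(rng), _random_points(rng)
        r = superpose(a, b).rotation
        np.testing.assert_allclose(r @ r.T, np.eye(3), atol=1e-8)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-8)


def test_degenerate_inputs_rejected():
    line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
    with pytest.raises(GeometryError):
        superpose(line, line)
    with pytest.raises(GeometryError):
        superpose(np.zeros((2, 3)), np.zeros((2, 3)))


def test_rmsd_symmetry_and_rigid_invariance():
    rng = np.random.default_rng(4)
    a, b = _random_points(rng, 12), _random_points(rng, 12)
    r_ab = superpose(a, b).rmsd
    r_ba = superpose(b, a).rmsd
    assert r_ab == pytest.approx(r_ba, abs=1e-9)
    rot = Rotation.from_euler("xyz", [11.0, 22.0, 33.0], degrees=True).as_matrix()
    a2 = a @ rot.T + np.array([4.0, 5.0, 6.0])
    assert superpose(a2, b).rmsd == pytest.approx(r_ab, abs=1e-9)


def _oracle_best_rmsd(mobile, reference, n_grid=24):
    """Direct RMSD minimization over rotations, independent of Kabsch/SVD:
    coarse rotation-vector grid then local refinement."""
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)

    def rmsd_of(rotvec):
        rot = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(np.mean(np.sum((mc @ rot.T - rc) ** 2, axis=1)))

    ticks = np.linspace(-np.pi, np.pi, n_grid)
    best, best_v = np.inf, None
    for x in ticks:
        for y in ticks:
            for z in ticks:
                v = np.array([x, y, z])
                if np.linalg.norm(v) > np.pi:
                    continue
                r = rmsd_of(v)
                if r < best:
                    best, best_v = r, v
    res = minimize(rmsd_of, best_v, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000})
    return min(best, float(res.fun))


def test_kabsch_matches_rotation_search_oracle():
    rng = np.random.default_rng(5)
    for _ in range(3):
        a, b = _random_points(rng, 5), _random_points(rng, 5)
        kabsch_rmsd = superpose(a, b).rmsd
        oracle = _oracle_best_rmsd(a, b)
        assert kabsch_rmsd <= oracle + 1e-4
        assert abs(kabsch_rmsd - oracle) < 1e-4


def test_apply_transform_round_trip(ideal_helix20):
    import copy
    s = copy.deepcopy(ideal_helix20)
    rng = np.random.default_rng(6)
    rot = Rotation.random(random_state=7).as_matrix()
    t = rng.normal(0, 5, 3)
    from helixweak.superpose import SuperpositionResult
    fwd = SuperpositionResult(rotation=rot, translation=t, rmsd=0.0, n_pairs=0)
    inv = SuperpositionResult(rotation=rot.T, translation=-rot.T @ t, rmsd=0.0, n_pairs=0)
    before = s.atom_coords()
    apply_transform(s, fwd)
    # distances preserved under the transform
    moved = s.atom_coords()
    d_before = np.linalg.norm(before[0] - before[-1])
    d_after = np.linalg.norm(moved[0] - moved[-1])
    assert d_after == pytest.approx(d_before, abs=1e-9)
    apply_transform(s, inv)
    np.testing.assert_allclose(s.atom_coords(), before, atol=1e-9)


def test_iterative_trimming_excludes_planted_outliers():
    rng = np.random.default_rng(8)
    pts = rng.normal(0, 5, (30, 3))
    moved = pts + rng.normal(0, 0.02, pts.shape)
    outliers = rng.choice(30, 3, replace=False)
    moved[outliers] += 10.0
    result = iterative_superpose(pts, moved, cutoff=3.5)
    assert result.rmsd < 0.1
    assert set(np.where(~result.mask)[0]) == set(outliers)


def test_iterative_with_infinite_cutoff_equals_plain():
    rng = np.random.default_rng(9)
    a, b = rng.normal(0, 3, (10, 3)), rng.normal(0, 3, (10, 3))
    plain = superpose(a, b)
    iterative = iterative_superpose(a, b, cutoff=np.inf)
    assert iterative.rmsd == pytest.approx(plain.rmsd, abs=1e-12)
    assert iterative.mask.all()


def test_iterative_too_aggressive_cutoff_fails():
    rng = np.random.default_rng(10)
    a, b = rng.normal(0, 3, (10, 3)), rng.normal(0, 3, (10, 3))
    with pytest.raises(GeometryError):
        iterative_superpose(a, b, cutoff=1e-9)
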