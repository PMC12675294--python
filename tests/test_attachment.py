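"""Attachment measures against exhaustive brute-force oracles."""

import itertools

import numpy as np
import pytest

import vesselflow as vf
from vesselflow.attachment import SinkhornConfig

from conftest import random_cloud


def brute_chamfer(A, B, wA=None, wB=None):
    """O(M M') all-pairs oracle for the (weighted) Chamfer distance."""
    d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(axis=2)
    f = d2.min(axis=1) if wA is None else wA * d2.min(axis=1)
    b = d2.min(axis=0) if wB is None else wB * d2.min(axis=0)
    return f.mean() + b.mean(), f, b


def brute_emd_sq(A, B):
    """Exact optimal transport for uniform clouds by enumerating matchings."""
    n = len(A)
    best = np.inf
    for perm in itertools.permutations(range(n)):
        cost = sum(((A[i] - B[perm[i]]) ** 2).sum() for i in range(n))
        best = min(best, cost)
    return best / n


class TestChamferFamily:
    def test_zero_on_identical_clouds(self):
        rng = np.random.default_rng(0)
        c = random_cloud(rng, 12, normals=True)
        assert vf.chamfer(c, c).total == 0.0
        assert vf.weighted_chamfer(c, c).total == 0.0
        # unit-normal dot products can round to 1 - eps, leaving ~1e-33 residue
        assert vf.chamfer_normals(c, c, w_n=0.3).total == pytest.approx(0.0, abs=1e-15)
        assert vf.point_to_plane_chamfer(c, c).total == 0.0

    def test_two_single_points(self):
        a = vf.WeightedPointCloud([[0, 0, 0]], [1.0])
        b = vf.WeightedPointCloud([[1, 0, 0]], [1.0])
        res = vf.chamfer(a, b)
        assert res.total == pytest.approx(2.0)
        assert res.forward_term == pytest.approx(1.0)
        assert res.backward_term == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        A = random_cloud(rng, rng.integers(2, 10))
        B = random_cloud(rng, rng.integers(2, 10))
        res = vf.chamfer(A, B)
        oracle, pf, pb = brute_chamfer(A.points, B.points)
        assert abs(res.total - oracle) <= 1e-12
        assert np.allclose(res.pointwise_forward, pf, atol=1e-12)
        wres = vf.weighted_chamfer(A, B)
        woracle, _, _ = brute_chamfer(A.points, B.points, A.weights, B.weights)
        assert abs(wres.total - woracle) <= 1e-12

    def test_symmetry(self):
        rng = np.random.default_rng(42)
        A, B = random_cloud(rng, 8), random_cloud(rng, 6)
        assert abs(vf.chamfer(A, B).total - vf.chamfer(B, A).total) <= 1e-12

    def test_uniform_weights_scale_as_inverse_cardinality(self):
        """With uniform weights 1/M each weighted directional term is the
        corresponding unweighted term divided by the cardinality."""
        rng = np.random.default_rng(1)
        A = vf.WeightedPointCloud(rng.uniform(size=(6, 3)), np.full(6, 1 / 6))
        B = vf.WeightedPointCloud(rng.uniform(size=(9, 3)), np.full(9, 1 / 9))
        plain, weighted = vf.chamfer(A, B), vf.weighted_chamfer(A, B)
        assert weighted.forward_term == pytest.approx(plain.forward_term / 6, rel=1e-12)
        assert weighted.backward_term == pytest.approx(plain.backward_term / 9, rel=1e-12)

    def test_heavy_outlier_dominates_weighted_forward_term(self):
        pts = np.array([[0, 0, 0], [5.0, 0, 0]])
        target = vf.WeightedPointCloud([[0, 0, 0]], [1.0])
        heavy = vf.WeightedPointCloud(pts, [0.1, 0.9])
        light = vf.WeightedPointCloud(pts, [0.99, 0.01])
        assert (
            vf.weighted_chamfer(heavy, target).forward_term
            > 50 * vf.weighted_chamfer(light, target).forward_term
        )

    def test_normals_penalty_degenerate_weight_equals_chamfer(self):
        rng = np.random.default_rng(2)
        A, B = random_cloud(rng, 7, normals=True), random_cloud(rng, 5, normals=True)
        assert vf.chamfer_normals(A, B, w_n=0.0).total == pytest.approx(
            vf.chamfer(A, B).total, abs=1e-15
        )

    def test_antiparallel_normals_penalty(self):
        a = vf.WeightedPointCloud([[0, 0, 0]], [1.0], [[0, 0, 1]])
        b = vf.WeightedPointCloud([[0, 0, 0]], [1.0], [[0, 0, -1]])
        w_n = 0.05
        # distance 0, penalty (w_n/2)(1-(-1))^2 in each direction = 4 w_n
        assert vf.chamfer_normals(a, b, w_n=w_n).total == pytest.approx(4 * w_n)

    def test_normals_converge_to_chamfer(self):
        rng = np.random.default_rng(3)
        A, B = random_cloud(rng, 6, normals=True), random_cloud(rng, 6, normals=True)
        cd = vf.chamfer(A, B).total
        gaps = [abs(vf.chamfer_normals(A, B, w_n=w).total - cd) for w in (1e-1, 1e-3, 1e-6)]
        assert gaps[0] > gaps[1] > gaps[2]


class TestPointToPlane:
    def test_tangential_displacement_costs_nothing(self):
        a = vf.WeightedPointCloud([[0, 0, 0]], [1.0], [[0, 0, 1]])
        b = vf.WeightedPointCloud([[0.4, 0.2, 0]], [1.0], [[0, 0, 1]])
        res = vf.point_to_plane_chamfer(a, b)
        assert res.forward_term == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_projected_minimum_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        A = random_cloud(rng, 6, normals=True)
        B = random_cloud(rng, 6, normals=True)
        res = vf.point_to_plane_chamfer(A, B)
        pf = (
            np.einsum("ijk,ik->ij", A.points[:, None, :] - B.points[None, :, :], A.normals)
            ** 2
        ).min(axis=1)
        pb = (
            np.einsum("ijk,ik->ij", B.points[:, None, :] - A.points[None, :, :], B.normals)
            ** 2
        ).min(axis=1)
        assert abs(res.total - (pf.mean() + pb.mean())) <= 1e-12


class TestSinkhorn:
    def test_zero_on_identical_uniform_clouds(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(size=(8, 3))
        c = vf.WeightedPointCloud(pts, np.full(8, 1 / 8))
        assert abs(vf.sinkhorn_divergence(c, c).total) <= 1e-6

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_approaches_enumerated_emd(self, n):
        rng = np.random.default_rng(5 + n)
        A = vf.WeightedPointCloud(rng.uniform(size=(n, 3)), np.full(n, 1 / n))
        B = vf.WeightedPointCloud(rng.uniform(size=(n, 3)), np.full(n, 1 / n))
        emd = brute_emd_sq(A.points, B.points)
        sd = vf.sinkhorn_divergence(A, B)
        assert abs(sd.total - emd) / emd < 1e-3

    def test_nonnegative(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            A, B = random_cloud(rng, 5), random_cloud(rng, 7)
            assert vf.sinkhorn_divergence(A, B, weighted=True).total >= -1e-6

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SinkhornConfig(epsilon=-1.0)
        with pytest.raises(ValueError):
            SinkhornConfig(scaling=1.5)

    def test_no_pointwise_decomposition(self):
        rng = np.random.default_rng(7)
        res = vf.sinkhorn_divergence(random_cloud(rng, 4), random_cloud(rng, 4))
        assert not res.supports_pointwise


class TestErrorMetrics:
    def test_fld_bld_zero_on_identical(self):
        rng = np.random.default_rng(8)
        c = random_cloud(rng, 20)
        fld, bld, summary = vf.fld_bld(c, c)
        assert np.all(fld == 0) and np.all(bld == 0)
        assert summary["fld_max"] == 0.0

    def test_rigid_offset_bound(self):
        rng = np.random.default_rng(9)
        c = random_cloud(rng, 30)
        shifted = c.with_points(c.points + [0.3, 0, 0])
        # well-separated: offset smaller than typical inter-point spacing? use sparse cloud
        sparse = vf.WeightedPointCloud(np.diag([3.0, 6.0, 9.0]), np.full(3, 1 / 3))
        moved = sparse.with_points(sparse.points + [0.3, 0, 0])
        fld, bld, summary = vf.fld_bld(moved, sparse)
        assert summary["fld_max"] == pytest.approx(0.3)
        # generic bound: FLD never exceeds the offset
        fld2, _, _ = vf.fld_bld(shifted, c)
        assert fld2.max() <= 0.3 + 1e-12

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_nn_oracle_distances_not_squared(self, seed):
        rng = np.random.default_rng(200 + seed)
        A, B = random_cloud(rng, 9), random_cloud(rng, 7)
        fld, bld, _ = vf.fld_bld(A, B)
        d = np.sqrt(((A.points[:, None, :] - B.points[None, :, :]) ** 2).sum(axis=2))
        assert np.allclose(fld, d.min(axis=1), atol=1e-12)
        assert np.allclose(bld, d.min(axis=0), atol=1e-12)

    def test_physical_units_via_unit_cube(self):
        pts = np.array([[0.0, 0, 0], [10.0, 10, 10]])
        cloud = vf.WeightedPointCloud(pts, [0.5, 0.5])
        cube = vf.fit_unit_cube([cloud], margin=0.0)
        a = cloud.with_points(cube.apply(cloud.points))
        b = a.with_points(a.points + [0.1, 0, 0])
        _, _, summary = vf.fld_bld(b, a, to_physical=cube)
        assert summary["fld_max"] == pytest.approx(1.0)  # 0.1 cube units = 1 cm


class TestBidirectionalError:
    def test_identity_map_equal_clouds(self):
        rng = np.random.default_rng(10)
        c = random_cloud(rng, 10)
        assert vf.bidirectional_error(c, c, c, c, "cd") == 0.0

    def test_identity_map_different_clouds_doubles_symmetric_measure(self):
        rng = np.random.default_rng(11)
        S, T = random_cloud(rng, 8), random_cloud(rng, 8)
        # identity map: forward_mapped = S, inverse_mapped = T
        e = vf.bidirectional_error(S, T, S, T, "cd")
        assert e == pytest.approx(2 * vf.chamfer(S, T).total, rel=1e-12)

    def test_equals_sum_of_directional_calls(self):
        rng = np.random.default_rng(12)
        S, T = random_cloud(rng, 6), random_cloud(rng, 9)
        fwd, inv = random_cloud(rng, 6), random_cloud(rng, 9)
        e = vf.bidirectional_error(S, T, fwd, inv, "cd")
        assert e == pytest.approx(
            vf.chamfer(fwd, T).total + vf.chamfer(inv, S).total, rel=1e-12
        )
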