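"""Currents kernel norm, dissimilarity, gradients, and surface registration."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrhist.geometry import Affine, TriangleMesh
from mrhist.surface import (
    CurrentsParams,
    affine_register_surfaces,
    cauchy_kernel,
    currents_dissimilarity,
    currents_energy_and_gradient,
    currents_norm_sq,
    currents_vertex_gradient,
    diffeo_register_surfaces,
    split_block_surface,
)
from conftest import random_mesh


def brute_force_pair(c1, n1, c2, n2, sigma):
    total = 0.0
    for i in range(len(c1)):
        for j in range(len(c2)):
            k = 1.0 / (1.0 + np.sum((c1[i] - c2[j]) ** 2) / sigma**2)
            total += float(n1[i] @ n2[j]) * k
    return total


def brute_force_dissimilarity(S1, S2, sigma):
    """Naive O(nm) double-sum oracle for the three-term expansion."""
    c1, n1 = S1.face_centers(), S1.face_normals()
    c2, n2 = S2.face_centers(), S2.face_normals()
    return (brute_force_pair(c1, n1, c1, n1, sigma)
            - 2.0 * brute_force_pair(c1, n1, c2, n2, sigma)
            + brute_force_pair(c2, n2, c2, n2, sigma))


class TestCauchyKernel:
    def test_identity_and_half_value(self):
        x = np.array([1.0, 2.0, 3.0])
        assert cauchy_kernel(x, x, 2.0) == 1.0
        y = x + np.array([2.0, 0.0, 0.0])  # |x-y| = sigma
        assert cauchy_kernel(x, y, 2.0) == pytest.approx(0.5)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.1, 5.0))
    def test_symmetry_and_range(self, seed, sigma):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 3))
        kxy = cauchy_kernel(x, y, sigma)
        assert kxy == pytest.approx(cauchy_kernel(y, x, sigma))
        assert 0.0 < kxy <= 1.0

    def test_monotone_decreasing_in_distance(self):
        x = np.zeros(3)
        d = np.linspace(0, 10, 50)
        vals = [cauchy_kernel(x, np.array([di, 0, 0]), 1.5) for di in d]
        assert np.all(np.diff(vals) < 0)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            cauchy_kernel(np.zeros(3), np.ones(3), -1.0)


class TestCurrentsNorm:
    def test_single_triangle_hand_value(self):
        # area-weighted normal (0, 0, 0.5): <eta, eta> k(c, c) = 0.25
        tri = TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        for sigma in (0.5, 1.0, 4.0):
            assert currents_norm_sq(tri, sigma) == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mesh = random_mesh(rng, 10, 14)
        sigma = float(rng.uniform(0.3, 3.0))
        c, n = mesh.face_centers(), mesh.face_normals()
        expected = brute_force_pair(c, n, c, n, sigma)
        assert currents_norm_sq(mesh, sigma) == pytest.approx(
            expected, rel=1e-12)

    def test_rigid_invariance(self, rng, ellipsoid_mesh):
        sigma = 1.7
        before = currents_norm_sq(ellipsoid_mesh, sigma)
        A = Affine.rotation_z(37.0).compose(Affine.translate([3, -1, 2]))
        after = currents_norm_sq(ellipsoid_mesh.transformed(A), sigma)
        assert after == pytest.approx(before, rel=1e-10)

    def test_empty_mesh_rejected(self):
        empty = TriangleMesh(np.empty((0, 3)), np.empty((0, 3), int))
        with pytest.raises(ValueError):
            currents_norm_sq(empty, 1.0)


class TestCurrentsDissimilarity:
    def test_identical_surfaces_zero(self, ellipsoid_mesh):
        assert abs(currents_dissimilarity(ellipsoid_mesh, ellipsoid_mesh,
                                          2.0)) < 1e-10

    @pytest.mark.parametrize("seed", [3, 4])
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        m1 = random_mesh(rng, 9, 12)
        m2 = random_mesh(rng, 11, 10, offset=1.0)
        d12 = currents_dissimilarity(m1, m2, 1.3)
        d21 = currents_dissimilarity(m2, m1, 1.3)
        assert d12 == pytest.approx(d21, rel=1e-12)

    def test_far_separation_approaches_norm_sum(self):
        t1 = TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        sigma = 1.0
        t2 = TriangleMesh(t1.vertices + np.array([10 * sigma, 0, 0]),
                          t1.faces)
        d = currents_dissimilarity(t1, t2, sigma)
        norms = currents_norm_sq(t1, sigma) + currents_norm_sq(t2, sigma)
        assert d == pytest.approx(norms, rel=0.02)
        assert d < norms  # the cross term is tiny but positive

    def test_vertex_order_invariance(self, rng, ellipsoid_mesh):
        """Registration energies must not depend on mesh array order."""
        m = ellipsoid_mesh
        perm = rng.permutation(m.n_vertices)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(m.n_vertices)
        shuffled = TriangleMesh(m.vertices[perm],
                                inv[m.faces][rng.permutation(m.n_faces)])
        other = m.transformed(Affine.translate([0.5, 0.2, -0.1]))
        d1 = currents_dissimilarity(m, other, 1.5)
        d2 = currents_dissimilarity(shuffled, other, 1.5)
        assert d1 == pytest.approx(d2, rel=1e-10)

    def test_oracle_equivalence_random_pairs(self):
        rng = np.random.default_rng(99)
        for _ in range(5):
            m1 = random_mesh(rng, 12, 20)
            m2 = random_mesh(rng, 10, 15, offset=0.5)
            sigma = float(rng.uniform(0.5, 2.5))
            got = currents_dissimilarity(m1, m2, sigma)
            want = brute_force_dissimilarity(m1, m2, sigma)
            assert got == pytest.approx(want, rel=1e-10, abs=1e-12)


class TestCurrentsGradient:
    @pytest.mark.parametrize("seed", [0, 7])
    def test_matches_central_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        moving = random_mesh(rng, 8, 10)
        target = random_mesh(rng, 9, 11, offset=0.8)
        sigma = 1.1
        grad = currents_vertex_gradient(moving, target, sigma)
        eps = 1e-6
        fd = np.zeros_like(grad)
        for i in range(moving.n_vertices):
            for d in range(3):
                vp = moving.vertices.copy()
                vp[i, d] += eps
                vm = moving.vertices.copy()
                vm[i, d] -= eps
                fd[i, d] = (
                    currents_dissimilarity(moving.with_vertices(vp), target,
                                           sigma)
                    - currents_dissimilarity(moving.with_vertices(vm),
                                             target, sigma)) / (2 * eps)
        scale = max(np.abs(fd).max(), 1e-12)
        assert np.abs(grad - fd).max() / scale < 1e-5

    def test_fused_energy_matches_dissimilarity(self, rng):
        m1 = random_mesh(rng, 10, 12)
        m2 = random_mesh(rng, 9, 11, offset=1.0)
        e, _ = currents_energy_and_gradient(m1, m2, 0.9)
        assert e == pytest.approx(currents_dissimilarity(m1, m2, 0.9),
                                  rel=1e-12)


class TestSplitBlockSurface:
    @staticmethod
    def unit_cube() -> TriangleMesh:
        import trimesh

        box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        return TriangleMesh(np.asarray(box.vertices),
                            np.asarray(box.faces))

    def test_cube_partition(self):
        cube = self.unit_cube()
        head, foot, ext = split_block_surface(cube, (0, 0, 1.0), 45.0)
        assert head.n_faces == 2 and foot.n_faces == 2
        assert ext.n_faces == 8
        assert head.n_faces + foot.n_faces + ext.n_faces == cube.n_faces

    def test_cylinder_caps_and_barrel(self):
        import trimesh

        cyl = trimesh.creation.cylinder(radius=1.0, height=2.0, sections=24)
        mesh = TriangleMesh(np.asarray(cyl.vertices), np.asarray(cyl.faces))
        head, foot, ext = split_block_surface(mesh, (0, 0, 1.0), 45.0)
        assert head.n_faces > 0 and foot.n_faces > 0 and ext.n_faces > 0
        # caps face straight up/down; barrel normals are horizontal
        assert np.all(head.unit_normals()[:, 2] > 0.99)
        assert np.all(foot.unit_normals()[:, 2] < -0.99)
        assert np.all(np.abs(ext.unit_normals()[:, 2]) < 0.01)
        total = head.n_faces + foot.n_faces + ext.n_faces
        assert total == mesh.n_faces

    def test_open_mesh_rejected(self):
        tri = TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]])
        with pytest.raises(ValueError):
            split_block_surface(tri, (0, 0, 1.0), 45.0)


class TestAffineSurfaceRegistration:
    def test_identity_for_identical_surfaces(self, ellipsoid_mesh):
        params = CurrentsParams(sigma=2.0, max_iters=50)
        res = affine_register_surfaces(ellipsoid_mesh, ellipsoid_mesh,
                                       params)
        assert np.allclose(res.transform.linear, np.eye(3), atol=1e-3)
        assert np.allclose(res.transform.translation, 0.0, atol=1e-3)

    def test_translation_recovery(self, ellipsoid_mesh):
        params = CurrentsParams(sigma=2.0, max_iters=150)
        target = ellipsoid_mesh.transformed(Affine.translate([2.0, 1.0, 0]))
        res = affine_register_surfaces(ellipsoid_mesh, target, params)
        assert np.abs(res.transform.translation - [2, 1, 0]).max() < 0.05
        moved = ellipsoid_mesh.transformed(res.transform)
        err = np.linalg.norm(moved.vertices - target.vertices, axis=1)
        assert err.mean() < 0.05

    def test_rotation_recovery(self, ellipsoid_mesh):
        params = CurrentsParams(sigma=2.0, max_iters=150)
        target = ellipsoid_mesh.transformed(Affine.rotation_z(10.0))
        res = affine_register_surfaces(ellipsoid_mesh, target, params)
        ang = np.rad2deg(np.arctan2(res.transform.linear[1, 0],
                                    res.transform.linear[0, 0]))
        assert abs(ang - 10.0) < 0.5

    def test_energy_monotone_over_iterations(self, ellipsoid_mesh):
        params = CurrentsParams(sigma=2.0, max_iters=60)
        target = ellipsoid_mesh.transformed(Affine.translate([1.0, 0, 0.5]))
        res = affine_register_surfaces(ellipsoid_mesh, target, params)
        e = np.array(res.energies)
        assert np.all(np.diff(e) <= 1e-9 * max(1.0, e[0]))


class TestDiffeoSurfaceRegistration:
    def test_identity_for_identical_surfaces(self, ellipsoid_mesh):
        params = CurrentsParams(sigma=1.5, velocity_kernel_scale=3.0,
                                max_iters=30)
        res = diffeo_register_surfaces(ellipsoid_mesh, ellipsoid_mesh,
                                       params)
        moved = res.transform.transform_points(ellipsoid_mesh.vertices)
        disp = np.linalg.norm(moved - ellipsoid_mesh.vertices, axis=1)
        assert disp.max() < 0.01

    def test_known_bump_recovery(self, ellipsoid_mesh):
        def bump(X):
            g = np.exp(-np.sum((X - np.array([3.0, 0, 1])) ** 2, axis=1)
                       / (2 * 3.0**2))
            return X + g[:, None] * np.array([0.6, 0.6, 0.5])

        target = ellipsoid_mesh.with_vertices(bump(ellipsoid_mesh.vertices))
        params = CurrentsParams(sigma=1.5, velocity_kernel_scale=3.0,
                                regularization=1e-4, max_iters=120)
        res = diffeo_register_surfaces(ellipsoid_mesh, target, params)
        moved = res.transform.transform_points(ellipsoid_mesh.vertices)
        err = np.linalg.norm(moved - target.vertices, axis=1)
        assert err.mean() < 0.2
        res.transform.check_valid()

    def test_z_translation_only_mode(self, ellipsoid_mesh):
        shift = np.array([0.0, 0.0, 0.4])
        target = ellipsoid_mesh.with_vertices(ellipsoid_mesh.vertices + shift)
        params = CurrentsParams(sigma=1.5, velocity_kernel_scale=3.0,
                                regularization=1e-4, max_iters=80)
        res = diffeo_register_surfaces(ellipsoid_mesh, target, params,
                                       constraint="z_translation_only")
        moved = res.transform.transform_points(ellipsoid_mesh.vertices)
        dz = moved[:, 2] - ellipsoid_mesh.vertices[:, 2]
        assert abs(dz.mean() - 0.4) < 0.05
        assert dz.std() < 1e-9  # z motion is exactly one global translation
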