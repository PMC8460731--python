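"""Intensity-based registration: energy, smoothing operator, recovery."""
import numpy as np
import pytest
from scipy.ndimage import binary_erosion, map_coordinates

from mrhist.geometry import Affine, GeometryError, Image2D, ImageVolume
from mrhist.imagereg import (
    ImageRegParams,
    affine_register_images,
    cauchy_navier_smooth,
    diffeo_register_images,
    resample,
    sse_energy,
    sse_gradient_field,
)
from conftest import binary_disk_image


class TestSseEnergy:
    def test_identical_images_zero(self, disk_image):
        assert sse_energy(disk_image, disk_image) == pytest.approx(0.0)

    def test_constant_offset_closed_form(self):
        shape = (8, 9, 10)
        spacing = (0.5, 1.0, 0.25)
        I0 = ImageVolume(np.zeros(shape), spacing, (0, 0, 0))
        c = 1.7
        I1 = I0.like(np.full(shape, c))
        volume = np.prod(shape) * np.prod(spacing)
        assert sse_energy(I1, I0) == pytest.approx(c**2 * volume)

    def test_matches_direct_voxel_sum(self, rng):
        vals0 = rng.normal(size=(8, 8, 8))
        vals1 = rng.normal(size=(8, 8, 8))
        I0 = ImageVolume(vals0, (1, 1, 1), (0, 0, 0))
        I1 = ImageVolume(vals1, (1, 1, 1), (0, 0, 0))
        expected = float(np.sum((vals1 - vals0) ** 2))
        assert sse_energy(I1, I0) == pytest.approx(expected, rel=1e-12)

    def test_gradient_field_matches_finite_differences(self, rng):
        n = 12
        vals = np.cumsum(rng.normal(size=(n, n)), axis=0)
        I1 = Image2D(vals, [1.0, 1.0], [0, 0])
        I0 = Image2D(rng.normal(size=(n, n)), [1.0, 1.0], [0, 0])
        u = 0.2 * rng.normal(size=(n, n, 2)) + 0.13  # avoid cell boundaries
        g = sse_gradient_field(I1, I0, u)
        eps = 1e-6
        for (i, j, d) in [(3, 4, 0), (7, 2, 1), (5, 5, 0)]:
            up = u.copy()
            up[i, j, d] += eps
            um = u.copy()
            um[i, j, d] -= eps

            def energy(uu):
                pts = I0.world_coords().reshape(-1, 2) + uu.reshape(-1, 2)
                vals_w = np.array([
                    map_coordinates(I1.values,
                                    I1.world_to_pixel(pts).T, order=1,
                                    mode="nearest")]).ravel()
                return float(np.sum((vals_w - I0.values.ravel())**2))

            fd = (energy(up) - energy(um)) / (2 * eps)
            assert g[i, j, d] == pytest.approx(fd, rel=1e-5, abs=1e-9)


class TestCauchyNavierSmoothing:
    def test_linear(self, rng):
        f1 = rng.normal(size=(16, 16, 2))
        f2 = rng.normal(size=(16, 16, 2))
        sp = np.array([1.0, 1.0])
        a, b = 2.0, -0.7
        lhs = cauchy_navier_smooth(a * f1 + b * f2, sp, 1.0, 1.0)
        rhs = a * cauchy_navier_smooth(f1, sp, 1.0, 1.0) + \
            b * cauchy_navier_smooth(f2, sp, 1.0, 1.0)
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_self_adjoint(self, rng):
        sp = np.array([1.0, 1.0])
        f = rng.normal(size=(12, 12, 2))
        g = rng.normal(size=(12, 12, 2))
        Kf = cauchy_navier_smooth(f, sp, 1.3, 0.8)
        Kg = cauchy_navier_smooth(g, sp, 1.3, 0.8)
        assert np.sum(g * Kf) == pytest.approx(np.sum(f * Kg), rel=1e-10)

    def test_reduces_high_frequency_energy(self, rng):
        sp = np.array([1.0, 1.0])
        f = rng.normal(size=(32, 32, 2))
        v = cauchy_navier_smooth(f, sp, 1.0, 1.0)
        def hf_energy(field):
            out = 0.0
            for d in range(2):
                F = np.fft.fftn(field[..., d])
                mask = np.ones_like(F, dtype=bool)
                mask[:8, :8] = False  # low-frequency corner
                out += float(np.sum(np.abs(F[mask]) ** 2))
            return out
        # normalize: smoothing also shrinks amplitude, compare fractions
        assert hf_energy(v) / np.sum(v**2) < hf_energy(f) / np.sum(f**2)


class TestAffineImageRegistration:
    def test_identity_for_identical(self, disk_image):
        res = affine_register_images(disk_image, disk_image)
        assert np.allclose(res.transform.linear, np.eye(2), atol=1e-3)
        assert np.abs(res.transform.translation).max() < 1e-2

    def test_flat_image_rejected(self):
        flat = Image2D(np.ones((16, 16)), [1, 1], [0, 0])
        with pytest.raises(GeometryError):
            affine_register_images(flat, flat)

    def test_known_shift_recovery(self, disk_image):
        sp = disk_image.spacing[0]
        A_true = Affine.translate([3 * sp, 1 * sp])
        I1 = resample(disk_image, A_true.inverse(), disk_image)
        res = affine_register_images(I1, disk_image)
        err_vox = np.abs(res.transform.translation -
                         A_true.translation) / sp
        assert err_vox.max() < 0.1

    def test_known_rotation_recovery(self, disk_image):
        c = np.array([16.0, 16.0])
        R = Affine.rotation_z(5.0, dim=2)
        A_true = Affine(R.linear, c - R.linear @ c)
        I1 = resample(disk_image, A_true.inverse(), disk_image)
        res = affine_register_images(I1, disk_image)
        ang = np.rad2deg(np.arctan2(res.transform.linear[1, 0],
                                    res.transform.linear[0, 0]))
        assert abs(ang - 5.0) < 0.2


def normal_bump_warp(img: Image2D, max_px: float = 1.5):
    """Smooth warp along the disk's boundary-normal field (identifiable
    from a binary image, unlike tangential motion)."""
    n = img.shape[0]
    sp = img.spacing[0]
    x, y = np.meshgrid(np.arange(n) * sp, np.arange(n) * sp, indexing="ij")
    c = n * sp / 2
    nx, ny = (x - c) / 10.0**2, (y - c) / 7.0**2
    norm = np.sqrt(nx**2 + ny**2)
    norm[norm == 0] = 1.0
    g = np.exp(-(((x - c) - 6) ** 2 + ((y - c) - 3) ** 2) / (2 * 6.0**2))
    u = max_px * sp * g[..., None] * np.stack([nx / norm, ny / norm],
                                              axis=-1)
    pts = img.world_coords().reshape(-1, 2)
    warped = img.sample(pts + u.reshape(-1, 2)).reshape(img.shape)
    return img.like(warped), u


class TestDiffeoImageRegistration:
    def test_identity_for_identical(self, disk_image):
        res = diffeo_register_images(disk_image, disk_image,
                                     ImageRegParams(max_iters=10))
        phi = res.transform
        pts = disk_image.world_coords().reshape(-1, 2)
        disp = np.linalg.norm(phi.transform_points(
            pts, check_domain=False) - pts, axis=1)
        assert disp.max() < 0.05 * disk_image.spacing[0]

    def test_known_warp_recovery(self, disk_image):
        I1, u = normal_bump_warp(disk_image)
        res = diffeo_register_images(I1, disk_image,
                                     ImageRegParams(max_iters=100))
        phi = res.transform
        warped = resample(I1, phi, disk_image)
        a = warped.values > 0.5
        b = disk_image.values > 0.5
        dice = 2 * np.sum(a & b) / (a.sum() + b.sum())
        assert dice >= 0.98
        # residual on boundary landmarks vs the fixed point of x + u(x)
        sp = disk_image.spacing[0]
        mask = disk_image.values.astype(bool)
        bnd = mask & ~binary_erosion(mask)
        lm = disk_image.world_coords()[bnd][::5]
        xstar = lm.copy()
        for _ in range(60):
            uu = np.stack([map_coordinates(u[..., d], (xstar / sp).T,
                                           order=1, mode="nearest")
                           for d in range(2)], axis=-1)
            xstar = lm - uu
        mapped = phi.transform_points(lm, check_domain=False)
        err = np.linalg.norm(mapped - xstar, axis=1) / sp
        assert err.mean() < 0.3
        phi.check_valid()

    def test_energy_nonincreasing_within_levels(self, disk_image):
        I1, _ = normal_bump_warp(disk_image)
        res = diffeo_register_images(I1, disk_image,
                                     ImageRegParams(max_iters=30))
        for level in res.level_energies:
            diffs = np.diff(level)
            assert np.all(diffs <= 0)


class TestResample:
    def test_identity_same_grid(self, disk_image):
        out = resample(disk_image, None, disk_image)
        assert np.allclose(out.values, disk_image.values)

    def test_integer_shift(self, disk_image):
        sp = disk_image.spacing[0]
        out = resample(disk_image, Affine.translate([sp, 0.0]), disk_image)
        assert np.allclose(out.values[:-1], disk_image.values[1:])

    def test_nearest_keeps_binary(self, disk_image):
        A = Affine(np.eye(2) * 1.05, np.array([0.3, -0.2]))
        out = resample(disk_image, A, disk_image, interpolation="nearest")
        assert set(np.unique(out.values)) <= {0.0, 1.0}
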