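"""Blockface imaging, stack assembly, surface extraction, R1, and the
sequential block reconstruction."""
import numpy as np
import pytest

from mrhist.blocks import (
    BlockSurfaceSet,
    align_blockface_stack,
    choose_center_block,
    lighting_difference,
    match_section_to_blockface,
    reconstruct_blocks,
    register_histology_to_blockface,
    stack_to_surface,
    surface_from_labels,
)
from mrhist.geometry import (
    Affine,
    GeometryError,
    Image2D,
    LabelVolume,
    TransformChain,
)
from mrhist.imagereg import ImageRegParams, resample
from mrhist.surface import CurrentsParams, currents_dissimilarity
from conftest import binary_disk_image


def img2d(values, spacing=0.5, depth=0.0):
    return Image2D(values, [spacing, spacing], [0.0, 0.0], depth)


class TestLightingDifference:
    def test_identical_images_zero(self, rng):
        a = img2d(rng.uniform(size=(8, 8)))
        out = lighting_difference(a, img2d(a.values.copy()))
        assert np.allclose(out.values, 0.0)

    def test_constant_offset_recovered(self, rng):
        perp = img2d(rng.uniform(size=(8, 8)))
        par = img2d(perp.values + 0.4)
        out = lighting_difference(par, perp)
        assert np.allclose(out.values, 0.4)

    def test_shows_only_exposed_tissue(self, small_phantom):
        """Simulated show-through cancels in the lighting difference."""
        spec, phantom, exvivo, blocks = small_phantom
        blk = blocks[1]
        k = len(blk.blockfaces) // 2
        diff = lighting_difference(blk.blockfaces[k],
                                   blk.blockfaces_perpendicular[k])
        surface = blk.blockface_segs[k].values > 0.5
        # exposed tissue is bright, non-tissue is noise-level
        assert diff.values[surface].mean() > 5 * abs(
            diff.values[~surface].mean())

    def test_mismatched_grids_rejected(self, rng):
        a = img2d(rng.uniform(size=(8, 8)))
        b = Image2D(rng.uniform(size=(8, 8)), [0.5, 0.5], [1.0, 0.0])
        with pytest.raises(GeometryError):
            lighting_difference(a, b)


class TestStackAlignment:
    @staticmethod
    def make_series(rng, n=4, jitter_px=0.0):
        """Anti-aliased ellipse rendered analytically at shifted positions
        (each frame is exact, so recovery is limited by the method, not by
        resampling artifacts in the fixture)."""
        npix, sp = 48, 0.5
        x, y = np.meshgrid(np.arange(npix) * sp, np.arange(npix) * sp,
                           indexing="ij")
        c = npix * sp / 2
        images, shifts = [], []
        for k in range(n):
            if k == 0 or jitter_px == 0:
                shift = np.zeros(2)
            else:
                shift = rng.uniform(-jitter_px, jitter_px, 2) * sp
            r = np.sqrt(((x + shift[0] - c) / 10.0) ** 2
                        + ((y + shift[1] - c) / 7.0) ** 2)
            vals = np.clip((1.0 - r) * 10.0 + 0.5, 0.0, 1.0)  # soft edge
            images.append(Image2D(vals, [sp, sp], [0.0, 0.0], 0.05 * k))
            shifts.append(shift)
        return images, shifts

    def test_aligned_stack_gives_identity_affines(self, rng):
        images, _ = self.make_series(rng, jitter_px=0.0)
        stack = align_blockface_stack(images)
        for A in stack.alignments:
            assert np.allclose(A.linear, np.eye(2), atol=5e-3)
            assert np.abs(A.translation).max() < 5e-3

    def test_known_jitter_recovered(self, rng):
        images, shifts = self.make_series(rng, n=4, jitter_px=2.0)
        stack = align_blockface_stack(images)
        for A, shift in zip(stack.alignments, shifts):
            # the affine maps stack frame -> raw frame, so it carries the
            # negated jitter of that image
            assert np.abs(A.translation + shift).max() < 0.2 * 0.5

    def test_volume_geometry(self, rng):
        images, _ = self.make_series(rng)
        stack = align_blockface_stack(images)
        assert stack.volume.shape[2] == len(images)
        assert stack.volume.spacing[2] == pytest.approx(0.05)

    def test_empty_list_rejected(self):
        with pytest.raises(GeometryError):
            align_blockface_stack([])


class TestSurfaceFromLabels:
    @staticmethod
    def ball(radius=10.0, spacing=1.0, n=26):
        coords = (np.arange(n) - n / 2 + 0.5) * spacing
        x, y, z = np.meshgrid(coords, coords, coords, indexing="ij")
        mask = x**2 + y**2 + z**2 <= radius**2
        return LabelVolume(mask.astype(float), (spacing,) * 3,
                           (coords[0],) * 3)

    def test_ball_area_near_analytic(self):
        """Staircase-smoothed surface area approaches the sphere's; the
        raw marching-cubes staircase systematically inflates area."""
        mesh = surface_from_labels(self.ball(), 0.5, smooth_iters=10)
        assert mesh.area() == pytest.approx(4 * np.pi * 100, rel=0.05)

    def test_closed_and_outward(self):
        mesh = surface_from_labels(self.ball(), 0.5)
        assert mesh.is_closed()
        signed_vol = np.einsum("ij,ij->", mesh.face_centers(),
                               mesh.face_normals()) / 3.0
        assert signed_vol > 0

    def test_vertices_near_label_boundary(self):
        mesh = surface_from_labels(self.ball(), 0.5)
        r = np.linalg.norm(mesh.vertices, axis=1)
        assert np.all(np.abs(r - 10.0) < 1.0)

    def test_empty_label_rejected(self):
        empty = LabelVolume(np.zeros((4, 4, 4)), (1, 1, 1), (0, 0, 0))
        with pytest.raises(GeometryError):
            surface_from_labels(empty)


class TestMatchSection:
    @staticmethod
    def stack_with_depths(rng):
        base = binary_disk_image(n=16)
        images = [Image2D(base.values, base.spacing, base.origin, 0.05 * k)
                  for k in range(8)]
        return align_blockface_stack(
            images, ImageRegParams(pyramid_levels=(1,), max_iters=1,
                                   affine_max_iters=1))

    def test_exact_depth(self, rng):
        stack = self.stack_with_depths(rng)
        assert match_section_to_blockface(0.15, stack) == 3

    def test_midpoint_ties_to_shallower(self, rng):
        stack = self.stack_with_depths(rng)
        assert match_section_to_blockface(0.125, stack) == 2

    def test_nearest_rounding(self, rng):
        stack = self.stack_with_depths(rng)
        assert match_section_to_blockface(0.26, stack) == 5

    def test_out_of_range_rejected(self, rng):
        stack = self.stack_with_depths(rng)
        with pytest.raises(GeometryError):
            match_section_to_blockface(2.0, stack)


class TestRegisterHistologyToBlockface:
    def test_identical_segmentations_near_identity(self, disk_image):
        chain, _ = register_histology_to_blockface(disk_image, disk_image)
        pts = disk_image.world_coords().reshape(-1, 2)[::17]
        moved = chain.transform_points(pts)
        assert np.abs(moved - pts).max() < 0.1 * disk_image.spacing[0]

    def test_known_warp_dice(self, disk_image):
        from test_imagereg import normal_bump_warp

        hist, _ = normal_bump_warp(disk_image, max_px=1.5)
        chain, diag = register_histology_to_blockface(hist, disk_image)
        # map histology label to blockface coordinates and compare
        warped = resample(hist, chain.inverted(), disk_image)
        a = warped.values > 0.5
        b = disk_image.values > 0.5
        dice = 2 * np.sum(a & b) / (a.sum() + b.sum())
        assert dice >= 0.98
        assert diag["affine_energies"][-1] <= diag["affine_energies"][0]

    def test_empty_segmentation_rejected(self, disk_image):
        empty = disk_image.like(np.zeros(disk_image.shape))
        with pytest.raises(GeometryError):
            register_histology_to_blockface(empty, disk_image)


def cube_blocks(n_blocks=3, size=12.0, thickness=4.0, spacing=0.5):
    """Axis-aligned cuboid sliced into blocks (analytic, no phantom)."""
    half = size / 2
    blocks = []
    for b in range(n_blocks):
        z0 = -n_blocks * thickness / 2 + b * thickness
        z1 = z0 + thickness
        nx = int(size / spacing) + 1
        nz = int(round(thickness / spacing))
        coords_x = -half + spacing * np.arange(nx)
        # voxel centers half a step inside the slab so adjacent blocks'
        # marching-cubes cut faces coincide at the shared cut plane
        coords_z = z0 + spacing / 2 + spacing * np.arange(nz)
        x, y, z = np.meshgrid(coords_x, coords_x, coords_z, indexing="ij")
        # rounded-square cross-section so rotation is identifiable
        mask = (np.maximum(np.abs(x), np.abs(y)) <= half - 1.0) & \
            (x**2 + y**2 <= (half - 0.5)**2)
        label = LabelVolume(mask.astype(float), (spacing, spacing, spacing),
                            (coords_x[0], coords_x[0], coords_z[0]))
        mesh = surface_from_labels(label, 0.5)
        cut = (None if b == 0 else z0, None if b == n_blocks - 1 else z1)
        blocks.append(BlockSurfaceSet.from_surface(b, mesh, cut_planes=cut))
    return blocks


class TestReconstructBlocks:
    def test_center_block_has_largest_exterior(self, small_phantom):
        spec, phantom, exvivo, blocks = small_phantom
        bss = []
        nb = len(blocks)
        for blk in blocks:
            surf = stack_to_surface(None, blk.blockface_segs,
                                    target_spacing=1.0)
            cut = (None if blk.index == 0 else blk.z0,
                   None if blk.index == nb - 1 else blk.z1)
            bss.append(BlockSurfaceSet.from_surface(blk.index, surf,
                                                    cut_planes=cut))
        center = choose_center_block(bss)
        areas = [b.exterior.area() for b in bss]
        assert areas[center] == max(areas)

    def test_single_block_identity(self):
        blocks = cube_blocks(n_blocks=1)
        ex_surface = blocks[0].surface
        params = CurrentsParams(sigma=1.5, velocity_kernel_scale=6.0,
                                regularization=1.0, max_iters=10,
                                flow_steps=3, convergence_tol=1e-5)
        chains, ext = reconstruct_blocks(blocks, ex_surface,
                                         params, params)
        pts = blocks[0].surface.vertices[::7]
        moved = ext.transform_points(chains[0].transform_points(pts))
        assert np.abs(moved - pts).max() < 0.2

    def test_known_translation_recovery(self):
        """Blocks shifted by known small translations are pulled back to
        their neighbors within a tenth of a millimeter."""
        blocks = cube_blocks(n_blocks=3)
        ex_surface = stack_like_union(blocks)
        shifts = {0: np.array([0.6, -0.4, 0.0]),
                  2: np.array([-0.5, 0.7, 0.0])}
        for b, shift in shifts.items():
            blk = blocks[b]
            moved = blk.surface.with_vertices(blk.surface.vertices + shift)
            cut = (None if b == 0 else blk.foot.vertices[:, 2].mean(),
                   None if b == 2 else blk.head.vertices[:, 2].mean())
            blocks[b] = BlockSurfaceSet.from_surface(
                b, moved, cut_planes=(
                    None if b == 0 else blocks[b].foot.vertices[:, 2].mean()
                    + shift[2],
                    None if b == 2 else blocks[b].head.vertices[:, 2].mean()
                    + shift[2]))
        params = CurrentsParams(sigma=1.0, velocity_kernel_scale=4.0,
                                regularization=0.1, max_iters=40,
                                flow_steps=4, convergence_tol=1e-6)
        ext_params = CurrentsParams(sigma=2.0, velocity_kernel_scale=8.0,
                                    regularization=3.0, max_iters=10,
                                    flow_steps=3, convergence_tol=1e-5)
        chains, ext = reconstruct_blocks(blocks, ex_surface, params,
                                         ext_params, center=1)
        for b, shift in shifts.items():
            pts = blocks[b].surface.vertices[::5]
            moved = chains[b].transform_points(pts)
            recovered = pts - moved  # should undo the shift
            err = np.abs(recovered.mean(axis=0) - shift)
            assert err.max() < 0.1

    def test_exterior_dissimilarity_decreases(self, small_phantom):
        spec, phantom, exvivo, blocks = small_phantom
        nb = len(blocks)
        bss = []
        for blk in blocks:
            fine = stack_to_surface(None, blk.blockface_segs,
                                    target_spacing=0.5)
            coarse = stack_to_surface(None, blk.blockface_segs,
                                      target_spacing=1.0, smooth_iters=10)
            cut = (None if blk.index == 0 else blk.z0,
                   None if blk.index == nb - 1 else blk.z1)
            bss.append(BlockSurfaceSet.from_surface(
                blk.index, fine, coarse_surface=coarse, cut_planes=cut))
        ex_surface = surface_from_labels(exvivo.tissue_mask,
                                         smooth_iters=10)
        from mrhist.geometry import merge_meshes

        joined_before = merge_meshes(
            [b.exterior_coarse for b in bss])
        before = currents_dissimilarity(joined_before, ex_surface, 2.0)
        params = CurrentsParams(sigma=1.0, velocity_kernel_scale=3.0,
                                regularization=3e-3, max_iters=15,
                                flow_steps=4, max_control_points=300,
                                convergence_tol=1e-5)
        chains, ext = reconstruct_blocks(bss, ex_surface, params, None)
        joined_after = merge_meshes(
            [b.deformed(b.exterior_coarse) for b in bss])
        moved = joined_after.with_vertices(
            ext.transform_points(joined_after.vertices))
        after = currents_dissimilarity(moved, ex_surface, 2.0)
        assert after < before

    def test_empty_block_list_rejected(self):
        with pytest.raises(GeometryError):
            reconstruct_blocks([], None)


def stack_like_union(blocks):
    """Union surface of the unshifted blocks (stand-in ex vivo surface)."""
    from mrhist.geometry import merge_meshes

    return merge_meshes([b.exterior for b in blocks])
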