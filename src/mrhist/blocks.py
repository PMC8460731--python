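"""Blockface stack assembly, histology-to-blockface registration and the
sequential tissue-block reconstruction to the ex vivo surface.

The reconstruction proceeds from a center block outward: each block's cut
face is registered (affine, then diffeomorphic, both minimizing the
currents dissimilarity) to the already-deformed facing surface of its
reconstructed neighbor, and the deformed block becomes the target for the
next one.  Finally the deformed exterior surfaces of all blocks are
joined and registered to the ex vivo tissue surface, yielding one global
chain applied after the per-block chains.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .geometry import (
    Affine,
    GeometryError,
    Image2D,
    ImageVolume,
    LabelVolume,
    TransformChain,
    TriangleMesh,
    merge_meshes,
)
from .imagereg import (
    ImageRegParams,
    affine_register_images,
    diffeo_register_images,
    resample,
)
from .surface import (
    CurrentsParams,
    affine_register_surfaces,
    currents_dissimilarity,
    currents_norm_sq as _norm_sq,
    diffeo_register_surfaces,
    split_block_surface,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BlockSurfaceSet",
    "BlockfaceStack",
    "lighting_difference",
    "align_blockface_stack",
    "surface_from_labels",
    "match_section_to_blockface",
    "register_histology_to_blockface",
    "choose_center_block",
    "trim_near_planes",
    "reconstruct_blocks",
    "stack_to_surface",
]


# ---------------------------------------------------------------------------
# Blockface imaging
# ---------------------------------------------------------------------------

def lighting_difference(img_parallel: Image2D,
                        img_perpendicular: Image2D) -> Image2D:
    """Difference of the two lighting conditions, clipped at zero.

    Paraffin is slightly translucent, so deeper tissue shows through in
    both images; only the parallel-light image adds the exposed surface,
    so the clipped difference isolates the tissue at the block face.
    """
    if img_parallel.shape != img_perpendicular.shape or not np.allclose(
            img_parallel.spacing, img_perpendicular.spacing) or not \
            np.allclose(img_parallel.origin, img_perpendicular.origin):
        raise GeometryError("lighting pair must share one grid")
    diff = np.clip(img_parallel.values - img_perpendicular.values, 0.0, None)
    return img_parallel.like(diff)


@dataclass
class BlockfaceStack:
    """Aligned blockface image series and its derived 3D volume."""

    images: list[Image2D]
    alignments: list[Affine]
    volume: ImageVolume = field(init=False)

    def __post_init__(self) -> None:
        depths = np.array([im.section_depth for im in self.images])
        if len(depths) >= 2:
            incs = np.diff(depths)
            if np.any(incs <= 0):
                raise GeometryError("blockface depths must strictly increase")
            if not np.allclose(incs, incs[0], atol=1e-9):
                raise GeometryError("blockface spacing must be uniform")
            dz = float(incs[0])
        else:
            dz = 1.0
        first = self.images[0]
        vals = np.stack([im.values for im in self.images], axis=-1)
        origin = np.array([first.origin[0], first.origin[1], depths[0]])
        spacing = np.array([first.spacing[0], first.spacing[1], dz])
        self.volume = ImageVolume(vals, spacing, origin)


def align_blockface_stack(images: list[Image2D],
                          params: ImageRegParams | None = None
                          ) -> BlockfaceStack:
    """Sequential 2D affine alignment of a blockface series.

    Image ``i`` is registered to the already-aligned image ``i-1`` (the
    first image is fixed), correcting small camera shifts; the recovered
    affines map stack coordinates to each raw image's coordinates.
    """
    if not images:
        raise GeometryError("empty blockface image list")
    params = params or ImageRegParams(pyramid_levels=(2, 1),
                                      max_iters=30, smoothing_sigma=1.0)
    aligned = [images[0]]
    affines = [Affine.identity(2)]
    for prev, im in zip(images, images[1:]):
        # frames before the tissue is exposed (or fully sectioned away)
        # are featureless; they stay where they are
        if np.ptp(im.values) == 0 or np.ptp(prev.values) == 0:
            A_rel = Affine.identity(2)
        else:
            # registering the raw pair and composing with the previous
            # accumulated affine targets the *aligned* predecessor while
            # touching each image with only one interpolation; camera
            # jitter is a shift, so the model is translation-only
            A_rel = affine_register_images(
                im, prev, params, constraint="translation_only").transform
        M = A_rel.compose(affines[-1])
        aligned.append(
            Image2D(resample(im, M, images[0]).values, im.spacing,
                    images[0].origin, im.section_depth))
        affines.append(M)
    return BlockfaceStack(aligned, affines)


def match_section_to_blockface(section_depth: float,
                               stack: BlockfaceStack) -> int:
    """Index of the blockface image nearest in depth (ties go shallower)."""
    depths = np.array([im.section_depth for im in stack.images])
    inc = float(depths[1] - depths[0]) if len(depths) > 1 else np.inf
    if section_depth < depths[0] - inc or section_depth > depths[-1] + inc:
        raise GeometryError(
            f"section depth {section_depth} outside blockface range")
    d = np.abs(depths - section_depth)
    best = float(d.min())
    return int(np.nonzero(np.isclose(d, best, atol=1e-9))[0][0])


# ---------------------------------------------------------------------------
# Surface extraction
# ---------------------------------------------------------------------------

def surface_from_labels(labels: LabelVolume, iso: float = 0.5,
                        smooth_iters: int = 0) -> TriangleMesh:
    """Closed, outward-oriented marching-cubes surface in world mm.

    ``smooth_iters`` > 0 applies Taubin smoothing to suppress voxel
    staircase artifacts (low-shrinkage, so the surface stays in place).
    """
    if labels.values.sum() == 0:
        raise GeometryError("empty label volume")
    padded = np.pad(labels.values, 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=iso)
    verts = verts - 1.0  # undo padding offset, back to voxel indices
    world = labels.voxel_to_world(verts)
    if smooth_iters > 0:
        import trimesh
        tm = trimesh.Trimesh(world, faces, process=False)
        trimesh.smoothing.filter_taubin(tm, iterations=smooth_iters)
        world = np.asarray(tm.vertices)
    mesh = TriangleMesh(world, faces, degenerate_ok=True)
    # enforce outward normals: signed volume of a closed surface with
    # outward winding is positive
    signed = np.einsum(
        "ij,ij->", mesh.face_centers(), mesh.face_normals()) / 3.0
    if signed < 0:
        mesh = TriangleMesh(world, faces[:, ::-1], degenerate_ok=True)
    return mesh


# ---------------------------------------------------------------------------
# R1: histology section -> blockface image
# ---------------------------------------------------------------------------

def register_histology_to_blockface(hist_seg: Image2D, bf_seg: Image2D,
                                    params: ImageRegParams | None = None
                                    ) -> tuple[TransformChain, dict]:
    """Affine + deformable 2D registration of a histology segmentation to
    its blockface segmentation.

    Returns a chain mapping *histology* coordinates to *blockface*
    coordinates, plus a diagnostics dict with the per-stage energies.
    """
    if hist_seg.values.sum() == 0 or bf_seg.values.sum() == 0:
        raise GeometryError("empty segmentation image")
    params = params or ImageRegParams(pyramid_levels=(2, 1))
    aff = affine_register_images(hist_seg, bf_seg, params)
    A = aff.transform  # maps blockface coords -> histology coords
    pre = Image2D(resample(hist_seg, A, bf_seg).values, bf_seg.spacing,
                  bf_seg.origin, hist_seg.section_depth)
    deform = diffeo_register_images(pre, bf_seg, params)
    phi = deform.transform  # forward: blockface coords -> pre-aligned coords
    # blockface -> histology is A o phi; the returned chain is its inverse
    chain = TransformChain([(phi, "inverse"), (A, "inverse")])
    diag = {"affine_energies": aff.energies, "diffeo_energies": deform.energies}
    return chain, diag


# ---------------------------------------------------------------------------
# R2: sequential block reconstruction
# ---------------------------------------------------------------------------

@dataclass
class BlockSurfaceSet:
    """A tissue block's surface with its head/foot/exterior partition.

    The head face points toward +z (the head end of the head-foot axis),
    the foot face toward -z.  ``chain`` accumulates the solved affine and
    diffeomorphism mapping block space to the reconstructed frame.
    """

    index: int
    surface: TriangleMesh
    head: TriangleMesh
    foot: TriangleMesh
    exterior: TriangleMesh
    chain: TransformChain = field(default_factory=TransformChain)
    exterior_coarse: TriangleMesh | None = None

    @classmethod
    def from_surface(cls, index: int, surface: TriangleMesh,
                     axis=(0.0, 0.0, 1.0), angle_threshold: float = 45.0,
                     coarse_surface: TriangleMesh | None = None,
                     cut_planes: tuple[float | None, float | None] = (None,
                                                                      None),
                     cut_tolerance: float = 1.5) -> "BlockSurfaceSet":
        """Split a block surface into head/foot/exterior parts.

        The normal rule alone mislabels tilted original tissue boundary
        (e.g. near the poles of the sample) as cut faces; the microtome
        cut planes are known from the slicing protocol, so -- emulating
        the manual correction of the semi-automatic split -- a face only
        counts as head/foot if its normal is within ``angle_threshold`` of
        the axis *and* its center lies within ``cut_tolerance`` mm of the
        corresponding cut plane.  ``cut_planes`` is ``(foot_z, head_z)``;
        ``None`` disables that side (an end block has only one cut).
        """
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)

        def _split(mesh):
            cos_thr = np.cos(np.deg2rad(angle_threshold))
            cosines = mesh.unit_normals() @ axis
            along = mesh.face_centers() @ axis
            foot_z, head_z = cut_planes
            head = cosines >= cos_thr
            if head_z is not None:
                head &= np.abs(along - head_z) <= cut_tolerance
            else:
                head &= False
            foot = cosines <= -cos_thr
            if foot_z is not None:
                foot &= np.abs(along - foot_z) <= cut_tolerance
            else:
                foot &= False
            return (mesh.submesh(head), mesh.submesh(foot),
                    mesh.submesh(~(head | foot)))

        head, foot, exterior = _split(surface)
        out = cls(index, surface, head, foot, exterior)
        if coarse_surface is not None:
            _, _, ext_c = _split(coarse_surface)
            out.exterior_coarse = trim_near_planes(ext_c, cut_planes)
        return out

    def deformed(self, mesh: TriangleMesh) -> TriangleMesh:
        return mesh.with_vertices(self.chain.transform_points(mesh.vertices))


def trim_near_planes(mesh: TriangleMesh, planes, margin: float = 0.9,
                     axis: int = 2) -> TriangleMesh:
    """Drop faces whose center lies within ``margin`` mm of any plane.

    Used to exclude the cut-seam bands from the exterior-to-ex-vivo data
    term: mesh extraction rounds each block's rim into the seam, so the
    band carries systematic surface-mass differences rather than signal.
    """
    planes = [p for p in planes if p is not None]
    if not planes or mesh.n_faces == 0:
        return mesh
    c = mesh.face_centers()[:, axis]
    keep = np.ones(mesh.n_faces, dtype=bool)
    for p in planes:
        keep &= np.abs(c - p) > margin
    if not keep.any():
        return mesh
    return mesh.submesh(keep)


def choose_center_block(blocks: list[BlockSurfaceSet]) -> int:
    """Center block = largest exterior surface area (most geometric anchor)."""
    areas = [b.exterior.area() for b in blocks]
    return int(np.argmax(areas))


def _register_surface_pair(moving: TriangleMesh, target: TriangleMesh,
                           params: CurrentsParams, affine_constraint: str,
                           diffeo_constraint: str,
                           domain_bounds) -> TransformChain:
    # corresponding cut faces carry opposite outward orientations (each
    # points out of its own block); align the currents orientation first,
    # otherwise coincidence is an energy maximum
    cross = 0.5 * (currents_dissimilarity(moving, target, params.sigma)
                   - _norm_sq(moving, params.sigma)
                   - _norm_sq(target, params.sigma))
    if cross > 0:  # dissimilarity cross term is -2<S_m, S_t>
        moving = moving.flipped()
    aff = affine_register_surfaces(moving, target, params,
                                   constraint=affine_constraint)
    A = aff.transform
    pre = moving.transformed(A)
    deff = diffeo_register_surfaces(pre, target, params,
                                    constraint=diffeo_constraint,
                                    domain_bounds=domain_bounds)
    return TransformChain([(A, "forward"), (deff.transform, "forward")])


def reconstruct_blocks(blocks: list[BlockSurfaceSet],
                       ex_vivo_surface: TriangleMesh,
                       face_params: CurrentsParams | None = None,
                       exterior_params: CurrentsParams | None = None,
                       mode: str = "full3d",
                       center: int | None = None,
                       ) -> tuple[list[TransformChain], TransformChain]:
    """Sequential reconstruction of the blocks to the ex vivo surface.

    Blocks must be ordered along the head-foot (z) axis, ascending.  The
    center block stays fixed; neighbors are registered face-to-face
    propagating first in the head (+z) direction, then in the foot (-z)
    direction, each block's cut face moving toward the already-deformed
    facing surface of its reconstructed neighbor.  Afterwards the
    deformed exterior surfaces are joined and registered to the ex vivo
    surface, giving one additional global chain (per-block transforms are
    not re-solved).  In ``slice2d`` mode every solved transform is
    constrained so motion along z is a translation only (the 2D
    slice-correlation emulation).
    """
    if len(blocks) < 1:
        raise GeometryError("need at least one block")
    if mode not in ("full3d", "slice2d"):
        raise ValueError(f"unknown mode {mode!r}")
    face_params = face_params or CurrentsParams(
        sigma=1.0, velocity_kernel_scale=3.0, regularization=3e-3,
        max_iters=25, flow_steps=5, max_control_points=400,
        convergence_tol=1e-5)
    # the assembled stack is already nearly in place, while its mesh is
    # stitched from per-block pieces whose discretization differs from the
    # ex vivo surface; the regularization is set so this stage applies an
    # essentially rigid (translation-dominated) correction -- a flexible
    # exterior flow chases meshing differences and systematically biases
    # the interior mapping at this resolution
    exterior_params = exterior_params or CurrentsParams(
        sigma=2.0, velocity_kernel_scale=8.0, regularization=1e3,
        max_iters=25, flow_steps=5, max_control_points=300,
        convergence_tol=1e-5)
    diffeo_constraint = "z_translation_only" if mode == "slice2d" else "none"
    # a flat cut face cannot identify rotation/scale, so the face affine
    # stage is translation-only (block motions are small; the kernel flow
    # supplies the non-rigid part); the exterior stage sees a curved,
    # globally constrained surface and solves the full affine
    face_affine = "translation_only"
    # the assembled stack is cut in place from the ex vivo sample, so no
    # global rotation/scale separates them; a translation plus the smooth
    # flow is the well-posed model for the exterior stage as well
    ext_affine = "translation_only"
    center = choose_center_block(blocks) if center is None else center
    if not 0 <= center < len(blocks):
        raise GeometryError(f"invalid center block {center}")

    all_pts = np.vstack([b.surface.vertices for b in blocks] +
                        [ex_vivo_surface.vertices])
    pad = 3.0 * max(face_params.velocity_kernel_scale,
                    exterior_params.velocity_kernel_scale)
    bounds = (all_pts.min(axis=0) - pad, all_pts.max(axis=0) + pad)

    order = [(b, +1) for b in range(center + 1, len(blocks))] + \
            [(b, -1) for b in range(center - 1, -1, -1)]
    for b, direction in order:
        blk = blocks[b]
        neighbor = blocks[b - direction]
        if direction > 0:
            moving, target_face = blk.foot, neighbor.head
            names = ("foot", "head")
        else:
            moving, target_face = blk.head, neighbor.foot
            names = ("head", "foot")
        if moving.n_faces == 0 or target_face.n_faces == 0:
            raise GeometryError(
                f"block {blk.index}: empty {names[0]}/{names[1]} facing "
                "surface")
        target = neighbor.deformed(target_face)
        logger.info("R2: registering block %d %s face to block %d", blk.index,
                    names[0], neighbor.index)
        blk.chain = _register_surface_pair(moving, target, face_params,
                                           face_affine, diffeo_constraint,
                                           bounds)

    joined = merge_meshes(
        [b.deformed(b.exterior_coarse if b.exterior_coarse is not None
                    else b.exterior)
         for b in blocks if b.exterior.n_faces > 0])
    logger.info("R2: registering joined exterior (%d faces) to ex vivo "
                "surface (%d faces)", joined.n_faces, ex_vivo_surface.n_faces)
    before = currents_dissimilarity(joined, ex_vivo_surface,
                                    exterior_params.sigma)
    exterior_chain = _register_surface_pair(joined, ex_vivo_surface,
                                            exterior_params, ext_affine,
                                            diffeo_constraint, bounds)
    after = currents_dissimilarity(
        joined.with_vertices(exterior_chain.transform_points(joined.vertices)),
        ex_vivo_surface, exterior_params.sigma)
    logger.info("R2: exterior-to-ex-vivo dissimilarity %.4g -> %.4g",
                before, after)
    return [b.chain for b in blocks], exterior_chain


def stack_to_surface(stack: BlockfaceStack | None, segs: list[Image2D],
                     target_spacing: float = 1.0,
                     smooth_iters: int = 10) -> TriangleMesh:
    """Block surface from stacked blockface segmentations.

    The segmentation stack is far finer along z (50 um) than in-plane;
    it is resampled to near-isotropic ``target_spacing`` before marching
    cubes so face counts stay tractable for the currents matching.
    """
    vals = np.stack([s.values for s in segs], axis=-1)
    first = segs[0]
    dz = segs[1].section_depth - segs[0].section_depth if len(segs) > 1 \
        else target_spacing
    spacing = np.array([first.spacing[0], first.spacing[1], dz])
    origin = np.array([first.origin[0], first.origin[1],
                       segs[0].section_depth])
    factors = np.maximum(1, np.round(target_spacing / spacing).astype(int))
    # bin-averaged downsampling keeps the tissue boundary in place (plain
    # striding can clip up to a voxel off the block extent along z)
    coarse = measure.block_reduce(vals, tuple(factors), np.mean)
    new_origin = origin + (factors - 1) / 2.0 * spacing
    vol = LabelVolume((coarse >= 0.5).astype(float), spacing * factors,
                      new_origin)
    return surface_from_labels(vol, 0.5, smooth_iters=smooth_iters)
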