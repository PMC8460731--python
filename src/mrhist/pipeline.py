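"""End-to-end composition: ex-vivo-to-in-vivo registration (R3), full
chain assembly, volumetric histology label construction in the in vivo
frame, and inverse mapping of MR onto histology planes.

The full chain for a histology section runs

    histology 2D -> (R1) block plane 2D -> embed at section depth
    -> (R2 per-block) reconstructed frame -> (R2 exterior) ex vivo
    -> (R3) in vivo

and every stage is a Diffeomorphism/affine chain, so the composition is
invertible within tolerance; inverting it pulls in vivo MR intensities
onto any histology plane.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt

from .blocks import (
    BlockSurfaceSet,
    trim_near_planes,
    align_blockface_stack,
    lighting_difference,
    match_section_to_blockface,
    reconstruct_blocks,
    register_histology_to_blockface,
    stack_to_surface,
    surface_from_labels,
)
from .geometry import (
    GeometryError,
    Image2D,
    ImageVolume,
    LabelVolume,
    PlanarEmbedding,
    TransformChain,
    TriangleMesh,
    merge_meshes,
)
from .imagereg import ImageRegParams
from .metrics import (
    cumulative_error,
    label_table,
    precision_recall_dice,
)
from .surface import (
    CurrentsParams,
    affine_register_surfaces,
    diffeo_register_surfaces,
)

logger = logging.getLogger(__name__)

__all__ = [
    "register_exvivo_to_invivo",
    "build_full_chain",
    "build_histology_volume",
    "resample_mr_onto_histology",
    "PipelineResult",
    "run_phantom_pipeline",
]


# ---------------------------------------------------------------------------
# R3: ex vivo -> in vivo feature-surface registration
# ---------------------------------------------------------------------------

def register_exvivo_to_invivo(feature_surfaces_ex: list[TriangleMesh],
                              feature_surfaces_in: list[TriangleMesh],
                              params: CurrentsParams | None = None,
                              domain_bounds=None) -> TransformChain:
    """Affine + diffeomorphism mapping ex vivo coordinates to in vivo.

    Corresponding feature surfaces (vessels, tumor, treatment features
    visible in both T2w spaces) are listed in the same order; their union
    drives a single currents registration -- no landmarks involved.
    """
    if len(feature_surfaces_ex) != len(feature_surfaces_in):
        raise GeometryError("feature surface lists must correspond 1:1")
    if not feature_surfaces_ex:
        raise GeometryError("need at least one feature surface")
    params = params or CurrentsParams(
        sigma=2.0, velocity_kernel_scale=6.0, regularization=0.3,
        max_iters=40, flow_steps=5, max_control_points=500,
        convergence_tol=1e-5)
    moving = merge_meshes(feature_surfaces_ex)
    target = merge_meshes(feature_surfaces_in)
    if domain_bounds is None:
        pts = np.vstack([moving.vertices, target.vertices])
        pad = 2.0 * params.velocity_kernel_scale
        domain_bounds = (pts.min(axis=0) - pad, pts.max(axis=0) + pad)
    aff = affine_register_surfaces(moving, target, params)
    pre = moving.transformed(aff.transform)
    deff = diffeo_register_surfaces(pre, target, params,
                                    domain_bounds=domain_bounds)
    logger.info("R3: currents dissimilarity %.4g -> %.4g",
                aff.energies[0], deff.energies[-1])
    return TransformChain([(aff.transform, "forward"),
                           (deff.transform, "forward")])


# ---------------------------------------------------------------------------
# Chain assembly
# ---------------------------------------------------------------------------

def build_full_chain(r1_chain: TransformChain,
                     block_chain: TransformChain,
                     exterior_chain: TransformChain,
                     r3_chain: TransformChain,
                     section_depth: float) -> TransformChain:
    """Full histology-plane -> in vivo chain for one section.

    ``r1_chain`` maps histology 2D mm to block-plane 2D mm; the plane is
    embedded at ``section_depth`` along the slicing axis; the per-block,
    exterior and R3 chains then carry the 3D point into the in vivo frame.
    """
    stages = {"r1": r1_chain, "block": block_chain,
              "exterior": exterior_chain, "r3": r3_chain}
    for name, ch in stages.items():
        if ch is None:
            raise GeometryError(f"missing pipeline stage: {name}")
    full = TransformChain()
    full.extend(r1_chain)
    full.append(PlanarEmbedding(section_depth))
    full.extend(block_chain)
    full.extend(exterior_chain)
    full.extend(r3_chain)
    return full


# ---------------------------------------------------------------------------
# Volumetric histology label
# ---------------------------------------------------------------------------

def _section_sdf(seg: Image2D) -> Image2D:
    """Signed distance to the label boundary in mm (negative inside)."""
    mask = seg.values > 0.5
    if mask.any():
        inside = distance_transform_edt(mask, sampling=seg.spacing)
        outside = distance_transform_edt(~mask, sampling=seg.spacing)
        sdf = outside - inside
    else:
        sdf = np.full(seg.shape, 1e3)
    return seg.like(sdf)


@dataclass
class SectionRecord:
    """A histology section's label image and its chains."""

    depth: float
    label: Image2D
    r1_chain: TransformChain
    block_index: int


def build_histology_volume(sections: list[SectionRecord],
                           block_chains: dict[int, TransformChain],
                           target_grid: ImageVolume) -> LabelVolume:
    """Dense volumetric label in the target (in vivo) frame.

    For each tissue block, target voxels are pulled back to block space
    through the inverted 3D chain; the two histology sections bracketing
    the voxel's depth contribute signed-distance values (sampled in their
    own histology frames through the inverted R1 chains), interpolated
    linearly along the sectioning axis and thresholded at zero.
    """
    if len(sections) < 2:
        raise GeometryError("need at least two sections")
    pts = target_grid.world_coords().reshape(-1, 3)
    n = len(pts)
    # adjacent blocks can disagree slightly where their chains meet; a
    # distance-weighted blend of their signed-distance contributions
    # avoids label discontinuities at the seams
    sdf_num = np.zeros(n)
    sdf_den = np.zeros(n)

    by_block: dict[int, list[SectionRecord]] = {}
    for rec in sections:
        by_block.setdefault(rec.block_index, []).append(rec)

    for b, recs in by_block.items():
        recs = sorted(recs, key=lambda r: r.depth)
        depths = np.array([r.depth for r in recs])
        if len(recs) == 1:
            continue
        spacing = float(np.median(np.diff(depths)))
        sdfs = [_section_sdf(r.label) for r in recs]
        back = block_chains[b].inverted().transform_points(
            pts, check_domain=False)
        z = back[:, 2]
        z_lo = depths[0] - 0.5 * spacing
        z_hi = depths[-1] + 0.5 * spacing
        inside = (z >= z_lo) & (z <= z_hi)
        if not inside.any():
            continue
        idx = np.nonzero(inside)[0]
        zin = np.clip(z[idx], depths[0], depths[-1])
        hi = np.clip(np.searchsorted(depths, zin), 1, len(depths) - 1)
        lo = hi - 1
        w = (zin - depths[lo]) / (depths[hi] - depths[lo])
        plane_pts = back[idx, :2]
        vals = np.zeros(len(idx))
        for s in range(len(recs)):
            wgt = np.where(lo == s, 1.0 - w, 0.0) + np.where(hi == s, w, 0.0)
            m = wgt > 0
            if not m.any():
                continue
            h = recs[s].r1_chain.inverted().transform_points(
                plane_pts[m], check_domain=False)
            v = sdfs[s].sample(h, order=1, fill=1e3)
            vals[m] += wgt[m] * v
        # block weight ramps down over the outermost half-spacing of its
        # sampled range so overlapping blocks blend instead of competing
        ramp = 0.5 * spacing
        edge = np.minimum(z[idx] - z_lo, z_hi - z[idx])
        wb = np.clip(edge / ramp, 0.0, 1.0) + 1e-6
        sdf_num[idx] += wb * vals
        sdf_den[idx] += wb

    sdf = np.where(sdf_den > 0, sdf_num / np.maximum(sdf_den, 1e-300), np.inf)
    label = (sdf <= 0.0).astype(float).reshape(target_grid.shape)
    return LabelVolume(label, target_grid.spacing, target_grid.origin,
                       target_grid.direction)


def resample_mr_onto_histology(mr: ImageVolume, full_chain: TransformChain,
                               section_template: Image2D,
                               interpolation: str = "linear",
                               fill: float = 0.0) -> Image2D:
    """Pull in vivo MR intensities onto a histology section's pixel grid."""
    pix = section_template.world_coords().reshape(-1, 2)
    mapped = full_chain.transform_points(pix)
    order = 0 if interpolation == "nearest" else 1
    vals = mr.sample(mapped, order=order, fill=fill)
    return section_template.like(vals.reshape(section_template.shape))


# ---------------------------------------------------------------------------
# Full phantom-driven pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    """Everything the restored pipeline produced, plus evaluation."""

    mode: str
    r1_chains: dict[tuple[int, int], TransformChain]
    block_chains: list[TransformChain]
    exterior_chain: TransformChain
    r3_chain: TransformChain
    histology_volume: LabelVolume | None
    tre: dict[str, dict] = field(default_factory=dict)
    biomarker_table: object = None
    timings: dict[str, float] = field(default_factory=dict)
    dice_vs_truth: float | None = None
    z_errors: dict[str, float] = field(default_factory=dict)


def run_phantom_pipeline(phantom, exvivo, blocks,
                         mode: str = "full3d",
                         face_params: CurrentsParams | None = None,
                         exterior_params: CurrentsParams | None = None,
                         r3_params: CurrentsParams | None = None,
                         r1_params: ImageRegParams | None = None,
                         run_stack_alignment: bool = True,
                         build_volume: bool = True,
                         surface_spacing: float = 0.5,
                         center_mode: str = "middle") -> PipelineResult:
    """Run R1 -> R2 -> R3 -> composition -> evaluation on a simulated study.

    ``phantom, exvivo, blocks`` come from :mod:`mrhist.phantom`.  Ground
    truth is used only for evaluation, never to drive registration.
    """
    timings: dict[str, float] = {}
    # an end block can come out of slicing with essentially no tissue
    # (the sample tapers); it contributes nothing to reconstruct
    kept = [blk for blk in blocks
            if sum(s.values.sum() for s in blk.blockface_segs) > 0]
    if len(kept) < len(blocks):
        dropped = [blk.index for blk in blocks if blk not in kept]
        logger.warning("dropping tissue-free blocks %s", dropped)
    blocks = kept
    nb = len(blocks)

    # ---- blockface stacks (alignment exercises the lighting difference) --
    t0 = time.perf_counter()
    stacks = []
    for blk in blocks:
        if run_stack_alignment:
            diffs = [lighting_difference(p, q) for p, q in
                     zip(blk.blockfaces, blk.blockfaces_perpendicular)]
            stack = align_blockface_stack(
                diffs, ImageRegParams(pyramid_levels=(2,), max_iters=10,
                                      affine_max_iters=20))
        else:
            stack = align_blockface_stack(
                blk.blockfaces[:2], ImageRegParams(pyramid_levels=(2,),
                                                   max_iters=1,
                                                   affine_max_iters=1))
        stacks.append(stack)
    timings["stack"] = time.perf_counter() - t0

    # ---- R1: histology -> blockface ------------------------------------
    t0 = time.perf_counter()
    r1_params = r1_params or ImageRegParams(pyramid_levels=(2, 1),
                                            max_iters=40,
                                            convergence_tol=1e-6)
    r1_chains: dict[tuple[int, int], TransformChain] = {}
    r1_errors = []
    for pos, blk in enumerate(blocks):
        for si, sec in enumerate(blk.sections):
            stack = stacks[pos]
            if run_stack_alignment:
                bf_idx = match_section_to_blockface(sec.depth, stack)
                bf_seg = blk.blockface_segs[bf_idx]
            else:
                k = int(round((sec.depth - blk.z0) /
                              (blk.blockfaces[1].section_depth -
                               blk.blockfaces[0].section_depth)))
                bf_seg = blk.blockface_segs[k]
            if sec.histology_seg.values.sum() == 0 or \
                    bf_seg.values.sum() == 0:
                continue  # slide before the tissue starts / after it ends
            chain, _ = register_histology_to_blockface(sec.histology_seg,
                                                       bf_seg, r1_params)
            r1_chains[(blk.index, si)] = chain
            if len(sec.landmarks_hist):
                rec = chain.transform_points(sec.landmarks_hist)
                r1_errors.extend(
                    np.linalg.norm(rec - sec.landmarks_plane, axis=1))
    timings["r1"] = time.perf_counter() - t0
    r1_errors = np.asarray(r1_errors)

    # ---- R2: block reconstruction ---------------------------------------
    t0 = time.perf_counter()
    bss = []
    for pos, blk in enumerate(blocks):
        # face meshes stay unsmoothed: Taubin rounds each block's rim
        # toward its own interior, which biases facing cut faces toward
        # each other along z
        fine = stack_to_surface(stacks[pos], blk.blockface_segs,
                                target_spacing=surface_spacing,
                                smooth_iters=0)
        try:
            coarse = stack_to_surface(stacks[pos], blk.blockface_segs,
                                      target_spacing=max(1.0,
                                                         surface_spacing),
                                      smooth_iters=10)
        except GeometryError:
            coarse = fine  # sliver block vanishes at coarse resolution
        cut_planes = (None if pos == 0 else blk.z0,
                      None if pos == nb - 1 else blk.z1)
        bss.append(BlockSurfaceSet.from_surface(
            blk.index, fine, coarse_surface=coarse, cut_planes=cut_planes))
    ex_surface = surface_from_labels(exvivo.tissue_mask, smooth_iters=10)
    interior_cuts = [blk.z1 for blk in blocks[:-1]]
    ex_surface = trim_near_planes(ex_surface, interior_cuts)
    center = len(bss) // 2 if center_mode == "middle" else None
    chains_list, exterior_chain = reconstruct_blocks(
        bss, ex_surface, face_params, exterior_params, mode=mode,
        center=center)
    block_chains = {blk.index: ch for blk, ch in zip(blocks, chains_list)}
    timings["r2"] = time.perf_counter() - t0

    r2_errors = []
    r2_z_errors = []
    for blk, bs in zip(blocks, bss):
        lm = blk.landmarks_block.points
        rec = exterior_chain.transform_points(bs.chain.transform_points(lm))
        diff = rec - blk.landmarks_exvivo.points
        r2_errors.extend(np.linalg.norm(diff, axis=1))
        r2_z_errors.extend(np.abs(diff[:, 2]))
    r2_errors = np.asarray(r2_errors)
    r2_z_errors = np.asarray(r2_z_errors)

    # ---- R3: ex vivo -> in vivo ------------------------------------------
    t0 = time.perf_counter()
    names = sorted(set(exvivo.feature_meshes) & set(phantom.feature_meshes))
    lo, hi = phantom.image.bounds()
    r3_chain = register_exvivo_to_invivo(
        [exvivo.feature_meshes[n] for n in names],
        [phantom.feature_meshes[n] for n in names],
        r3_params, domain_bounds=(lo - 8.0, hi + 8.0))
    timings["r3"] = time.perf_counter() - t0

    rec = r3_chain.transform_points(exvivo.landmarks_exvivo.points)
    r3_errors = np.linalg.norm(rec - exvivo.landmarks_invivo.points, axis=1)

    # ---- composed chains and end-to-end TRE ------------------------------
    composed_errors = []
    for blk in blocks:
        for si, sec in enumerate(blk.sections):
            if not len(sec.landmarks_hist) or \
                    (blk.index, si) not in r1_chains:
                continue
            full = build_full_chain(r1_chains[(blk.index, si)],
                                    block_chains[blk.index], exterior_chain,
                                    r3_chain, sec.depth)
            mapped = full.transform_points(sec.landmarks_hist)
            anc = _ancestors(exvivo, blk, sec)
            composed_errors.extend(np.linalg.norm(mapped - anc, axis=1))
    composed_errors = np.asarray(composed_errors)

    # ---- volumetric histology necrosis label -----------------------------
    hist_volume = None
    dice = None
    table = None
    if build_volume:
        t0 = time.perf_counter()
        sections = []
        for blk in blocks:
            for si, sec in enumerate(blk.sections):
                if (blk.index, si) not in r1_chains:
                    continue
                sections.append(SectionRecord(sec.depth, sec.necrosis_seg,
                                              r1_chains[(blk.index, si)],
                                              blk.index))
        chains3d = {
            blk.index: TransformChain()
            .extend(block_chains[blk.index])
            .extend(exterior_chain)
            .extend(r3_chain)
            for blk in blocks
        }
        hist_volume = build_histology_volume(sections, chains3d,
                                             phantom.necrosis)
        timings["histvol"] = time.perf_counter() - t0
        _, _, dice = precision_recall_dice(hist_volume, phantom.necrosis)
        table = label_table({"acute_npv": phantom.acute_npv,
                             "post_npv": phantom.post_npv}, hist_volume)

    def stats(arr):
        return {"mean": float(arr.mean()), "sd": float(arr.std(ddof=0)),
                "n": int(arr.size)} if arr.size else \
            {"mean": np.nan, "sd": np.nan, "n": 0}

    tre = {"r1": stats(r1_errors), "r2": stats(r2_errors),
           "r3": stats(r3_errors), "composed": stats(composed_errors)}
    tre["cumulative"] = {"mean": cumulative_error(
        [tre["r1"]["mean"], tre["r2"]["mean"], tre["r3"]["mean"]])}

    return PipelineResult(
        mode=mode, r1_chains=r1_chains, block_chains=block_chains,
        exterior_chain=exterior_chain, r3_chain=r3_chain,
        histology_volume=hist_volume, tre=tre, biomarker_table=table,
        timings=timings, dice_vs_truth=dice,
        z_errors={"r2_mean_abs_z": float(r2_z_errors.mean())},
    )


def _ancestors(exvivo, blk, sec) -> np.ndarray:
    """Ground-truth in vivo positions of a section's plane landmarks."""
    plane = sec.landmarks_plane
    pts3 = np.column_stack([plane, np.full(len(plane), sec.depth)])
    ex = (blk.gt_chain.inverted().transform_points(pts3)
          if len(blk.gt_chain) else pts3)
    return exvivo.gt_chain.inverted().transform_points(ex)
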