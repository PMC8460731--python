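"""Synthetic destructive-histopathology simulator.

Generates a digital tissue volume (an agar-embedded quadriceps surrogate
with an internal necrosis lesion, a surrounding tumor blob, and tubular
vessel features), then replays the destructive steps of histology
processing with *known* ground-truth transforms:

* excision/fixation -- a smooth random diffeomorphism plus a small rigid
  perturbation mapping the in vivo frame to the ex vivo frame;
* gross slicing -- axis-aligned ~3 mm cuts along the head-foot (z) axis,
  each block receiving an independent small rigid + smooth deformation;
* microtome sectioning -- blockface images every 50 um (with simulated
  paraffin show-through under two lighting conditions) and histology
  sections every 250 um, each section under an independent smooth 2D
  distortion.

All tissue shapes are analytic implicit functions in the in vivo frame,
and every stage image is rendered by mapping its grid points back through
the exact ground-truth transform chain, so masks and landmarks are
consistent across stages to the transform-inversion tolerance.  The
ground-truth chain is the oracle for every registration-recovery test.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import (
    Affine,
    Diffeomorphism,
    GeometryError,
    Image2D,
    ImageVolume,
    LabelVolume,
    LandmarkSet,
    RegularGrid,
    TransformChain,
    TriangleMesh,
)

__all__ = [
    "PhantomSpec",
    "Phantom",
    "ExVivoSample",
    "SimulatedBlock",
    "SimulatedSection",
    "generate_phantom",
    "simulate_excision",
    "simulate_gross_slicing",
    "simulate_sectioning",
    "simulate_full",
    "make_smooth_diffeomorphism",
]

# Stage-specific intensity palettes: contrasts deliberately differ between
# stages so no registration step can succeed by intensity identity.
PALETTES = {
    "invivo": {"bg": 0.05, "tissue": 1.0, "tumor": 1.35, "necrosis": 1.7,
               "vessel": 0.5},
    "exvivo": {"bg": 0.05, "tissue": 0.9, "tumor": 1.5, "necrosis": 1.15,
               "vessel": 0.4},
    "blockface": {"bg": 0.1, "tissue": 0.8, "tumor": 0.55, "necrosis": 0.35,
                  "vessel": 0.7},
    "histology": {"bg": 0.05, "tissue": 0.6, "tumor": 0.78, "necrosis": 0.95,
                  "vessel": 0.45},
}


@dataclass
class PhantomSpec:
    """Geometry and degradation parameters of the synthetic study.

    Defaults model the study conditions: ~15 mm of tissue along the
    head-foot axis sliced into 3 mm blocks, blockface imaging every
    50 um, histology sections every 250 um, five evaluation landmarks
    per registration stage.  Deformation magnitudes (excision 2 mm,
    per-block 0.8 mm, per-section 0.4 mm) are chosen so the per-stage
    ground-truth displacements bracket sub-millimeter stage errors.
    """

    volume_size_mm: tuple[float, float, float] = (26.0, 26.0, 22.0)
    voxel_spacing_mm: float = 1.0
    tissue_radii_mm: tuple[float, float, float] = (10.0, 9.5, 7.5)
    lesion_center_mm: tuple[float, float, float] = (1.0, -0.5, 0.5)
    lesion_radii_mm: tuple[float, float, float] = (4.6, 4.2, 3.6)
    tumor_radii_mm: tuple[float, float, float] = (6.4, 6.0, 5.2)
    vessel_count: int = 2
    vessel_radius_mm: float = 1.6
    blob_count: int = 1
    excision_magnitude_mm: float = 2.0
    excision_smoothness_mm: float = 7.0
    block_thickness_mm: float = 3.0
    block_magnitude_mm: float = 0.8
    block_smoothness_mm: float = 5.0
    block_axis_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    section_spacing_um: float = 250.0
    blockface_spacing_um: float = 50.0
    section_magnitude_mm: float = 0.4
    section_smoothness_mm: float = 4.0
    section_pixel_mm: float = 0.5
    landmark_count: int = 5
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_spacing_mm <= 0 or self.section_pixel_mm <= 0:
            raise GeometryError("spacings must be positive")
        if min(self.excision_magnitude_mm, self.block_magnitude_mm,
               self.section_magnitude_mm) < 0:
            raise GeometryError("deformation magnitudes must be >= 0")
        if self.block_thickness_mm <= self.section_spacing_um / 1000.0:
            raise GeometryError("block thickness must exceed section spacing")
        lesion_hi = np.abs(np.asarray(self.lesion_center_mm)) + \
            np.asarray(self.lesion_radii_mm)
        if np.any(lesion_hi >= np.asarray(self.tissue_radii_mm)):
            raise GeometryError("necrosis lesion must lie inside the tissue")

    @property
    def section_spacing_mm(self) -> float:
        return self.section_spacing_um / 1000.0

    @property
    def blockface_spacing_mm(self) -> float:
        return self.blockface_spacing_um / 1000.0


# ---------------------------------------------------------------------------
# Analytic anatomy in the in vivo frame
# ---------------------------------------------------------------------------

class _Anatomy:
    """Implicit-function tissue model evaluated at in vivo points.

    The tissue boundary is an ellipsoid with smooth angular irregularity
    (low-order harmonics of the in-plane radius, drifting slowly along
    z).  Real muscle cross-sections are irregular, and that irregularity
    is what anchors in-plane registration of the flat cut faces; a
    perfectly elliptical cross-section is rotationally near-symmetric
    and would make the block faces artificially uninformative.
    """

    def __init__(self, spec: PhantomSpec, rng: np.random.Generator):
        self.spec = spec
        self.tissue_radii = np.asarray(spec.tissue_radii_mm)
        self.lesion_center = np.asarray(spec.lesion_center_mm)
        self.lesion_radii = np.asarray(spec.lesion_radii_mm)
        self.tumor_radii = np.asarray(spec.tumor_radii_mm)
        # boundary harmonics: order, amplitude, phase, z-drift of phase
        self._harmonics = [
            (2, rng.uniform(0.04, 0.07), rng.uniform(0, 2 * np.pi),
             rng.uniform(-0.08, 0.08)),
            (3, rng.uniform(0.05, 0.08), rng.uniform(0, 2 * np.pi),
             rng.uniform(-0.08, 0.08)),
            (5, rng.uniform(0.03, 0.05), rng.uniform(0, 2 * np.pi),
             rng.uniform(-0.08, 0.08)),
        ]
        # vessels: straight tubes through the tissue at random orientations
        self.vessels = []
        for _ in range(spec.vessel_count):
            direction = rng.normal(size=3)
            direction[2] = abs(direction[2]) + 0.8  # cross several blocks
            direction /= np.linalg.norm(direction)
            offset = rng.uniform(-0.45, 0.45, size=3) * self.tissue_radii
            offset += self.lesion_center * 0.3
            self.vessels.append((offset, direction))

    def _boundary_factor(self, pts: np.ndarray) -> np.ndarray:
        theta = np.arctan2(pts[:, 1], pts[:, 0])
        z = pts[:, 2]
        f = np.ones(len(pts))
        for order, amp, phase, drift in self._harmonics:
            f += amp * np.cos(order * theta + phase + drift * z)
        return f

    def tissue(self, pts: np.ndarray) -> np.ndarray:
        return np.sum((pts / self.tissue_radii) ** 2, axis=1) <= \
            self._boundary_factor(pts) ** 2

    def tumor(self, pts: np.ndarray) -> np.ndarray:
        d = (pts - self.lesion_center) / self.tumor_radii
        return np.sum(d**2, axis=1) <= 1.0

    def necrosis(self, pts: np.ndarray) -> np.ndarray:
        d = (pts - self.lesion_center) / self.lesion_radii
        return np.sum(d**2, axis=1) <= 1.0

    def vessel(self, pts: np.ndarray, i: int) -> np.ndarray:
        offset, direction = self.vessels[i]
        rel = pts - offset
        along = rel @ direction
        radial = rel - np.outer(along, direction)
        return (np.linalg.norm(radial, axis=1) <= self.spec.vessel_radius_mm) \
            & self.tissue(pts)

    def any_vessel(self, pts: np.ndarray) -> np.ndarray:
        out = np.zeros(len(pts), dtype=bool)
        for i in range(len(self.vessels)):
            out |= self.vessel(pts, i)
        return out

    def classes(self, pts: np.ndarray) -> np.ndarray:
        """Class index per point: 0 bg, 1 tissue, 2 tumor, 3 necrosis, 4 vessel."""
        out = np.zeros(len(pts), dtype=np.int8)
        t = self.tissue(pts)
        out[t] = 1
        out[t & self.tumor(pts)] = 2
        out[t & self.necrosis(pts)] = 3
        v = self.any_vessel(pts) & ~self.necrosis(pts)
        out[v] = 4
        return out


def _render(classes: np.ndarray, palette: dict, rng: np.random.Generator,
            noise_sd: float, shape) -> np.ndarray:
    lut = np.array([palette["bg"], palette["tissue"], palette["tumor"],
                    palette["necrosis"], palette["vessel"]])
    vals = lut[classes].reshape(shape)
    if noise_sd > 0:
        bias = gaussian_filter(rng.normal(size=shape), sigma=6.0)
        bias = 1.0 + 0.1 * bias / max(np.abs(bias).max(), 1e-12)
        vals = vals * bias + rng.normal(scale=noise_sd, size=shape)
    return vals


# ---------------------------------------------------------------------------
# Random smooth diffeomorphisms (ground-truth deformations)
# ---------------------------------------------------------------------------

def make_smooth_diffeomorphism(lo, hi, magnitude: float, smoothness: float,
                               rng: np.random.Generator, dim: int = 3,
                               n_steps: int = 4,
                               inplane_only: bool = False,
                               axis_weights=None) -> Diffeomorphism:
    """Gaussian-smoothed random stationary velocity field over a box.

    The velocity is scaled so the maximum node speed equals ``magnitude``
    (mm); since the flow time is 1, no point moves farther than
    ``magnitude``.  Folding at a requested amplitude triggers regeneration
    at reduced amplitude with a warning.
    """
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    spacing = max(smoothness / 2.5, float((hi - lo).max()) / 48.0)
    grid = RegularGrid.from_bounds(lo, hi, spacing)
    amp = magnitude
    for _ in range(6):
        V = np.stack(
            [gaussian_filter(rng.normal(size=grid.shape),
                             sigma=smoothness / spacing)
             for _ in range(dim)], axis=-1)
        if inplane_only and dim == 3:
            V[..., 2] = 0.0
        if axis_weights is not None:
            V = V * np.asarray(axis_weights, dtype=float)
        speeds = np.linalg.norm(V.reshape(-1, dim), axis=1)
        vmax = speeds.max()
        if vmax > 0 and amp > 0:
            V *= amp / vmax
        else:
            V[:] = 0.0
        diffeo = Diffeomorphism.from_stationary_velocity(grid, V,
                                                         n_steps=n_steps)
        diffeo.fp_iters = 12
        if np.all(diffeo.jacobian_determinants() > 0):
            return diffeo
        import warnings
        warnings.warn("smooth deformation folded; regenerating at reduced "
                      "amplitude", RuntimeWarning, stacklevel=2)
        amp *= 0.7
    raise GeometryError("could not generate a fold-free deformation")


def _small_rigid(rng: np.random.Generator, max_angle_deg: float,
                 max_shift_mm: float, dim: int = 3,
                 inplane_only: bool = False) -> Affine:
    if dim == 2:
        ang = rng.uniform(-max_angle_deg, max_angle_deg)
        A = Affine.rotation_z(ang, dim=2)
        return Affine(A.linear, rng.uniform(-max_shift_mm, max_shift_mm, 2))
    axis = rng.normal(size=3)
    if inplane_only:
        axis = np.array([0.0, 0.0, 1.0])
    axis /= np.linalg.norm(axis)
    ang = np.deg2rad(rng.uniform(-max_angle_deg, max_angle_deg))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
    t = rng.uniform(-max_shift_mm, max_shift_mm, 3)
    if inplane_only:
        t[2] = rng.uniform(-max_shift_mm, max_shift_mm)
    return Affine(R, t)


# ---------------------------------------------------------------------------
# Stage containers
# ---------------------------------------------------------------------------

@dataclass
class Phantom:
    """In vivo ground truth: image, labels, feature meshes, landmarks."""

    spec: PhantomSpec
    anatomy: _Anatomy
    image: ImageVolume
    tissue_mask: LabelVolume
    necrosis: LabelVolume
    acute_npv: LabelVolume
    post_npv: LabelVolume
    feature_meshes: dict[str, TriangleMesh]
    landmarks: LandmarkSet


@dataclass
class ExVivoSample:
    image: ImageVolume
    tissue_mask: LabelVolume
    feature_meshes: dict[str, TriangleMesh]
    gt_chain: TransformChain          # in vivo -> ex vivo
    landmarks_exvivo: LandmarkSet     # ground-truth ex vivo positions
    landmarks_invivo: LandmarkSet     # their in vivo ancestors


@dataclass
class SimulatedSection:
    depth: float                      # block-space z of the section plane
    histology: Image2D
    histology_seg: Image2D
    necrosis_seg: Image2D
    gt_chain_2d: TransformChain       # block-plane (u,v) -> histology (u,v)
    landmarks_hist: np.ndarray        # K x 2, histology coordinates
    landmarks_plane: np.ndarray       # K x 2, true block-plane coordinates


@dataclass
class SimulatedBlock:
    index: int
    z0: float
    z1: float
    volume: ImageVolume               # blockface-contrast voxel stack
    tissue_mask: LabelVolume
    gt_chain: TransformChain          # ex vivo -> block space
    blockfaces: list[Image2D] = dc_field(default_factory=list)
    blockfaces_perpendicular: list[Image2D] = dc_field(default_factory=list)
    blockface_segs: list[Image2D] = dc_field(default_factory=list)
    sections: list[SimulatedSection] = dc_field(default_factory=list)
    landmarks_block: LandmarkSet | None = None
    landmarks_exvivo: LandmarkSet | None = None


# ---------------------------------------------------------------------------
# Stage generators
# ---------------------------------------------------------------------------

def _volume_grid(spec: PhantomSpec):
    size = np.asarray(spec.volume_size_mm)
    sp = spec.voxel_spacing_mm
    shape = tuple(int(round(s / sp)) + 1 for s in size)
    origin = -size / 2.0
    return shape, origin, np.full(3, sp)


def _sample_inside(rng, test, lo, hi, count):
    pts = []
    while len(pts) < count:
        cand = rng.uniform(lo, hi, size=(4 * count, 3))
        keep = cand[test(cand)]
        pts.extend(keep.tolist())
    return np.asarray(pts[:count])


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Render the in vivo stage: image, labels, feature meshes, landmarks."""
    rng = np.random.default_rng(spec.seed)
    anatomy = _Anatomy(spec, rng)
    shape, origin, spacing = _volume_grid(spec)
    vol = ImageVolume(np.zeros(shape), spacing, origin)
    pts = vol.world_coords().reshape(-1, 3)
    classes = anatomy.classes(pts)
    image = vol.like(_render(classes, PALETTES["invivo"], rng, spec.noise_sd,
                             shape))
    tissue = LabelVolume(anatomy.tissue(pts).reshape(shape).astype(float),
                         spacing, origin)
    necrosis = LabelVolume(
        (anatomy.necrosis(pts) & anatomy.tissue(pts)).reshape(shape)
        .astype(float), spacing, origin)
    # NPV surrogates: the acute NPV over-predicts necrosis (transient
    # perfusion effects), the follow-up NPV over-predicts mildly
    c = anatomy.lesion_center
    acute = np.sum(((pts - c) / (anatomy.lesion_radii * 1.35)) ** 2,
                   axis=1) <= 1.0
    lobe_c = c + np.array([anatomy.lesion_radii[0] * 1.2, 1.0, 0.5])
    acute |= np.sum(((pts - lobe_c) / 2.4) ** 2, axis=1) <= 1.0
    acute &= anatomy.tissue(pts)
    post = np.sum(((pts - c) / (anatomy.lesion_radii * 1.1)) ** 2,
                  axis=1) <= 1.0
    post &= anatomy.tissue(pts)
    acute_npv = LabelVolume(acute.reshape(shape).astype(float), spacing,
                            origin)
    post_npv = LabelVolume(post.reshape(shape).astype(float), spacing, origin)

    meshes = _feature_meshes(anatomy, vol)
    lm_pts = _sample_inside(rng, anatomy.tissue,
                            origin, origin + np.asarray(spec.volume_size_mm),
                            spec.landmark_count)
    landmarks = LandmarkSet(lm_pts,
                            [f"iv{i}" for i in range(len(lm_pts))], "invivo")
    return Phantom(spec, anatomy, image, tissue, necrosis, acute_npv,
                   post_npv, meshes, landmarks)


def _feature_meshes(anatomy: _Anatomy, vol: ImageVolume,
                    chain: TransformChain | None = None) -> dict:
    """Marching-cubes surfaces of tumor and vessels, optionally deformed."""
    from .blocks import surface_from_labels

    pts = vol.world_coords().reshape(-1, 3)
    if chain is not None:
        pts = chain.inverted().transform_points(pts)
    shape = vol.shape
    out = {}
    tumor = (anatomy.tumor(pts) & anatomy.tissue(pts)).reshape(shape)
    out["tumor"] = surface_from_labels(
        LabelVolume(tumor.astype(float), vol.spacing, vol.origin), 0.5)
    for i in range(len(anatomy.vessels)):
        v = anatomy.vessel(pts, i).reshape(shape)
        if v.sum() > 8:
            out[f"vessel{i}"] = surface_from_labels(
                LabelVolume(v.astype(float), vol.spacing, vol.origin), 0.5)
    return out


def simulate_excision(phantom: Phantom,
                      spec: PhantomSpec | None = None) -> ExVivoSample:
    """Apply the excision/fixation deformation; return the ex vivo stage."""
    spec = spec or phantom.spec
    rng = np.random.default_rng(spec.seed + 1)
    vol = phantom.image
    lo, hi = vol.bounds()
    pad = 3.0
    diffeo = make_smooth_diffeomorphism(lo - pad, hi + pad,
                                        spec.excision_magnitude_mm,
                                        spec.excision_smoothness_mm, rng)
    rigid = _small_rigid(rng, max_angle_deg=2.0, max_shift_mm=0.8)
    chain = TransformChain([(rigid, "forward"), (diffeo, "forward")])

    shape, origin, spacing = _volume_grid(spec)
    grid_vol = ImageVolume(np.zeros(shape), spacing, origin)
    pts = grid_vol.world_coords().reshape(-1, 3)
    back = chain.inverted().transform_points(pts)
    classes = phantom.anatomy.classes(back)
    image = grid_vol.like(_render(classes, PALETTES["exvivo"], rng,
                                  spec.noise_sd, shape))
    tissue = LabelVolume(
        phantom.anatomy.tissue(back).reshape(shape).astype(float),
        spacing, origin)
    meshes = _feature_meshes(phantom.anatomy, grid_vol, chain)
    lm_ex = chain.transform_points(phantom.landmarks.points)
    lms_ex = LandmarkSet(lm_ex, list(phantom.landmarks.labels), "exvivo")
    return ExVivoSample(image, tissue, meshes, chain, lms_ex,
                        phantom.landmarks)


def simulate_gross_slicing(phantom: Phantom, exvivo: ExVivoSample,
                           spec: PhantomSpec | None = None
                           ) -> list[SimulatedBlock]:
    """Cut the ex vivo tissue into ~3 mm blocks with independent deformations."""
    spec = spec or phantom.spec
    tissue = exvivo.tissue_mask
    occupied = np.nonzero(tissue.values.sum(axis=(0, 1)) > 0)[0]
    if len(occupied) == 0:
        raise GeometryError("ex vivo tissue mask is empty")
    zs = tissue.voxel_to_world(
        np.array([[0, 0, occupied[0]], [0, 0, occupied[-1]]], dtype=float)
    )[:, 2]
    z_min, z_max = float(zs[0]) - 0.5 * tissue.spacing[2], \
        float(zs[1]) + 0.5 * tissue.spacing[2]
    extent = z_max - z_min
    if spec.block_thickness_mm > extent:
        raise GeometryError("block thickness exceeds tissue extent")
    # "~3 mm increments": the sample is divided into equal blocks as close
    # to the nominal thickness as possible -- no thin sliver at the end
    nb = max(1, int(round(extent / spec.block_thickness_mm)))
    actual = extent / nb
    blocks: list[SimulatedBlock] = []
    lo_w, hi_w = exvivo.image.bounds()
    for b in range(nb):
        z0 = z_min + b * actual
        z1 = min(z0 + actual, z_max)
        rng = np.random.default_rng(spec.seed + 100 + b)
        elements = []
        if spec.block_magnitude_mm > 0:
            rigid = _small_rigid(rng, max_angle_deg=1.5,
                                 max_shift_mm=0.3 * spec.block_magnitude_mm)
            diffeo = make_smooth_diffeomorphism(
                np.array([lo_w[0] - 3.0, lo_w[1] - 3.0, z0 - 2.0]),
                np.array([hi_w[0] + 3.0, hi_w[1] + 3.0, z1 + 2.0]),
                spec.block_magnitude_mm, spec.block_smoothness_mm, rng,
                axis_weights=spec.block_axis_weights)
            elements = [(rigid, "forward"), (diffeo, "forward")]
        chain = TransformChain(elements)
        block = _render_block(phantom, exvivo, spec, b, z0, z1, chain, rng)
        blocks.append(block)
    return blocks


def _exvivo_class_at(phantom: Phantom, exvivo: ExVivoSample,
                     pts_ex: np.ndarray, z_range=None) -> np.ndarray:
    """Class index at ex vivo points, optionally slab-restricted in z."""
    back = exvivo.gt_chain.inverted().transform_points(pts_ex)
    classes = phantom.anatomy.classes(back)
    if z_range is not None:
        inside = (pts_ex[:, 2] >= z_range[0] - 1e-9) & \
            (pts_ex[:, 2] < z_range[1] - 1e-9)
        classes = np.where(inside, classes, 0)
    return classes


def _render_block(phantom, exvivo, spec, b, z0, z1, chain, rng
                  ) -> SimulatedBlock:
    sp = spec.voxel_spacing_mm
    lo_w, hi_w = exvivo.image.bounds()
    margin = 2.0
    origin = np.array([lo_w[0], lo_w[1], z0 - margin])
    size = np.array([hi_w[0] - lo_w[0], hi_w[1] - lo_w[1],
                     (z1 - z0) + 2 * margin])
    shape = tuple(int(round(s / sp)) + 1 for s in size)
    grid_vol = ImageVolume(np.zeros(shape), np.full(3, sp), origin)
    pts = grid_vol.world_coords().reshape(-1, 3)
    pts_ex = chain.inverted().transform_points(pts) if len(chain) else pts
    classes = _exvivo_class_at(phantom, exvivo, pts_ex, (z0, z1))
    volume = grid_vol.like(_render(classes, PALETTES["blockface"], rng,
                                   spec.noise_sd, shape))
    mask = LabelVolume((classes > 0).reshape(shape).astype(float),
                       grid_vol.spacing, origin)
    block = SimulatedBlock(index=b, z0=z0, z1=z1, volume=volume,
                           tissue_mask=mask, gt_chain=chain)
    # per-block evaluation landmarks with exact ex vivo ancestors
    mid = 0.5 * (z0 + z1)
    def in_block(cand):
        cls = _exvivo_class_at(phantom, exvivo,
                               chain.inverted().transform_points(cand)
                               if len(chain) else cand, (z0, z1))
        return cls > 0
    lm = _sample_inside(rng, in_block,
                        np.array([lo_w[0], lo_w[1], mid - 1.0]),
                        np.array([hi_w[0], hi_w[1], mid + 1.0]),
                        spec.landmark_count)
    labels = [f"b{b}_{i}" for i in range(len(lm))]
    block.landmarks_block = LandmarkSet(lm, labels, f"block{b}")
    anc = chain.inverted().transform_points(lm) if len(chain) else lm
    block.landmarks_exvivo = LandmarkSet(anc, labels, "exvivo")
    return block


def simulate_sectioning(phantom: Phantom, exvivo: ExVivoSample,
                        block: SimulatedBlock,
                        spec: PhantomSpec | None = None) -> SimulatedBlock:
    """Render blockface and histology images for one block (in place)."""
    spec = spec or phantom.spec
    thickness = block.z1 - block.z0
    if thickness < spec.section_spacing_mm:
        raise GeometryError(f"block {block.index} too thin to section")
    rng = np.random.default_rng(spec.seed + 500 + block.index)
    sp2 = spec.section_pixel_mm
    lo_w, hi_w = exvivo.image.bounds()
    origin2 = np.array([lo_w[0], lo_w[1]])
    size2 = np.array([hi_w[0] - lo_w[0], hi_w[1] - lo_w[1]])
    shape2 = tuple(int(round(s / sp2)) + 1 for s in size2)
    tmpl = Image2D(np.zeros(shape2), np.full(2, sp2), origin2)
    pix = tmpl.world_coords().reshape(-1, 2)

    def planes_classes(depths: np.ndarray,
                       plane_pts: np.ndarray | None = None) -> np.ndarray:
        """Class maps for many block-space planes in one chain inversion."""
        npx = len(pix)
        base = pix if plane_pts is None else plane_pts
        if base.ndim == 2 and plane_pts is None:
            pts3 = np.column_stack([
                np.tile(pix, (len(depths), 1)),
                np.repeat(np.asarray(depths, dtype=float), npx)])
        else:
            pts3 = np.column_stack([
                base.reshape(-1, 2),
                np.repeat(np.asarray(depths, dtype=float), npx)])
        pts_ex = (block.gt_chain.inverted().transform_points(pts3)
                  if len(block.gt_chain) else pts3)
        cls = _exvivo_class_at(phantom, exvivo, pts_ex,
                               (block.z0, block.z1))
        return cls.reshape(len(depths), npx)

    # blockface images every 50 um, with paraffin show-through: the
    # perpendicular-light image contains only show-through from deeper
    # tissue; the parallel-light image adds the exposed surface
    n_bf = int(round(thickness / spec.blockface_spacing_mm))
    show_depth = 0.5  # mm of paraffin translucency
    depths_bf = block.z0 + spec.blockface_spacing_mm * np.arange(n_bf)
    cls_surface = planes_classes(depths_bf)
    cls_deeper = planes_classes(np.minimum(depths_bf + show_depth,
                                           block.z1 - 1e-6))
    for k in range(n_bf):
        d = float(depths_bf[k])
        cls = cls_surface[k]
        surface = _render(cls, PALETTES["blockface"], rng, 0.0, shape2)
        show = 0.35 * (cls_deeper[k] > 0).astype(float).reshape(shape2)
        noise = rng.normal(scale=spec.noise_sd, size=shape2)
        par = Image2D(np.clip(surface + show + noise, 0, None),
                      tmpl.spacing, tmpl.origin, d)
        perp = Image2D(np.clip(show + noise, 0, None),
                       tmpl.spacing, tmpl.origin, d)
        seg = Image2D((cls > 0).astype(float).reshape(shape2),
                      tmpl.spacing, tmpl.origin, d)
        block.blockfaces.append(par)
        block.blockfaces_perpendicular.append(perp)
        block.blockface_segs.append(seg)

    # histology sections every 250 um with independent 2D distortions
    n_sec = int(round(thickness / spec.section_spacing_mm))
    depths_sec = block.z0 + spec.section_spacing_mm * np.arange(n_sec)
    chains2, plane_pts_all, rngs = [], [], []
    for s in range(n_sec):
        srng = np.random.default_rng(spec.seed + 1000 * (block.index + 1) + s)
        elements = []
        if spec.section_magnitude_mm > 0:
            rigid2 = _small_rigid(srng, max_angle_deg=2.0,
                                  max_shift_mm=0.3 * spec.section_magnitude_mm,
                                  dim=2)
            diffeo2 = make_smooth_diffeomorphism(
                origin2 - 2.0, origin2 + size2 + 2.0,
                spec.section_magnitude_mm, spec.section_smoothness_mm,
                srng, dim=2)
            elements = [(rigid2, "forward"), (diffeo2, "forward")]
        chain2 = TransformChain(elements)
        chains2.append(chain2)
        rngs.append(srng)
        plane_pts_all.append(chain2.inverted().transform_points(pix)
                             if len(chain2) else pix)
    cls_sections = planes_classes(depths_sec, np.stack(plane_pts_all))
    cls_planes = planes_classes(depths_sec)
    for s in range(n_sec):
        d = float(depths_sec[s])
        srng, chain2 = rngs[s], chains2[s]
        cls = cls_sections[s]
        hist = Image2D(_render(cls, PALETTES["histology"], srng,
                               spec.noise_sd, shape2),
                       tmpl.spacing, tmpl.origin, d)
        seg = Image2D((cls > 0).astype(float).reshape(shape2),
                      tmpl.spacing, tmpl.origin, d)
        nec = Image2D((cls == 3).astype(float).reshape(shape2),
                      tmpl.spacing, tmpl.origin, d)
        # landmarks on the section: block-plane points inside the tissue
        inside = pix[cls_planes[s] > 0]
        if len(inside):
            pick = srng.choice(len(inside),
                               size=min(3, len(inside)), replace=False)
            lp = inside[pick]
            lh = chain2.transform_points(lp) if len(chain2) else lp.copy()
        else:
            lp = np.empty((0, 2))
            lh = np.empty((0, 2))
        block.sections.append(SimulatedSection(
            depth=d, histology=hist, histology_seg=seg, necrosis_seg=nec,
            gt_chain_2d=chain2, landmarks_hist=lh, landmarks_plane=lp))
    return block


def simulate_full(spec: PhantomSpec):
    """Run the full destructive pipeline: phantom -> ex vivo -> blocks."""
    phantom = generate_phantom(spec)
    exvivo = simulate_excision(phantom, spec)
    blocks = simulate_gross_slicing(phantom, exvivo, spec)
    for block in blocks:
        simulate_sectioning(phantom, exvivo, block, spec)
    return phantom, exvivo, blocks
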