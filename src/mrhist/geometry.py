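"""Coordinate-aware containers for images, meshes, transforms and landmarks.

All spatial quantities are expressed in world millimeters.  Images carry
their geometry (spacing, origin, direction cosines) so that registration
always operates in physical space, never in voxel indices; voxel centers
define positions and index (0, 0, 0) maps to the origin.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "GeometryError",
    "DomainError",
    "ImageVolume",
    "LabelVolume",
    "Image2D",
    "TriangleMesh",
    "Affine",
    "AffineTransform3",
    "RegularGrid",
    "Diffeomorphism",
    "PlanarEmbedding",
    "TransformChain",
    "LandmarkSet",
]


class GeometryError(ValueError):
    """Raised for invalid spatial metadata (spacing, orientation, indices)."""


class DomainError(ValueError):
    """Raised when points fall outside the domain of a spatial map."""


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

@dataclass
class ImageVolume:
    """3D scalar grid with world geometry.

    ``values`` is indexed ``[i, j, k]``; the world position of voxel
    ``(i, j, k)`` is ``origin + direction @ (spacing * (i, j, k))``.
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if self.values.ndim != 3:
            raise GeometryError("ImageVolume values must be 3D")
        if np.any(self.spacing <= 0):
            raise GeometryError("spacing must be strictly positive")
        if abs(abs(np.linalg.det(self.direction)) - 1.0) > 1e-9:
            raise GeometryError("direction matrix must be orthonormal (|det| = 1)")

    # -- voxel <-> world ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return self.origin + (self.direction @ (idx * self.spacing).T).T

    def world_to_voxel(self, x: np.ndarray) -> np.ndarray:
        """Continuous voxel index of world points (out-of-range allowed)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        local = np.linalg.solve(self.direction, (x - self.origin).T).T
        return local / self.spacing

    def world_coords(self) -> np.ndarray:
        """World positions of every voxel center, shape ``(*shape, 3)``."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"), axis=-1
        )
        flat = self.voxel_to_world(idx.reshape(-1, 3))
        return flat.reshape(*self.shape, 3)

    def sample(self, x: np.ndarray, order: int = 1, fill: float = 0.0) -> np.ndarray:
        """Interpolate intensities at world points."""
        idx = self.world_to_voxel(x)
        return map_coordinates(
            self.values, idx.T, order=order, mode="constant", cval=fill
        )

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        corners = self.voxel_to_world(
            np.array([[i, j, k] for i in (0, self.shape[0] - 1)
                      for j in (0, self.shape[1] - 1)
                      for k in (0, self.shape[2] - 1)], dtype=float)
        )
        return corners.min(axis=0), corners.max(axis=0)

    def like(self, values: np.ndarray) -> "ImageVolume":
        return ImageVolume(values, self.spacing.copy(), self.origin.copy(),
                           self.direction.copy())


class LabelVolume(ImageVolume):
    """Binary mask on an ImageVolume grid (values restricted to {0, 1})."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.values)
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise GeometryError("LabelVolume values must be binary")

    @property
    def volume_mm3(self) -> float:
        return float(self.values.sum() * self.voxel_volume)

    def like(self, values: np.ndarray) -> "LabelVolume":
        return LabelVolume(values, self.spacing.copy(), self.origin.copy(),
                           self.direction.copy())


@dataclass
class Image2D:
    """2D section image; ``values[i, j]`` sits at ``origin + spacing*(i, j)``.

    ``section_depth`` records the position of the section along the
    sectioning (z) axis of its parent block, in millimeters.
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    section_depth: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(2)
        self.origin = np.asarray(self.origin, dtype=float).reshape(2)
        if self.values.ndim != 2:
            raise GeometryError("Image2D values must be 2D")
        if np.any(self.spacing <= 0):
            raise GeometryError("spacing must be strictly positive")
        if not np.isfinite(self.section_depth):
            raise GeometryError("section_depth must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def pixel_area(self) -> float:
        return float(np.prod(self.spacing))

    def world_to_pixel(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return (x - self.origin) / self.spacing

    def pixel_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return self.origin + idx * self.spacing

    def world_coords(self) -> np.ndarray:
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"), axis=-1
        )
        return self.pixel_to_world(idx.reshape(-1, 2)).reshape(*self.shape, 2)

    def sample(self, x: np.ndarray, order: int = 1, fill: float = 0.0) -> np.ndarray:
        idx = self.world_to_pixel(x)
        return map_coordinates(
            self.values, idx.T, order=order, mode="constant", cval=fill
        )

    def like(self, values: np.ndarray) -> "Image2D":
        return Image2D(values, self.spacing.copy(), self.origin.copy(),
                       self.section_depth)


# ---------------------------------------------------------------------------
# Meshes
# ---------------------------------------------------------------------------

@dataclass
class TriangleMesh:
    """Triangular surface in world millimeters.

    Per-face quantities follow the currents convention: the face center is
    the mean of the three vertices, and the face normal is area-weighted
    (half the cross product of the edge vectors, magnitude = triangle area).
    """

    vertices: np.ndarray
    faces: np.ndarray
    degenerate_ok: bool = False
    _area_eps: float = 1e-12

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise GeometryError("face indices out of range")
        if not self.degenerate_ok and self.n_faces:
            if np.any(self.face_areas() < self._area_eps):
                raise GeometryError("mesh contains degenerate (zero-area) faces")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def _edges(self) -> tuple[np.ndarray, np.ndarray]:
        tri = self.vertices[self.faces]
        return tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]

    def face_centers(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def face_normals(self) -> np.ndarray:
        """Area-weighted normals ``0.5 * (v1 - v0) x (v2 - v0)``."""
        e1, e2 = self._edges()
        return 0.5 * np.cross(e1, e2)

    def face_areas(self) -> np.ndarray:
        return np.linalg.norm(self.face_normals(), axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def unit_normals(self) -> np.ndarray:
        n = self.face_normals()
        a = np.linalg.norm(n, axis=1, keepdims=True)
        return n / np.maximum(a, 1e-300)

    def with_vertices(self, vertices: np.ndarray) -> "TriangleMesh":
        return TriangleMesh(vertices, self.faces.copy(),
                            degenerate_ok=self.degenerate_ok)

    def flipped(self) -> "TriangleMesh":
        """Same geometry with reversed winding (normals negated)."""
        return TriangleMesh(self.vertices.copy(), self.faces[:, ::-1].copy(),
                            degenerate_ok=self.degenerate_ok)

    def submesh(self, face_mask: np.ndarray) -> "TriangleMesh":
        """Mesh restricted to the selected faces (vertices re-indexed)."""
        faces = self.faces[np.asarray(face_mask)]
        used = np.unique(faces)
        remap = np.full(self.n_vertices, -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        return TriangleMesh(self.vertices[used], remap[faces],
                            degenerate_ok=self.degenerate_ok)

    def transformed(self, transform) -> "TriangleMesh":
        return self.with_vertices(transform.transform_points(self.vertices))

    def is_closed(self) -> bool:
        """True when every edge is shared by exactly two faces."""
        edges = np.sort(
            self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))


def merge_meshes(meshes: Sequence[TriangleMesh]) -> TriangleMesh:
    """Concatenate meshes into one (no vertex welding)."""
    if not meshes:
        raise GeometryError("cannot merge an empty mesh list")
    verts, faces, offset = [], [], 0
    for m in meshes:
        verts.append(m.vertices)
        faces.append(m.faces + offset)
        offset += m.n_vertices
    return TriangleMesh(np.vstack(verts), np.vstack(faces), degenerate_ok=True)


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

@dataclass
class Affine:
    """Affine map ``x -> linear @ x + translation`` in 2 or 3 dimensions."""

    linear: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float)
        d = self.linear.shape[0]
        self.linear = self.linear.reshape(d, d)
        self.translation = np.asarray(self.translation, dtype=float).reshape(d)
        if abs(np.linalg.det(self.linear)) < 1e-12:
            raise GeometryError("affine linear part must be invertible")

    @classmethod
    def identity(cls, dim: int = 3) -> "Affine":
        return cls(np.eye(dim), np.zeros(dim))

    @classmethod
    def translate(cls, t: Iterable[float]) -> "Affine":
        t = np.asarray(list(t), dtype=float)
        return cls(np.eye(len(t)), t)

    @classmethod
    def rotation_z(cls, angle_deg: float, dim: int = 3) -> "Affine":
        a = np.deg2rad(angle_deg)
        r2 = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        if dim == 2:
            return cls(r2, np.zeros(2))
        lin = np.eye(3)
        lin[:2, :2] = r2
        return cls(lin, np.zeros(3))

    @property
    def dim(self) -> int:
        return self.linear.shape[0]

    def transform_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return pts @ self.linear.T + self.translation

    def inverse(self) -> "Affine":
        inv = np.linalg.inv(self.linear)
        return Affine(inv, -inv @ self.translation)

    def compose(self, other: "Affine") -> "Affine":
        """Map applying ``other`` first, then ``self``."""
        return Affine(self.linear @ other.linear,
                      self.linear @ other.translation + self.translation)


AffineTransform3 = Affine  # 3D is the common case; the map is dimension-generic


@dataclass
class RegularGrid:
    """Axis-aligned sampling grid for velocity fields (2D or 3D)."""

    origin: np.ndarray
    spacing: np.ndarray
    shape: tuple[int, ...]

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).ravel()
        self.spacing = np.asarray(self.spacing, dtype=float).ravel()
        self.shape = tuple(int(n) for n in self.shape)
        if np.any(self.spacing <= 0):
            raise GeometryError("grid spacing must be positive")

    @property
    def dim(self) -> int:
        return len(self.shape)

    def nodes(self) -> np.ndarray:
        axes = [self.origin[d] + self.spacing[d] * np.arange(self.shape[d])
                for d in range(self.dim)]
        pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        return pts.reshape(-1, self.dim)

    def to_index(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return (x - self.origin) / self.spacing

    def sample_field(self, field_vals: np.ndarray, x: np.ndarray) -> np.ndarray:
        """Linear interpolation of a vector field ``(*shape, dim)`` at points."""
        idx = self.to_index(x).T
        out = np.empty((x.shape[0] if x.ndim > 1 else 1, self.dim))
        for d in range(self.dim):
            out[:, d] = map_coordinates(field_vals[..., d], idx, order=1,
                                        mode="nearest")
        return out

    @classmethod
    def from_bounds(cls, lo, hi, spacing) -> "RegularGrid":
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        spacing = np.broadcast_to(np.asarray(spacing, dtype=float), lo.shape).copy()
        shape = tuple(int(np.ceil((hi[d] - lo[d]) / spacing[d])) + 1
                      for d in range(len(lo)))
        return cls(lo, spacing, shape)


class Diffeomorphism:
    """Invertible smooth map realized as the flow of grid-sampled velocities.

    ``steps`` is a time-indexed list ``[(dt, V), ...]`` where each ``V`` has
    shape ``(*grid.shape, dim)``.  The forward map integrates the steps in
    order with explicit Euler (``x <- x + dt * V(x)``); the inverse sweeps
    the steps in reverse, solving each Euler step by fixed-point iteration,
    so forward/inverse consistency holds to the fixed-point tolerance.
    A stationary velocity field is the single-entry case.
    """

    def __init__(self, grid: RegularGrid, steps, domain_bounds=None,
                 fp_iters: int = 8):
        self.grid = grid
        self.steps = [(float(dt), np.asarray(V, dtype=float)) for dt, V in steps]
        for _, V in self.steps:
            if V.shape != (*grid.shape, grid.dim):
                raise GeometryError("velocity field shape mismatch with grid")
        if domain_bounds is None:
            lo = grid.origin
            hi = grid.origin + grid.spacing * (np.array(grid.shape) - 1)
            domain_bounds = (lo, hi)
        self.domain_bounds = (np.asarray(domain_bounds[0], dtype=float),
                              np.asarray(domain_bounds[1], dtype=float))
        self.fp_iters = fp_iters

    # -- construction helpers ----------------------------------------------
    @classmethod
    def identity(cls, grid: RegularGrid) -> "Diffeomorphism":
        V = np.zeros((*grid.shape, grid.dim))
        return cls(grid, [(1.0, V)])

    @classmethod
    def from_stationary_velocity(cls, grid: RegularGrid, velocity: np.ndarray,
                                 n_steps: int = 10) -> "Diffeomorphism":
        dt = 1.0 / n_steps
        return cls(grid, [(dt, velocity)] * n_steps)

    @property
    def dim(self) -> int:
        return self.grid.dim

    # -- evaluation ---------------------------------------------------------
    def _check_domain(self, pts: np.ndarray, tol: float = 1e-6) -> None:
        lo, hi = self.domain_bounds
        if np.any(pts < lo - tol) or np.any(pts > hi + tol):
            raise DomainError(
                "points outside diffeomorphism domain "
                f"[{lo.tolist()}, {hi.tolist()}]"
            )

    def transform_points(self, pts: np.ndarray, inverse: bool = False,
                         check_domain: bool = True) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        if check_domain:
            self._check_domain(pts)
        x = pts.copy()
        if not inverse:
            for dt, V in self.steps:
                x = x + dt * self.grid.sample_field(V, x)
        else:
            for dt, V in reversed(self.steps):
                y = x
                # fixed point of x = y - dt * V(x): exact inverse of the
                # forward Euler step up to the iteration tolerance
                for _ in range(self.fp_iters):
                    x_new = y - dt * self.grid.sample_field(V, x)
                    delta = float(np.abs(x_new - x).max())
                    x = x_new
                    if delta < 1e-12:
                        break
        return x

    def forward_map(self, pts: np.ndarray) -> np.ndarray:
        return self.transform_points(pts, inverse=False)

    def inverse_map(self, pts: np.ndarray) -> np.ndarray:
        return self.transform_points(pts, inverse=True)

    def inverse(self) -> "_InvertedDiffeomorphism":
        return _InvertedDiffeomorphism(self)

    # -- contracts ----------------------------------------------------------
    def displacement_on_grid(self) -> np.ndarray:
        nodes = self.grid.nodes()
        mapped = self.transform_points(nodes, check_domain=False)
        return (mapped - nodes).reshape(*self.grid.shape, self.dim)

    def jacobian_determinants(self) -> np.ndarray:
        """det of the forward-map Jacobian at interior grid nodes."""
        disp = self.displacement_on_grid()
        dim = self.dim
        jac = np.empty((*self.grid.shape, dim, dim))
        for comp in range(dim):
            phi_c = disp[..., comp]
            for ax in range(dim):
                g = np.gradient(phi_c, self.grid.spacing[ax], axis=ax)
                jac[..., comp, ax] = g + (1.0 if comp == ax else 0.0)
        return np.linalg.det(jac)

    def inverse_consistency_error(self, pts: np.ndarray | None = None) -> float:
        if pts is None:
            pts = self.grid.nodes()
        fwd = self.transform_points(pts, check_domain=False)
        back = self.transform_points(fwd, inverse=True, check_domain=False)
        return float(np.linalg.norm(back - pts, axis=1).max())

    def check_valid(self, consistency_tol: float = 0.1) -> None:
        """Positive-Jacobian and inverse-consistency contracts.

        ``consistency_tol`` is in units of the smallest grid spacing
        (default 0.1 voxel).
        """
        dets = self.jacobian_determinants()
        if not np.all(dets > 0):
            raise GeometryError(
                f"non-positive Jacobian determinant (min {dets.min():.3g})"
            )
        err = self.inverse_consistency_error()
        tol = consistency_tol * float(self.grid.spacing.min())
        if err > tol:
            raise GeometryError(
                f"inverse-consistency error {err:.3g} mm exceeds {tol:.3g} mm"
            )


class _InvertedDiffeomorphism:
    """View of a diffeomorphism with forward/inverse roles swapped."""

    def __init__(self, base: Diffeomorphism):
        self.base = base

    def transform_points(self, pts: np.ndarray, inverse: bool = False,
                         check_domain: bool = True) -> np.ndarray:
        return self.base.transform_points(pts, inverse=not inverse,
                                          check_domain=check_domain)

    def inverse(self) -> Diffeomorphism:
        return self.base


@dataclass
class PlanarEmbedding:
    """Embed a 2D section plane into 3D at a fixed depth along z.

    Forward maps in-plane points ``(u, v)`` to ``(u, v, depth)``; the
    inverse projects 3D points back to the plane by dropping z.
    """

    depth: float

    def transform_points(self, pts: np.ndarray, inverse: bool = False,
                         check_domain: bool = True) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        if not inverse:
            if pts.shape[1] != 2:
                raise GeometryError("PlanarEmbedding forward expects 2D points")
            z = np.full((len(pts), 1), self.depth)
            return np.hstack([pts, z])
        if pts.shape[1] != 3:
            raise GeometryError("PlanarEmbedding inverse expects 3D points")
        return pts[:, :2].copy()

    def inverse(self) -> "_InvertedPlanarEmbedding":
        return _InvertedPlanarEmbedding(self)


class _InvertedPlanarEmbedding:
    def __init__(self, base: PlanarEmbedding):
        self.base = base

    def transform_points(self, pts, inverse: bool = False,
                         check_domain: bool = True):
        return self.base.transform_points(pts, inverse=not inverse)

    def inverse(self) -> PlanarEmbedding:
        return self.base


class TransformChain:
    """Ordered composition of transforms, each applied forward or inverse.

    Elements are ``(transform, direction)`` with direction ``"forward"`` or
    ``"inverse"``; application is sequential in list order.  The empty chain
    is the identity.
    """

    FORWARD = "forward"
    INVERSE = "inverse"

    def __init__(self, elements=()):
        self.elements: list[tuple[object, str]] = []
        for el in elements:
            if isinstance(el, tuple):
                t, direction = el
            else:
                t, direction = el, self.FORWARD
            if direction not in (self.FORWARD, self.INVERSE):
                raise ValueError(f"unknown direction {direction!r}")
            self.elements.append((t, direction))

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)

    def append(self, transform, direction: str = FORWARD) -> "TransformChain":
        self.elements.append((transform, direction))
        return self

    def extend(self, other: "TransformChain") -> "TransformChain":
        self.elements.extend(other.elements)
        return self

    def transform_points(self, pts: np.ndarray,
                         check_domain: bool = True) -> np.ndarray:
        x = np.atleast_2d(np.asarray(pts, dtype=float))
        for i, (t, direction) in enumerate(self.elements):
            inverse = direction == self.INVERSE
            try:
                if isinstance(t, (Diffeomorphism, _InvertedDiffeomorphism)):
                    x = t.transform_points(x, inverse=inverse,
                                           check_domain=check_domain)
                elif isinstance(t, (PlanarEmbedding,
                                    _InvertedPlanarEmbedding)):
                    x = t.transform_points(x, inverse=inverse)
                elif inverse:
                    x = t.inverse().transform_points(x)
                else:
                    x = t.transform_points(x)
            except DomainError as exc:
                raise DomainError(
                    f"chain element {i} ({type(t).__name__}): {exc}"
                ) from exc
        return x

    def inverted(self) -> "TransformChain":
        flipped = []
        for t, direction in reversed(self.elements):
            flipped.append(
                (t, self.INVERSE if direction == self.FORWARD else self.FORWARD)
            )
        return TransformChain(flipped)


def apply_chain(chain: TransformChain, pts: np.ndarray) -> np.ndarray:
    """Apply a transform chain to a point set (module-level convenience)."""
    return chain.transform_points(pts)


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

@dataclass
class LandmarkSet:
    """Named 3D points in a declared coordinate space (evaluation only)."""

    points: np.ndarray
    labels: list[str]
    space: str = "world"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.labels = [str(l) for l in self.labels]
        if len(self.points) < 1:
            raise GeometryError("landmark set must contain at least one point")
        if len(self.labels) != len(self.points):
            raise GeometryError("labels/points length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise GeometryError("landmark labels must be unique")

    def __len__(self) -> int:
        return len(self.points)

    def transformed(self, transform, space: str | None = None) -> "LandmarkSet":
        pts = (transform.transform_points(self.points)
               if not isinstance(transform, TransformChain)
               else transform.transform_points(self.points))
        return LandmarkSet(pts, list(self.labels), space or self.space)
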