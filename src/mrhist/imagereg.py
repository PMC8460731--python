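"""Intensity-based affine and multi-scale diffeomorphic image registration.

Both stages minimize the sum-of-squares matching energy

    E = integral_Omega | I1(phi^{-1}(x)) - I0(x) |^2

approximated by the voxel sum times the voxel volume.  The deformable
stage is a greedy gradient flow: at each iteration the pointwise force
``2 r grad I1(phi^{-1}(x))`` is smoothed by inverting a Cauchy-Navier
elasticity operator ``L = -alpha lap - alpha grad(div) + gamma I``
spectrally (FFT), and the current map is composed with a small step along
the smoothed velocity.  The accumulated velocity steps form the returned
:class:`~mrhist.geometry.Diffeomorphism`.  Runs coarse-to-fine over an
image pyramid.  Works for 2D sections and 3D volumes alike.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import (
    Affine,
    Diffeomorphism,
    DomainError,
    GeometryError,
    Image2D,
    ImageVolume,
    RegularGrid,
    TransformChain,
)
from .surface import RegistrationResult

__all__ = [
    "ImageRegParams",
    "sse_energy",
    "sse_gradient_field",
    "cauchy_navier_smooth",
    "affine_register_images",
    "diffeo_register_images",
    "resample",
    "downsample_image",
]


@dataclass
class ImageRegParams:
    """Parameters of the intensity registration stages.

    alpha, gamma        Cauchy-Navier operator coefficients
    pyramid_levels      descending downsample factors, finest last
    smoothing_sigma     Gaussian presmoothing of binary inputs, voxels
    """

    pyramid_levels: tuple[int, ...] = (4, 2, 1)
    alpha: float = 1.0
    gamma: float = 1.0
    step_size: float = 0.4
    max_iters: int = 60
    convergence_tol: float = 1e-6
    smoothing_sigma: float = 1.0
    affine_max_iters: int = 200

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.gamma <= 0:
            raise ValueError("alpha and gamma must be positive")
        levels = tuple(int(f) for f in self.pyramid_levels)
        if any(f < 1 for f in levels) or list(levels) != sorted(levels,
                                                               reverse=True):
            raise ValueError("pyramid factors must be descending integers >= 1")
        self.pyramid_levels = levels


# ---------------------------------------------------------------------------
# Interpolation with exact interpolant gradients
# ---------------------------------------------------------------------------

def _interp_with_grad(values: np.ndarray, idx: np.ndarray):
    """N-linear interpolation returning values and exact index-gradients.

    ``idx`` has shape (npts, dim) in continuous voxel coordinates; indices
    are clamped to the grid (edge extension).  The gradient is the true
    derivative of the interpolant, so finite differences of the sampled
    values reproduce it away from cell boundaries.
    """
    dim = values.ndim
    idx = np.clip(idx, 0.0, np.array(values.shape) - 1.0)
    lo = np.floor(idx).astype(int)
    lo = np.minimum(lo, np.array(values.shape) - 2)
    lo = np.maximum(lo, 0)
    frac = idx - lo
    out = np.zeros(len(idx))
    grad = np.zeros_like(idx)
    for corner in range(2**dim):
        offs = np.array([(corner >> d) & 1 for d in range(dim)])
        vals = values[tuple((lo + offs).T)]
        w = np.ones(len(idx))
        for d in range(dim):
            w = w * (frac[:, d] if offs[d] else 1.0 - frac[:, d])
        out += w * vals
        for d in range(dim):
            wd = np.ones(len(idx))
            for d2 in range(dim):
                if d2 == d:
                    wd = wd * (1.0 if offs[d2] else -1.0)
                else:
                    wd = wd * (frac[:, d2] if offs[d2] else 1.0 - frac[:, d2])
            grad[:, d] += wd * vals
    return out, grad


def _sample_with_world_grad(img, pts: np.ndarray):
    """Sample an image at world points; gradient in world units (per mm)."""
    if isinstance(img, ImageVolume):
        idx = img.world_to_voxel(pts)
        vals, g = _interp_with_grad(img.values, idx)
        # d(idx)/d(world) = diag(1/spacing) @ direction^{-1}
        jac = np.linalg.inv(img.direction) / img.spacing[:, None]
        return vals, g @ jac
    idx = img.world_to_pixel(pts)
    vals, g = _interp_with_grad(img.values, idx)
    return vals, g / img.spacing


def _pixel_measure(img) -> float:
    return img.voxel_volume if isinstance(img, ImageVolume) else img.pixel_area


def _grid_points(img) -> np.ndarray:
    dim = 3 if isinstance(img, ImageVolume) else 2
    return img.world_coords().reshape(-1, dim)


# ---------------------------------------------------------------------------
# Energy
# ---------------------------------------------------------------------------

def sse_energy(I1, I0, phi_inv=None) -> float:
    """Sum-of-squares energy over I0's domain, ``phi_inv`` pulling I1.

    ``phi_inv`` may be None (identity), an Affine, a Diffeomorphism (its
    forward map is used) or a TransformChain.
    """
    if I1.values.ndim != I0.values.ndim:
        raise DomainError("images must share dimensionality")
    pts = _grid_points(I0)
    warped = _warp_points(phi_inv, pts)
    vals, _ = _sample_with_world_grad(I1, warped)
    r = vals - I0.values.ravel()
    return float(np.sum(r**2) * _pixel_measure(I0))


def _warp_points(phi_inv, pts):
    if phi_inv is None:
        return pts
    if isinstance(phi_inv, (Diffeomorphism, TransformChain)):
        return phi_inv.transform_points(pts, check_domain=False)
    return phi_inv.transform_points(pts)


def sse_gradient_field(I1, I0, displacement: np.ndarray) -> np.ndarray:
    """Exact gradient of the discretized energy w.r.t. the displacement.

    ``displacement`` has shape ``(*I0.shape, dim)`` in mm on I0's grid;
    the map is ``phi^{-1}(x) = x + u(x)``.  Returns an array of the same
    shape: ``2 r(x) grad I1(x + u(x)) * voxel_volume``.
    """
    pts = _grid_points(I0)
    dim = pts.shape[1]
    u = displacement.reshape(-1, dim)
    vals, grads = _sample_with_world_grad(I1, pts + u)
    r = vals - I0.values.ravel()
    g = 2.0 * r[:, None] * grads * _pixel_measure(I0)
    return g.reshape(*I0.shape, dim)


# ---------------------------------------------------------------------------
# Cauchy-Navier spectral smoothing
# ---------------------------------------------------------------------------

def cauchy_navier_smooth(force: np.ndarray, spacing: np.ndarray,
                         alpha: float, gamma: float) -> np.ndarray:
    """Apply the inverse Cauchy-Navier operator to a vector field.

    The operator ``L = -alpha lap - alpha grad(div) + gamma I`` is
    inverted per spatial frequency: its symbol is
    ``(alpha lam + gamma) I + alpha d d^H`` with the finite-difference
    Laplacian symbol ``lam`` and central-difference gradient symbol ``d``,
    inverted in closed form (Sherman-Morrison).  Linear and self-adjoint;
    attenuates high frequencies.
    """
    shape = force.shape[:-1]
    dim = force.shape[-1]
    spacing = np.asarray(spacing, dtype=float)
    freqs = [2.0 * np.pi * np.fft.fftfreq(n) for n in shape]
    mesh = np.meshgrid(*freqs, indexing="ij")
    lam = sum((2.0 - 2.0 * np.cos(m)) / spacing[d] ** 2
              for d, m in enumerate(mesh))
    d_sym = np.stack([1j * np.sin(m) / spacing[d]
                      for d, m in enumerate(mesh)], axis=-1)
    a = alpha * lam + gamma
    d_norm2 = np.sum(np.abs(d_sym) ** 2, axis=-1)
    fhat = np.stack([np.fft.fftn(force[..., d]) for d in range(dim)], axis=-1)
    proj = np.sum(np.conj(d_sym) * fhat, axis=-1)
    coef = alpha * proj / (a * (a + alpha * d_norm2))
    vhat = fhat / a[..., None] - coef[..., None] * d_sym
    out = np.stack([np.fft.ifftn(vhat[..., d]).real for d in range(dim)],
                   axis=-1)
    return out


# ---------------------------------------------------------------------------
# Pyramid helpers
# ---------------------------------------------------------------------------

def downsample_image(img, factor: int):
    """Gaussian-smoothed subsampling preserving world geometry."""
    if factor == 1:
        return img
    vals = gaussian_filter(img.values, sigma=factor / 2.0)
    if isinstance(img, ImageVolume):
        sub = vals[::factor, ::factor, ::factor]
        return ImageVolume(sub, img.spacing * factor, img.origin,
                           img.direction)
    sub = vals[::factor, ::factor]
    return Image2D(sub, img.spacing * factor, img.origin, img.section_depth)


def _presmooth(img, sigma: float):
    if sigma <= 0:
        return img
    return img.like(gaussian_filter(img.values, sigma=sigma))


# ---------------------------------------------------------------------------
# Affine intensity registration
# ---------------------------------------------------------------------------

def affine_register_images(I1, I0, params: ImageRegParams | None = None,
                           constraint: str = "full") -> RegistrationResult:
    """Affine map A with ``I1(A(x)) ~ I0(x)``, minimizing the SSE energy.

    Coarse-to-fine over the parameter pyramid; analytic gradient via the
    chain rule through the interpolant.  ``constraint="translation_only"``
    restricts the model to a shift (e.g. camera jitter).  Raises on
    constant (flat) images, which carry no intensity gradient.
    """
    if constraint not in ("full", "translation_only"):
        raise ValueError(f"unknown constraint {constraint!r}")
    params = params or ImageRegParams()
    if np.ptp(I1.values) == 0 or np.ptp(I0.values) == 0:
        raise GeometryError("flat image: intensity gradient is zero "
                            "everywhere, affine registration is undefined")
    dim = I0.values.ndim
    I1s = _presmooth(I1, params.smoothing_sigma)
    I0s = _presmooth(I0, params.smoothing_sigma)
    lin = np.eye(dim)
    trans = np.zeros(dim)
    energies: list[float] = []
    from scipy.optimize import minimize

    # parameterize the linear part about the fixed image's center: linear
    # and translation parameters are otherwise nearly collinear for
    # content far from the world origin, which stalls the optimizer
    c0 = _grid_points(I0).mean(axis=0)

    for factor in params.pyramid_levels:
        lvl1 = downsample_image(I1s, factor)
        lvl0 = downsample_image(I0s, factor)
        pts = _grid_points(lvl0)
        ref = lvl0.values.ravel()
        measure = _pixel_measure(lvl0)
        centered = pts - c0

        def objective(theta):
            if constraint == "translation_only":
                L = np.eye(dim)
                t = theta
            else:
                L = theta[:dim * dim].reshape(dim, dim)
                t = theta[dim * dim:]
            warped = centered @ L.T + c0 + t
            vals, grads = _sample_with_world_grad(lvl1, warped)
            r = vals - ref
            e = float(np.sum(r**2) * measure)
            gw = 2.0 * r[:, None] * grads * measure
            gt = gw.sum(axis=0)
            if constraint == "translation_only":
                return e, gt
            gL = gw.T @ centered
            return e, np.concatenate([gL.ravel(), gt])

        theta0 = (trans.copy() if constraint == "translation_only"
                  else np.concatenate([lin.ravel(), trans]))
        res = minimize(objective, theta0, jac=True, method="L-BFGS-B",
                       options={"maxiter": params.affine_max_iters,
                                "ftol": params.convergence_tol, "gtol": 1e-12})
        e0 = objective(theta0)[0]
        if res.fun <= e0:
            if constraint == "translation_only":
                trans = res.x.copy()
            else:
                lin = res.x[:dim * dim].reshape(dim, dim)
                trans = res.x[dim * dim:]
            energies.append(float(res.fun))
        else:
            energies.append(e0)
    A = Affine(lin, c0 - lin @ c0 + trans)
    return RegistrationResult(A, energies, True, "")


# ---------------------------------------------------------------------------
# Greedy diffeomorphic gradient flow
# ---------------------------------------------------------------------------

def _level_grid(img) -> RegularGrid:
    if isinstance(img, ImageVolume):
        if not np.allclose(img.direction, np.eye(3)):
            raise GeometryError("deformable registration requires an "
                                "axis-aligned volume grid")
        return RegularGrid(img.origin, img.spacing, img.shape)
    return RegularGrid(img.origin, img.spacing, img.shape)


def diffeo_register_images(I1, I0, params: ImageRegParams | None = None
                           ) -> RegistrationResult:
    """Greedy diffeomorphic gradient flow on the SSE energy.

    Returns a RegistrationResult whose transform is a Diffeomorphism whose
    *forward* map is ``phi^{-1}`` of the energy: ``I1(forward(x)) ~ I0(x)``
    for x on I0's grid.  Velocity updates are Cauchy-Navier smoothed and
    applied by composition, with backtracking on the energy; all accepted
    steps decrease the energy.
    """
    params = params or ImageRegParams()
    I1s = _presmooth(I1, params.smoothing_sigma)
    I0s = _presmooth(I0, params.smoothing_sigma)
    dim = I0.values.ndim
    steps: list[tuple[float, np.ndarray, RegularGrid]] = []
    level_energies: list[list[float]] = []

    def apply_steps(pts):
        x = pts
        for dt, V, grid in steps:
            x = x + dt * grid.sample_field(V, x)
        return x

    for factor in params.pyramid_levels:
        lvl1 = downsample_image(I1s, factor)
        lvl0 = downsample_image(I0s, factor)
        grid = _level_grid(lvl0)
        pts = _grid_points(lvl0)
        ref = lvl0.values.ravel()
        measure = _pixel_measure(lvl0)
        # dense displacement cache of the accumulated map on this level's
        # grid; new greedy steps perturb the grid points first, so the old
        # map is evaluated by interpolating this cache
        U = apply_steps(pts) - pts

        def energy_at(wpts):
            vals, _ = _sample_with_world_grad(lvl1, wpts)
            return float(np.sum((vals - ref) ** 2) * measure)

        e = energy_at(pts + U)
        elist = [e]
        step = params.step_size
        Ufield = U.reshape(*lvl0.shape, dim)
        for _ in range(params.max_iters):
            vals, grads = _sample_with_world_grad(lvl1, pts + U)
            r = vals - ref
            force = (2.0 * r[:, None] * grads * measure).reshape(
                *lvl0.shape, dim)
            v = cauchy_navier_smooth(force, grid.spacing, params.alpha,
                                     params.gamma)
            vmax = float(np.linalg.norm(v.reshape(-1, dim), axis=1).max())
            if vmax < 1e-14:
                break
            # scale so the largest displacement is `step` voxels
            scale = step * float(grid.spacing.min()) / vmax
            accepted = False
            while scale * vmax > 1e-9 * float(grid.spacing.min()):
                dt_v = -scale * v
                inner = pts + dt_v.reshape(-1, dim)
                trial_warped = inner + grid.sample_field(Ufield, inner)
                e_trial = energy_at(trial_warped)
                if e_trial < e * (1.0 - 1e-12):
                    steps.insert(0, (1.0, dt_v, grid))
                    U = trial_warped - pts
                    Ufield = U.reshape(*lvl0.shape, dim)
                    accepted = True
                    rel = (e - e_trial) / max(e, 1e-300)
                    e = e_trial
                    elist.append(e)
                    break
                scale *= 0.5
            if not accepted:
                break
            if rel < params.convergence_tol:
                break
        level_energies.append(elist)

    diffeo = _consolidate_steps(steps, _level_grid(
        downsample_image(I0s, params.pyramid_levels[-1])))
    result = RegistrationResult(diffeo, [e for lv in level_energies
                                         for e in lv], True, "")
    result.level_energies = level_energies
    return result


def _consolidate_steps(steps, fine_grid: RegularGrid) -> Diffeomorphism:
    """Resample all velocity steps onto the finest grid.

    ``steps`` is kept in application order (newest greedy step first,
    i.e. innermost in the composition); the Diffeomorphism integrates its
    list in the same order, so no reordering is needed.
    """
    if not steps:
        return Diffeomorphism.identity(fine_grid)
    nodes = fine_grid.nodes()
    vlist = []
    for dt, V, grid in steps:
        Vf = grid.sample_field(V, nodes).reshape(*fine_grid.shape,
                                                 fine_grid.dim)
        vlist.append((dt, Vf))
    return Diffeomorphism(fine_grid, vlist)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample(I, T, target_grid, interpolation: str = "linear",
             fill: float = 0.0):
    """Pull ``I`` onto ``target_grid`` through the map ``T``.

    ``T`` maps target-grid world coordinates into I's coordinates; it may
    be None (identity), an Affine, a Diffeomorphism, or a TransformChain.
    ``interpolation`` is "linear" or "nearest" (labels stay binary with
    nearest).
    """
    dim = 3 if isinstance(target_grid, ImageVolume) else 2
    pts = _grid_points(target_grid)
    src = _warp_points(T, pts)
    order = 0 if interpolation == "nearest" else 1
    vals = I.sample(src, order=order, fill=fill).reshape(target_grid.shape)
    return target_grid.like(vals)
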