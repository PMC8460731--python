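"""Currents-based surface dissimilarity and surface registration.

An oriented triangular mesh is represented as a current: a sum of
vector-valued Dirac masses, one per face, carrying the area-weighted face
normal at the face center.  The squared kernel norm (K-norm) of a surface
``S`` with faces ``p`` is

    ||S||_K^2 = sum_p sum_p' <eta(p), eta(p')> k(c(p), c(p'))

with a scalar Cauchy kernel ``k(x, y) = 1 / (1 + |x - y|^2 / sigma^2)``.
The dissimilarity between two surfaces is the K-norm of the difference of
their currents, which expands into three double sums and requires no point
correspondence.  Registration minimizes this dissimilarity over affine
transforms or over diffeomorphisms generated by kernel velocity fields.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.optimize import minimize

from .geometry import (
    Affine,
    Diffeomorphism,
    GeometryError,
    RegularGrid,
    TriangleMesh,
)

__all__ = [
    "CurrentsParams",
    "RegistrationResult",
    "cauchy_kernel",
    "currents_norm_sq",
    "currents_dissimilarity",
    "currents_vertex_gradient",
    "currents_energy_and_gradient",
    "split_block_surface",
    "affine_register_surfaces",
    "diffeo_register_surfaces",
]


class EmptyMeshError(ValueError):
    pass


class OrientationError(ValueError):
    pass


@dataclass
class CurrentsParams:
    """Tunable parameters of the currents matching stages.

    sigma               kernel scale of the data term, mm
    velocity_kernel_scale  kernel scale of the deformation velocity field, mm
    flow_steps          Euler integration steps over flow time [0, 1]
    regularization      weight on the velocity-field norm
    step_size           initial optimizer step scale
    max_iters           optimizer iteration cap
    convergence_tol     relative energy change declaring convergence
    max_control_points  velocity control-point cap (vertices subsampled above)
    """

    sigma: float = 1.0
    velocity_kernel_scale: float = 2.0
    flow_steps: int = 8
    regularization: float = 1e-3
    step_size: float = 1.0
    max_iters: int = 100
    convergence_tol: float = 1e-6
    max_control_points: int = 700
    grid_spacing: float | None = None
    affine_ridge: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.velocity_kernel_scale <= 0:
            raise ValueError("kernel scales must be positive")
        if self.flow_steps < 1 or self.max_iters < 1:
            raise ValueError("flow_steps and max_iters must be >= 1")


@dataclass
class RegistrationResult:
    """Outcome of a surface registration stage."""

    transform: object
    energies: list[float] = field(default_factory=list)
    converged: bool = True
    message: str = ""
    level_energies: list[list[float]] | None = None

    @property
    def initial_energy(self) -> float:
        return self.energies[0] if self.energies else np.nan

    @property
    def final_energy(self) -> float:
        return self.energies[-1] if self.energies else np.nan


# ---------------------------------------------------------------------------
# Kernel and currents energies
# ---------------------------------------------------------------------------

def cauchy_kernel(x: np.ndarray, y: np.ndarray, sigma: float) -> np.ndarray:
    """Scalar Cauchy kernel ``1 / (1 + |x - y|^2 / sigma^2)``."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d2 = np.sum((x - y) ** 2, axis=-1)
    return 1.0 / (1.0 + d2 / sigma**2)


def _kernel_matrix(c1: np.ndarray, c2: np.ndarray, sigma: float) -> np.ndarray:
    d2 = np.sum((c1[:, None, :] - c2[None, :, :]) ** 2, axis=-1)
    return 1.0 / (1.0 + d2 / sigma**2)


# -- numba-accelerated pairwise kernels (exact float64, no temporaries) ----

@njit(cache=True, fastmath=True)
def _pair_terms_nb(ca, na, cb, nb, sigma2):  # pragma: no cover - jitted
    n, m = ca.shape[0], cb.shape[0]
    e = 0.0
    gC = np.zeros((n, 3))
    gN = np.zeros((n, 3))
    for i in range(n):
        gc0 = gc1 = gc2 = 0.0
        gn0 = gn1 = gn2 = 0.0
        for j in range(m):
            d0 = ca[i, 0] - cb[j, 0]
            d1 = ca[i, 1] - cb[j, 1]
            d2 = ca[i, 2] - cb[j, 2]
            k = 1.0 / (1.0 + (d0 * d0 + d1 * d1 + d2 * d2) / sigma2)
            dot = (na[i, 0] * nb[j, 0] + na[i, 1] * nb[j, 1]
                   + na[i, 2] * nb[j, 2])
            e += dot * k
            w = dot * k * k * (-2.0 / sigma2)
            gc0 += w * d0
            gc1 += w * d1
            gc2 += w * d2
            gn0 += k * nb[j, 0]
            gn1 += k * nb[j, 1]
            gn2 += k * nb[j, 2]
        gC[i, 0] = gc0
        gC[i, 1] = gc1
        gC[i, 2] = gc2
        gN[i, 0] = gn0
        gN[i, 1] = gn1
        gN[i, 2] = gn2
    return e, gC, gN


@njit(cache=True, fastmath=True)
def _pair_energy_nb(ca, na, cb, nb, sigma2):  # pragma: no cover - jitted
    n, m = ca.shape[0], cb.shape[0]
    e = 0.0
    for i in range(n):
        for j in range(m):
            d0 = ca[i, 0] - cb[j, 0]
            d1 = ca[i, 1] - cb[j, 1]
            d2 = ca[i, 2] - cb[j, 2]
            k = 1.0 / (1.0 + (d0 * d0 + d1 * d1 + d2 * d2) / sigma2)
            e += (na[i, 0] * nb[j, 0] + na[i, 1] * nb[j, 1]
                  + na[i, 2] * nb[j, 2]) * k
    return e


@njit(cache=True, fastmath=True)
def _flow_back_step_nb(X, P, A, G, sigma2, constrained
                       ):  # pragma: no cover - jitted
    n, nc = X.shape[0], P.shape[0]
    GA = np.zeros((nc, 3))
    Gx = np.zeros((n, 3))
    g_tz = 0.0
    for i in range(n):
        if constrained:
            g_tz += G[i, 2]
        for j in range(nc):
            d0 = X[i, 0] - P[j, 0]
            d1 = X[i, 1] - P[j, 1]
            d2 = X[i, 2] - P[j, 2]
            k = 1.0 / (1.0 + (d0 * d0 + d1 * d1 + d2 * d2) / sigma2)
            GA[j, 0] += k * G[i, 0]
            GA[j, 1] += k * G[i, 1]
            GA[j, 2] += k * G[i, 2]
            m = (G[i, 0] * A[j, 0] + G[i, 1] * A[j, 1]
                 + G[i, 2] * A[j, 2]) * k * k * (-2.0 / sigma2)
            Gx[i, 0] += m * d0
            Gx[i, 1] += m * d1
            Gx[i, 2] += m * d2
    return GA, Gx, g_tz


def _pair_energy(c1, n1, c2, n2, sigma) -> float:
    return float(_pair_energy_nb(np.ascontiguousarray(c1),
                                 np.ascontiguousarray(n1),
                                 np.ascontiguousarray(c2),
                                 np.ascontiguousarray(n2),
                                 float(sigma) ** 2))


def _require_faces(mesh: TriangleMesh, name: str) -> None:
    if mesh.n_faces == 0:
        raise EmptyMeshError(f"{name} has no faces")


def currents_norm_sq(S: TriangleMesh, sigma: float) -> float:
    """Squared K-norm of a surface (double sum over its faces)."""
    _require_faces(S, "mesh")
    c, n = S.face_centers(), S.face_normals()
    return _pair_energy(c, n, c, n, sigma)


def currents_dissimilarity(S1: TriangleMesh, S2: TriangleMesh,
                           sigma: float) -> float:
    """Squared K-norm of the difference of the two surface currents."""
    _require_faces(S1, "S1")
    _require_faces(S2, "S2")
    c1, n1 = S1.face_centers(), S1.face_normals()
    c2, n2 = S2.face_centers(), S2.face_normals()
    return (_pair_energy(c1, n1, c1, n1, sigma)
            - 2.0 * _pair_energy(c1, n1, c2, n2, sigma)
            + _pair_energy(c2, n2, c2, n2, sigma))


# ---------------------------------------------------------------------------
# Analytic gradient with respect to moving-mesh vertices
# ---------------------------------------------------------------------------

def _center_normal_grads(c1, n1, c2, n2, sigma):
    """Gradients of sum_ij <n1_i, n2_j> k(c1_i, c2_j) w.r.t. c1 and n1."""
    diff = c1[:, None, :] - c2[None, :, :]
    K = 1.0 / (1.0 + np.sum(diff**2, axis=-1) / sigma**2)
    dot = n1 @ n2.T
    # dk/dx = -(2/sigma^2) (x - y) k^2
    gC = np.einsum("ij,ijd->id", dot * K**2, diff) * (-2.0 / sigma**2)
    gN = K @ n2
    return gC, gN


def _scatter_to_vertices(mesh: TriangleMesh, verts: np.ndarray,
                         gC: np.ndarray, gN: np.ndarray) -> np.ndarray:
    """Chain rule from per-face center/normal gradients to vertex gradient."""
    grad = np.zeros_like(verts)
    f = mesh.faces
    np.add.at(grad, f[:, 0], gC / 3.0)
    np.add.at(grad, f[:, 1], gC / 3.0)
    np.add.at(grad, f[:, 2], gC / 3.0)
    tri = verts[f]
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    # eta = 0.5 e1 x e2 ; for upstream g: d<g,eta>/de1 = 0.5 e2 x g,
    # d<g,eta>/de2 = 0.5 g x e1 (scalar triple product identities)
    g1 = 0.5 * np.cross(e2, gN)
    g2 = 0.5 * np.cross(gN, e1)
    np.add.at(grad, f[:, 1], g1)
    np.add.at(grad, f[:, 2], g2)
    np.add.at(grad, f[:, 0], -(g1 + g2))
    return grad


def currents_vertex_gradient(moving: TriangleMesh, target: TriangleMesh,
                             sigma: float,
                             vertices: np.ndarray | None = None) -> np.ndarray:
    """d currents_dissimilarity / d(moving vertices), analytic.

    ``vertices`` overrides the moving mesh's vertex positions (same
    connectivity), which lets optimizers evaluate the gradient at trial
    configurations without rebuilding meshes.
    """
    _, grad = currents_energy_and_gradient(moving, target, sigma, vertices)
    return grad


def currents_energy_and_gradient(moving: TriangleMesh, target: TriangleMesh,
                                 sigma: float,
                                 vertices: np.ndarray | None = None,
                                 target_norm_sq: float | None = None
                                 ) -> tuple[float, np.ndarray]:
    """Dissimilarity and its vertex gradient in one pass (shared kernels).

    ``target_norm_sq`` caches the target's constant self term across
    optimizer iterations.
    """
    verts = moving.vertices if vertices is None else np.asarray(vertices, float)
    work = moving.with_vertices(verts) if vertices is not None else moving
    c1, n1 = work.face_centers(), work.face_normals()
    c2, n2 = target.face_centers(), target.face_normals()
    sigma2 = float(sigma) ** 2
    e_self, gC_self, gN_self = _pair_terms_nb(c1, n1, c1, n1, sigma2)
    e_cross, gC_cross, gN_cross = _pair_terms_nb(c1, n1, c2, n2, sigma2)
    e_tt = (_pair_energy(c2, n2, c2, n2, sigma)
            if target_norm_sq is None else target_norm_sq)
    energy = e_self - 2.0 * e_cross + e_tt
    gC = 2.0 * (gC_self - gC_cross)
    gN = 2.0 * (gN_self - gN_cross)
    return energy, _scatter_to_vertices(work, verts, gC, gN)


# ---------------------------------------------------------------------------
# Head / foot / exterior face splitting
# ---------------------------------------------------------------------------

def _check_oriented(mesh: TriangleMesh) -> None:
    edges = mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
    directed = {}
    for a, b in edges:
        key = (int(a), int(b))
        directed[key] = directed.get(key, 0) + 1
    for (a, b), cnt in directed.items():
        if cnt != 1 or directed.get((b, a), 0) != 1:
            raise OrientationError(
                "mesh is not a closed, consistently oriented surface"
            )


def split_block_surface(S_b: TriangleMesh, axis: np.ndarray,
                        angle_threshold: float = 45.0):
    """Partition a closed block surface into head, foot and exterior parts.

    Faces whose outward unit normal lies within ``angle_threshold`` degrees
    of ``+axis`` form the head surface, those within the threshold of
    ``-axis`` the foot surface, and the remainder the exterior.  Returns
    ``(head, foot, exterior)`` submeshes that exactly partition the faces.
    """
    _check_oriented(S_b)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    cos_thr = np.cos(np.deg2rad(angle_threshold))
    cosines = S_b.unit_normals() @ axis
    head = cosines >= cos_thr
    foot = cosines <= -cos_thr
    exterior = ~(head | foot)
    return S_b.submesh(head), S_b.submesh(foot), S_b.submesh(exterior)


# ---------------------------------------------------------------------------
# Affine surface registration
# ---------------------------------------------------------------------------

def _affine_pack(A: Affine, constraint: str) -> np.ndarray:
    if constraint == "translation_only":
        return A.translation.copy()
    if constraint == "z_translation_only":
        # rows x, y free (incl. z coupling); z row fixed to z' = z + tz
        return np.concatenate([A.linear[:2].ravel(), A.translation[:2],
                               [A.translation[2]]])
    return np.concatenate([A.linear.ravel(), A.translation])


def _affine_unpack(theta: np.ndarray, constraint: str) -> Affine:
    if constraint == "translation_only":
        return Affine(np.eye(3), theta)
    if constraint == "z_translation_only":
        lin = np.eye(3)
        lin[:2] = theta[:6].reshape(2, 3)
        t = np.array([theta[6], theta[7], theta[8]])
        return Affine(lin, t)
    return Affine(theta[:9].reshape(3, 3), theta[9:12])


def affine_register_surfaces(S_m: TriangleMesh, S_t: TriangleMesh,
                             params: CurrentsParams,
                             constraint: str = "none") -> RegistrationResult:
    """Affine minimization of the currents dissimilarity.

    Optimizes the affine parameters directly against the currents energy
    with a quasi-Newton method and the analytic gradient.  With
    ``constraint="z_translation_only"`` motion along z is restricted to a
    single translation (the 2D-slice-correlation ablation mode).
    """
    _require_faces(S_m, "moving mesh")
    _require_faces(S_t, "target mesh")
    V0 = S_m.vertices
    energies: list[float] = []
    e_id = currents_dissimilarity(S_m, S_t, params.sigma)
    # a flat cut face leaves out-of-plane affine components unidentified;
    # a small identity-anchored ridge (scaled by the identity energy) pins
    # those null directions.  The ridge is annealed to zero in a second
    # pass so it cannot bias directions the data does identify (gradients
    # vanish along true null directions, so the refinement stays put
    # there).
    ridge = params.affine_ridge * e_id
    diam = max(float(np.ptp(V0, axis=0).max()), 1e-6)

    e_tt = currents_norm_sq(S_t, params.sigma)

    def objective(theta):
        A = _affine_unpack(theta, constraint)
        verts = A.transform_points(V0)
        e, gV = currents_energy_and_gradient(S_m, S_t, params.sigma,
                                             vertices=verts,
                                             target_norm_sq=e_tt)
        gL = gV.T @ V0       # dE/dlinear
        gT = gV.sum(axis=0)  # dE/dtranslation
        dL = A.linear - np.eye(3)
        e = e + ridge * (np.sum(dL**2) + np.sum(A.translation**2) / diam**2)
        gL = gL + 2.0 * ridge * dL
        gT = gT + 2.0 * ridge * A.translation / diam**2
        if constraint == "translation_only":
            grad = gT
        elif constraint == "z_translation_only":
            grad = np.concatenate([gL[:2].ravel(), gT[:2], [gT[2]]])
        else:
            grad = np.concatenate([gL.ravel(), gT])
        return e, grad

    theta0 = _affine_pack(Affine.identity(3), constraint)
    e0, _ = objective(theta0)

    # coarse-to-fine kernel schedule widens the capture range; the last
    # stage runs without the ridge so it cannot bias directions the data
    # identifies (gradients vanish along true null directions, so the
    # refinement stays put there)
    theta = theta0
    opts = {"maxiter": params.max_iters,
            "ftol": params.convergence_tol, "gtol": 1e-12}
    base_sigma = params.sigma
    level_energies: list[list[float]] = []
    res = None
    for scale, ridge_on in ((4.0, True), (2.0, True), (1.0, True),
                            (1.0, False)):
        sigma_eff = base_sigma * scale
        e_tt = currents_norm_sq(S_t, sigma_eff)
        ridge = (params.affine_ridge
                 * currents_dissimilarity(S_m, S_t, sigma_eff)
                 if ridge_on else 0.0)
        stage: list[float] = []
        try:
            params.sigma = sigma_eff
            stage.append(objective(theta)[0])
            res = minimize(objective, theta, jac=True, method="L-BFGS-B",
                           callback=lambda th, _s=stage: _s.append(
                               objective(th)[0]),
                           options=opts)
            theta = res.x
        finally:
            params.sigma = base_sigma
        level_energies.append(stage)
    energies = [e0] + level_energies[-1][1:]
    A = _affine_unpack(res.x, constraint)
    final = currents_dissimilarity(S_m.transformed(A), S_t, params.sigma)
    if final > e0:  # never return something worse than the identity
        A, final = Affine.identity(3), e0
    converged = bool(res.success) or final <= e0
    msg = "" if res.success else f"optimizer stopped early: {res.message}"
    if not res.success:
        warnings.warn(f"affine surface registration: {msg}", RuntimeWarning,
                      stacklevel=2)
    energies.append(final)
    out = RegistrationResult(A, energies, converged, msg)
    out.level_energies = level_energies
    return out


# ---------------------------------------------------------------------------
# Diffeomorphic surface registration (kernel velocity flow)
# ---------------------------------------------------------------------------

def _flow_forward(X0, P, A, sigma_v, dt, n_steps, tz=0.0):
    traj = [X0]
    X = X0
    for _ in range(n_steps):
        K = _kernel_matrix(X, P, sigma_v)
        V = K @ A
        if tz:
            V = V + np.array([0.0, 0.0, tz])
        X = X + dt * V
        traj.append(X)
    return traj


def _flow_backward(traj, P, A, sigma_v, dt, G_T, constrained):
    """Backpropagate a vertex gradient through the Euler flow.

    Returns (grad_momenta, grad_tz); ``G_T`` is the data-term gradient at
    the final vertex positions.
    """
    GA = np.zeros_like(A)
    g_tz = 0.0
    G = G_T
    sigma2 = sigma_v**2
    for t in range(len(traj) - 2, -1, -1):
        X = traj[t]
        dGA, Gx, d_tz = _flow_back_step_nb(X, P, A, np.ascontiguousarray(G),
                                           sigma2, constrained)
        GA += dt * dGA
        if constrained:
            g_tz += dt * d_tz
        G = G + dt * Gx
    return GA, g_tz


def _subsample_controls(V0: np.ndarray, cap: int, seed: int) -> np.ndarray:
    if len(V0) <= cap:
        return V0
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(V0), size=cap, replace=False)
    return V0[np.sort(idx)]


def diffeo_register_surfaces(S_m: TriangleMesh, S_t: TriangleMesh,
                             params: CurrentsParams,
                             constraint: str = "none",
                             domain_bounds=None) -> RegistrationResult:
    """Diffeomorphic surface registration by kernel velocity flow.

    The deformation is the flow of a stationary velocity field
    ``v(x) = sum_i k_V(x, p_i) alpha_i`` spanned by Cauchy kernels at
    control points (the moving-mesh vertices, subsampled above a cap),
    integrated over [0, 1] in ``flow_steps`` Euler steps.  The energy is
    the currents dissimilarity of the deformed mesh plus a reproducing
    kernel norm penalty on the velocity.  With
    ``constraint="z_translation_only"`` the velocity's z-component is a
    single global translation rate, so the map's z-motion is exactly a
    translation.

    Returns a :class:`RegistrationResult` whose transform is a
    :class:`~mrhist.geometry.Diffeomorphism` (grid-sampled velocity).
    """
    _require_faces(S_m, "moving mesh")
    _require_faces(S_t, "target mesh")
    if constraint not in ("none", "z_translation_only"):
        raise ValueError(f"unknown constraint {constraint!r}")
    constrained = constraint == "z_translation_only"

    V0 = S_m.vertices
    P = _subsample_controls(V0, params.max_control_points, params.seed)
    nc = len(P)
    sigma_v = params.velocity_kernel_scale
    dt = 1.0 / params.flow_steps
    lam = params.regularization
    Kpp = _kernel_matrix(P, P, sigma_v)
    e_tt = currents_norm_sq(S_t, params.sigma)
    energies: list[float] = []

    def objective(theta):
        if constrained:
            A = np.zeros((nc, 3))
            A[:, :2] = theta[:-1].reshape(nc, 2)
            tz = theta[-1]
        else:
            A = theta.reshape(nc, 3)
            tz = 0.0
        traj = _flow_forward(V0, P, A, sigma_v, dt, params.flow_steps, tz)
        data, G_T = currents_energy_and_gradient(S_m, S_t, params.sigma,
                                                 vertices=traj[-1],
                                                 target_norm_sq=e_tt)
        reg = lam * float(np.einsum("ij,id,jd->", Kpp, A, A))
        GA, g_tz = _flow_backward(traj, P, A, sigma_v, dt, G_T, constrained)
        GA = GA + 2.0 * lam * (Kpp @ A)
        if constrained:
            grad = np.concatenate([GA[:, :2].ravel(), [g_tz]])
        else:
            grad = GA.ravel()
        return data + reg, grad

    n_par = nc * 2 + 1 if constrained else nc * 3
    theta0 = np.zeros(n_par)
    e0, _ = objective(theta0)
    energies.append(e0)
    res = minimize(objective, theta0, jac=True, method="L-BFGS-B",
                   callback=lambda th: energies.append(objective(th)[0]),
                   options={"maxiter": params.max_iters,
                            "ftol": params.convergence_tol,
                            "gtol": 1e-12})
    theta = res.x

    for attempt in range(4):
        diffeo = _build_diffeomorphism(theta, V0, P, params, constrained,
                                       S_m, S_t, domain_bounds)
        dets = diffeo.jacobian_determinants()
        if np.all(dets > 0):
            break
        # unrecoverable folding at this amplitude: shrink toward identity
        theta = 0.5 * theta
    else:
        raise GeometryError("diffeomorphic registration failed: could not "
                            "restore a positive Jacobian")
    final, _ = objective(theta)
    energies.append(final)
    converged = bool(res.success) or final <= e0
    msg = "" if res.success else f"optimizer stopped early: {res.message}"
    return RegistrationResult(diffeo, energies, converged, msg)


def _build_diffeomorphism(theta, V0, P, params, constrained, S_m, S_t,
                          domain_bounds) -> Diffeomorphism:
    nc = len(P)
    if constrained:
        A = np.zeros((nc, 3))
        A[:, :2] = theta[:-1].reshape(nc, 2)
        tz = float(theta[-1])
    else:
        A = theta.reshape(nc, 3)
        tz = 0.0
    sigma_v = params.velocity_kernel_scale
    if domain_bounds is None:
        pts = np.vstack([S_m.vertices, S_t.vertices])
        pad = 3.0 * sigma_v
        lo, hi = pts.min(axis=0) - pad, pts.max(axis=0) + pad
    else:
        lo = np.asarray(domain_bounds[0], dtype=float)
        hi = np.asarray(domain_bounds[1], dtype=float)
    h = params.grid_spacing
    if h is None:
        h = max(sigma_v / 2.0, float((hi - lo).max()) / 64.0)
    grid = RegularGrid.from_bounds(lo, hi, h)
    nodes = grid.nodes()
    V = (_kernel_matrix(nodes, P, sigma_v) @ A)
    if constrained:
        V[:, 2] = tz
    V = V.reshape(*grid.shape, 3)
    return Diffeomorphism.from_stationary_velocity(grid, V,
                                                   n_steps=params.flow_steps)
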