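"""Meshless Total Lagrangian Explicit Dynamics (MTLED) solver.

Computes the static deformation of soft tissue (brain) under prescribed
surface displacements.  The displacement field lives on a scattered node
cloud; moving least squares (MLS) shape functions provide the approximation,
a tetrahedral background grid provides integration (4-point Gauss per tet),
and an explicit central-difference iteration with adaptive dynamic relaxation
drives the system to static equilibrium.

Numerical design notes
----------------------
* Essential boundary conditions are imposed directly on nodal parameters;
  the MLS weights are made interpolating at nodes (singular, inverse-distance
  augmented) so parameters coincide with displacements.
* Internal forces are assembled with zeroth-order variationally consistent
  gradients: corrected so that for every node the quadrature sum of the test
  gradient equals the boundary integral of the shape function times the
  outward normal.  This makes homogeneous (affine) deformation states exact
  discrete equilibria, i.e. the linear patch test passes to solver tolerance
  and reactions of uniform states are exact.  The deformation gradient uses
  the plain MLS gradients (Petrov-Galerkin pairing).
* The constitutive model is compressible neo-Hookean (deviatoric/volumetric
  split); soft-tissue defaults E = 3000 Pa, nu = 0.49.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "TetBackgroundGrid",
    "MLSParams",
    "MTLEDConfig",
    "LoadTable",
    "DeformationState",
    "MeshlessModel",
    "structured_tet_grid",
    "build_integration_points",
    "mls_shape",
    "neo_hookean_pk2",
    "neo_hookean_energy",
    "internal_forces",
    "solve_static",
    "reaction_force",
    "assign_materials",
    "read_abaqus_inp",
    "write_vtu",
]

# 4-point degree-2 Gauss rule on the tetrahedron (barycentric permutations):
# alpha = (5 + 3 sqrt 5)/20 = 0.58541020..., beta = (5 - sqrt 5)/20 = 0.13819660...
TET4_ALPHA = (5.0 + 3.0 * np.sqrt(5.0)) / 20.0
TET4_BETA = (5.0 - np.sqrt(5.0)) / 20.0


# ---------------------------------------------------------------------------
# Background grid
# ---------------------------------------------------------------------------

@dataclass
class TetBackgroundGrid:
    """Node cloud plus tetrahedral background integration grid."""

    nodes: np.ndarray  # (n, 3) mm
    tets: np.ndarray   # (m, 4) int

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.tets = np.asarray(self.tets, dtype=np.int64).reshape(-1, 4)
        if self.tets.size and self.tets.max() >= len(self.nodes):
            raise ValueError("tet index out of range")
        # orientation fix: enforce positive volume
        v = self._vol6()
        flip = v < 0
        self.tets[flip] = self.tets[flip][:, [0, 1, 3, 2]]
        v = self._vol6()
        if np.any(v <= 0):
            raise ValueError("degenerate (zero-volume) tetrahedron in grid")

    def _vol6(self):
        x = self.nodes[self.tets]
        return np.einsum("ij,ij->i", x[:, 1] - x[:, 0],
                         np.cross(x[:, 2] - x[:, 0], x[:, 3] - x[:, 0]))

    def volumes(self) -> np.ndarray:
        return self._vol6() / 6.0

    def node_spacing(self) -> np.ndarray:
        """Shortest incident edge length per node (local cloud spacing)."""
        e = np.concatenate([self.tets[:, p] for p in
                            [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]])
        e = np.sort(e, axis=1)
        e = np.unique(e, axis=0)
        ln = np.linalg.norm(self.nodes[e[:, 0]] - self.nodes[e[:, 1]], axis=1)
        s = np.full(len(self.nodes), np.inf)
        for k in (0, 1):
            np.minimum.at(s, e[:, k], ln)
        s[~np.isfinite(s)] = ln.mean() if len(ln) else 1.0
        return s

    def boundary_faces(self) -> np.ndarray:
        """Outward-oriented boundary triangles (faces used by one tet)."""
        t = self.tets
        faces = np.concatenate([t[:, [0, 2, 1]], t[:, [0, 1, 3]],
                                t[:, [1, 2, 3]], t[:, [0, 3, 2]]])
        key = np.sort(faces, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True,
                                   return_counts=True)
        return faces[counts[inv] == 1]


def structured_tet_grid(n_nodes, extent, origin=(0.0, 0.0, 0.0)) -> TetBackgroundGrid:
    """Regular node lattice with a Kuhn (6-tet per cell) background grid.

    ``n_nodes``: nodes per axis (e.g. (5,5,5)); ``extent``: physical size mm.
    """
    n = tuple(int(x) for x in n_nodes)
    ext = np.asarray(extent, dtype=float) * np.ones(3)
    axes = [np.linspace(0, ext[a], n[a]) + origin[a] for a in range(3)]
    gi, gj, gk = np.meshgrid(*axes, indexing="ij")
    nodes = np.stack([gi, gj, gk], axis=-1).reshape(-1, 3)

    def nid(i, j, k):
        return (i * n[1] + j) * n[2] + k

    tets = []
    corner_perm = [((0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)),
                   ((0, 0, 0), (1, 1, 0), (0, 1, 0), (1, 1, 1)),
                   ((0, 0, 0), (0, 1, 0), (0, 1, 1), (1, 1, 1)),
                   ((0, 0, 0), (0, 1, 1), (0, 0, 1), (1, 1, 1)),
                   ((0, 0, 0), (0, 0, 1), (1, 0, 1), (1, 1, 1)),
                   ((0, 0, 0), (1, 0, 1), (1, 0, 0), (1, 1, 1))]
    for i in range(n[0] - 1):
        for j in range(n[1] - 1):
            for k in range(n[2] - 1):
                for perm in corner_perm:
                    tets.append([nid(i + di, j + dj, k + dk) for di, dj, dk in perm])
    return TetBackgroundGrid(nodes, np.asarray(tets))


def build_integration_points(grid: TetBackgroundGrid):
    """4-point Gauss rule per tet: positions (4m,3), weights (4m,), tet ids."""
    x = grid.nodes[grid.tets]  # (m,4,3)
    vol = grid.volumes()
    a, b = TET4_ALPHA, TET4_BETA
    bary = np.array([[a, b, b, b], [b, a, b, b], [b, b, a, b], [b, b, b, a]])
    pos = np.einsum("qc,mcd->mqd", bary, x).reshape(-1, 3)
    w = np.repeat(vol / 4.0, 4)
    tet_ids = np.repeat(np.arange(len(grid.tets)), 4)
    return pos, w, tet_ids


# ---------------------------------------------------------------------------
# Moving least squares shape functions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MLSParams:
    """MLS configuration: linear basis, quartic spline weight.

    ``support_scale`` multiplies the local nodal spacing to give each node's
    support radius.  ``interpolating=True`` augments the weight with an
    inverse squared normalized distance, which makes the shape functions
    interpolate nodal values (used to impose essential boundary conditions
    exactly).
    """

    basis: str = "linear"
    weight: str = "quartic"
    support_scale: float = 1.8
    interpolating: bool = False

    def __post_init__(self):
        if self.basis != "linear":
            raise ValueError("only the linear basis is implemented")
        if self.weight != "quartic":
            raise ValueError("only the quartic spline weight is implemented")
        if self.support_scale <= 1.0:
            raise ValueError("support_scale must exceed 1 for invertible moments")


def _quartic(q):
    w = 1.0 - 6.0 * q ** 2 + 8.0 * q ** 3 - 3.0 * q ** 4
    dw = -12.0 * q + 24.0 * q ** 2 - 12.0 * q ** 3
    out = q < 1.0
    return np.where(out, w, 0.0), np.where(out, dw, 0.0)


def mls_shape(point, nodes, params: MLSParams, radii, tree: cKDTree | None = None,
              node_tol: float = 1e-9):
    """MLS shape function values and gradients at one evaluation point.

    Returns ``(support_ids, values, gradients)`` with gradients of shape
    (k, 3).  Raises if the moment matrix is singular (insufficient support).
    """
    x = np.asarray(point, dtype=float)
    nodes = np.asarray(nodes, dtype=float)
    radii = np.asarray(radii, dtype=float) * np.ones(len(nodes))
    if tree is None:
        tree = cKDTree(nodes)
    cand = np.asarray(tree.query_ball_point(x, radii.max()), dtype=np.int64)
    d = nodes[cand] - x
    r = np.linalg.norm(d, axis=1)
    keep = r < radii[cand]
    ids, d, r = cand[keep], d[keep], r[keep]
    if len(ids) < 4:
        raise ValueError(f"insufficient MLS support at point {x.tolist()} "
                         f"({len(ids)} nodes)")
    rho = radii[ids]
    if params.interpolating:
        jmin = int(np.argmin(r))
        if r[jmin] < node_tol * rho[jmin]:
            # evaluation at a node: interpolating MLS is the Kronecker delta
            phi = np.zeros(len(ids))
            phi[jmin] = 1.0
            return ids, phi, np.zeros((len(ids), 3))

    q = r / rho
    w, dwdq = _quartic(q)
    if params.interpolating:
        q2 = q ** 2
        w, dwdq = w / q2, (dwdq * q - 2.0 * w) / (q * q2)
    # weight gradient wrt x: dq/dx = -d/(r*rho)
    dqdx = -d / (r * rho)[:, None]
    dw = dwdq[:, None] * dqdx  # (k,3)

    hbar = rho.mean()
    P = np.concatenate([np.ones((len(ids), 1)), d / hbar], axis=1)  # (k,4)
    dPdx = np.zeros((3, len(ids), 4))
    for kk in range(3):
        dPdx[kk, :, kk + 1] = -1.0 / hbar

    A = (w[:, None] * P).T @ P
    try:
        c = np.linalg.solve(A, np.array([1.0, 0.0, 0.0, 0.0]))
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular MLS moment matrix at point {x.tolist()}") from exc
    Pc = P @ c
    phi = w * Pc
    grad = np.empty((len(ids), 3))
    for kk in range(3):
        dA = (dw[:, kk][:, None] * P).T @ P
        dA += (w[:, None] * dPdx[kk]).T @ P + (w[:, None] * P).T @ dPdx[kk]
        dc = -np.linalg.solve(A, dA @ c)
        grad[:, kk] = dw[:, kk] * Pc + w * (P @ dc) + w * (dPdx[kk] @ c)
    return ids, phi, grad


# ---------------------------------------------------------------------------
# Constitutive model
# ---------------------------------------------------------------------------

def _nh_moduli(E, nu):
    mu = E / (2.0 * (1.0 + nu))
    K = E / (3.0 * (1.0 - 2.0 * nu))
    return mu, K


def neo_hookean_pk2(F, E, nu):
    """Second Piola-Kirchhoff stress of the compressible neo-Hookean model.

    S = mu J^(-2/3) (I - tr(C)/3 C^-1) + K J (J-1) C^-1.  Batched over
    leading dimensions of F.
    """
    F = np.asarray(F, dtype=float)
    single = F.ndim == 2
    F = F.reshape((-1, 3, 3))
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ValueError("non-positive det(F): element inversion")
    C = np.matmul(np.swapaxes(F, 1, 2), F)
    Cinv = np.linalg.inv(C)
    trC = np.trace(C, axis1=1, axis2=2)
    mu, K = _nh_moduli(np.asarray(E, dtype=float), nu)
    mu = np.broadcast_to(mu, J.shape)
    K = np.broadcast_to(K, J.shape)
    I = np.broadcast_to(np.eye(3), C.shape)
    S = (mu * J ** (-2.0 / 3.0))[:, None, None] * (I - (trC / 3.0)[:, None, None] * Cinv) \
        + (K * J * (J - 1.0))[:, None, None] * Cinv
    return S[0] if single else S


def neo_hookean_energy(F, E, nu):
    """Stored energy density W = mu/2 (J^(-2/3) trC - 3) + K/2 (J-1)^2."""
    F = np.asarray(F, dtype=float).reshape((-1, 3, 3))
    J = np.linalg.det(F)
    trC = np.einsum("nij,nij->n", F, F)
    mu, K = _nh_moduli(np.asarray(E, dtype=float), nu)
    return (np.broadcast_to(mu, J.shape) / 2.0 * (J ** (-2.0 / 3.0) * trC - 3.0)
            + np.broadcast_to(K, J.shape) / 2.0 * (J - 1.0) ** 2)


# ---------------------------------------------------------------------------
# Assembled meshless model
# ---------------------------------------------------------------------------

class MeshlessModel:
    """Precomputed MLS shape data over a background grid.

    Stores, per integration point, the support node ids, shape values, plain
    reference gradients (used for the deformation gradient) and variationally
    consistent corrected gradients (used for force assembly).
    """

    def __init__(self, grid: TetBackgroundGrid, params: MLSParams | None = None):
        self.grid = grid
        self.params = params or MLSParams(interpolating=True)
        self.nodes = grid.nodes
        self.h = grid.node_spacing()
        self.radii = self.params.support_scale * self.h
        self.tree = cKDTree(self.nodes)

        pos, w, tet_ids = build_integration_points(grid)
        self.ip_pos, self.ip_w, self.ip_tet = pos, w, tet_ids
        nip = len(pos)

        sup, phi, grad = [], [], []
        for i in range(nip):
            ids, p, g = mls_shape(pos[i], self.nodes, self.params, self.radii,
                                  tree=self.tree)
            sup.append(ids); phi.append(p); grad.append(g)
        smax = max(len(s) for s in sup)
        n = len(self.nodes)
        self.sup = np.zeros((nip, smax), dtype=np.int64)
        self.phi = np.zeros((nip, smax))
        self.grad = np.zeros((nip, smax, 3))
        for i in range(nip):
            k = len(sup[i])
            self.sup[i, :k] = sup[i]
            self.phi[i, :k] = phi[i]
            self.grad[i, :k] = grad[i]

        # --- zeroth-order variational consistency correction --------------
        # Target for the quadrature sum of each node's test gradient:
        # the boundary integral of phi_a * n for nodes lying on the domain
        # boundary, zero for interior nodes (whose test functions are treated
        # as conforming, i.e. vanishing on the boundary).  With these targets
        # homogeneous (affine) deformation states are exact discrete
        # equilibria: the linear patch test passes to solver tolerance.
        bint = np.zeros((n, 3))
        faces = grid.boundary_faces()
        self.boundary_nodes = np.unique(faces)
        fx = self.nodes[faces]
        fn = np.cross(fx[:, 1] - fx[:, 0], fx[:, 2] - fx[:, 0]) / 2.0  # area-weighted
        gauss = np.array([[2 / 3, 1 / 6, 1 / 6], [1 / 6, 2 / 3, 1 / 6],
                          [1 / 6, 1 / 6, 2 / 3]])
        for f in range(len(faces)):
            for gq in gauss:
                xg = gq @ fx[f]
                ids, p, _ = mls_shape(xg, self.nodes, self.params, self.radii,
                                      tree=self.tree)
                bint[ids] += np.outer(p, fn[f] / 3.0)
        interior = np.ones(n, dtype=bool)
        interior[self.boundary_nodes] = False
        bint[interior] = 0.0
        # quadrature sum of plain gradients and per-node support volume
        s = np.zeros((n, 3))
        va = np.zeros(n)
        np.add.at(s, self.sup, self.ip_w[:, None, None] * self.grad)
        active = self.phi != 0
        np.add.at(va, self.sup, self.ip_w[:, None] * active)
        corr = (bint - s) / np.where(va > 0, va, 1.0)[:, None]
        self.grad_c = self.grad + corr[self.sup] * active[:, :, None]

        # default uniform material
        self.E = np.full(nip, 3000.0)
        self.nu = 0.49

    @property
    def n_nodes(self):
        return len(self.nodes)

    def set_materials(self, E, nu):
        self.E = np.broadcast_to(np.asarray(E, dtype=float), self.ip_w.shape).copy()
        self.nu = float(nu)

    # -- kinematics ------------------------------------------------------
    def deformation_gradients(self, d):
        """F = I + sum_a d_a grad(phi_a) at every integration point."""
        dsup = d[self.sup]  # (nip, smax, 3)
        H = np.matmul(dsup.transpose(0, 2, 1), self.grad)
        return H + np.eye(3)

    def evaluate(self, d, points):
        """MLS-interpolated field values at arbitrary points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.zeros((len(pts),) + d.shape[1:])
        for i, p in enumerate(pts):
            ids, phi, _ = mls_shape(p, self.nodes, self.params, self.radii,
                                    tree=self.tree)
            out[i] = phi @ d[ids]
        return out


def internal_forces(model: MeshlessModel, d):
    """Nodal internal forces and total strain energy for parameters ``d``.

    Total-Lagrangian assembly: f_a = sum_ip w * P(F) grad~(phi_a) with the
    first Piola-Kirchhoff stress P = F S and corrected test gradients.
    """
    F = model.deformation_gradients(d)
    S = neo_hookean_pk2(F, model.E, model.nu)
    P = np.matmul(F, S)
    contrib = model.ip_w[:, None, None] * np.matmul(model.grad_c,
                                                    np.swapaxes(P, 1, 2))
    idx = model.sup.ravel()
    f = np.stack([np.bincount(idx, weights=contrib[:, :, k].ravel(),
                              minlength=model.n_nodes) for k in range(3)], axis=1)
    W = float(np.sum(model.ip_w * neo_hookean_energy(F, model.E, model.nu)))
    return f, W


# ---------------------------------------------------------------------------
# Loads / configuration / state
# ---------------------------------------------------------------------------

@dataclass
class LoadTable:
    """Prescribed nodal displacements: unique node ids + vectors (mm)."""

    node_ids: np.ndarray
    displacements: np.ndarray

    def __post_init__(self):
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64).ravel()
        self.displacements = np.asarray(self.displacements, dtype=float).reshape(-1, 3)
        if len(self.node_ids) != len(self.displacements):
            raise ValueError("node_ids / displacements length mismatch")
        if len(np.unique(self.node_ids)) != len(self.node_ids):
            raise ValueError("duplicate node ids in load table")
        if not np.isfinite(self.displacements).all():
            raise ValueError("non-finite prescribed displacement")

    def save_txt(self, path):
        with open(path, "w") as f:
            for i, u in zip(self.node_ids, self.displacements):
                f.write(f"{i} {u[0]:.9g} {u[1]:.9g} {u[2]:.9g}\n")

    @classmethod
    def load_txt(cls, path):
        data = np.loadtxt(path, ndmin=2)
        return cls(data[:, 0].astype(int), data[:, 1:4])


@dataclass
class MTLEDConfig:
    """Adaptive dynamic relaxation settings.

    Masses are fictitious (scaled for stability at ``dt``), so ``density``
    only sets their overall scale and does not affect the converged static
    solution.  Termination: the max nodal displacement increment must stay
    below ``tol`` (mm) for ``tol_window`` consecutive steps after the load
    ramp completes.
    """

    dt: float = 1.0
    density: float = 1000.0
    mass_safety: float = 1.5
    ramp_steps: int = 500
    max_steps: int = 20000
    tol: float = 1e-5
    tol_window: int = 100

    def __post_init__(self):
        if self.dt <= 0 or self.mass_safety < 1.0:
            raise ValueError("dt must be > 0 and mass_safety >= 1")


@dataclass
class DeformationState:
    parameters: np.ndarray        # nodal MLS parameters (= displacements)
    displacements: np.ndarray     # evaluated nodal displacements, mm
    steps: int
    converged: bool
    energy_history: np.ndarray    # total (strain + kinetic) energy per step
    model: MeshlessModel = field(repr=False, default=None)

    def deformation_gradients(self):
        return self.model.deformation_gradients(self.parameters)


def _ramp_345(tau):
    t = np.clip(tau, 0.0, 1.0)
    return 10 * t ** 3 - 15 * t ** 4 + 6 * t ** 5


def solve_static(model_or_grid, loads: LoadTable, config: MTLEDConfig | None = None,
                 params: MLSParams | None = None, E=3000.0, nu: float = 0.49):
    """Static solution by explicit central differences with adaptive dynamic
    relaxation.  Prescribed nodes track the smoothly ramped loads exactly.
    """
    if isinstance(model_or_grid, MeshlessModel):
        model = model_or_grid
    else:
        model = MeshlessModel(model_or_grid,
                              params or MLSParams(interpolating=True))
        model.set_materials(E, nu)
    cfg = config or MTLEDConfig()
    n = model.n_nodes
    pid = loads.node_ids
    if len(pid) and pid.max() >= n:
        raise ValueError("load table references nonexistent nodes")
    target = loads.displacements
    free = np.ones(n, dtype=bool)
    free[pid] = False

    # stability mass: row-sum bound on the linearized stiffness
    mu, K = _nh_moduli(model.E, model.nu)
    emod = K + 4.0 * mu / 3.0  # constrained (P-wave) modulus
    gn = np.linalg.norm(model.grad, axis=2)           # (nip, smax)
    srow = gn.sum(axis=1)                             # sum_b |grad phi_b|
    ka = np.zeros(n)
    np.add.at(ka, model.sup, (model.ip_w * emod * srow)[:, None] * gn)
    m = cfg.mass_safety * 0.25 * cfg.dt ** 2 * ka
    m[m <= 0] = m[m > 0].min() if np.any(m > 0) else 1.0

    d = np.zeros((n, 3))
    v = np.zeros((n, 3))
    r_prev = None
    c_damp = 0.0
    dt = cfg.dt
    energy = []
    inc_hist = []
    W0 = None
    for step in range(1, cfg.max_steps + 1):
        d_old = d.copy()
        try:
            f, W = internal_forces(model, d)
        except ValueError as exc:  # element inversion mid-iteration
            raise RuntimeError(
                "MTLED diverged (element inversion); reduce the time step, "
                "increase mass_safety, or lengthen the load ramp") from exc
        r = -f
        # adaptive damping from a Rayleigh-quotient estimate of the lowest mode
        if r_prev is not None:
            vmask = np.abs(v) > 1e-30
            k_loc = np.zeros_like(v)
            k_loc[vmask] = -(r[vmask] - r_prev[vmask]) / (dt * v[vmask])
            num = float(np.sum(k_loc[free] * d[free] ** 2))
            den = float(np.sum(m[free, None] * d[free] ** 2))
            lam = max(num / den, 0.0) if den > 0 else 0.0
            c_damp = min(2.0 * np.sqrt(lam), 1.9 / dt)
        r_prev = r
        a = r / m[:, None]
        v = ((2.0 - c_damp * dt) * v + 2.0 * dt * a) / (2.0 + c_damp * dt)
        d = d + dt * v
        d[pid] = _ramp_345(step / max(cfg.ramp_steps, 1)) * target
        v[pid] = (d[pid] - d_old[pid]) / dt

        Wkin = 0.5 * float(np.sum(m[:, None] * v ** 2))
        energy.append(W + Wkin)
        if W0 is None:
            W0 = max(abs(W + Wkin), 1.0)
        if not np.isfinite(W) or abs(W) > 1e12 * W0:
            raise RuntimeError(
                "MTLED diverged (energy blow-up); reduce the time step, "
                "increase mass_safety, or lengthen the load ramp")
        inc = float(np.abs(d - d_old).max())
        inc_hist.append(inc)
        if step > cfg.ramp_steps + cfg.tol_window and \
                max(inc_hist[-cfg.tol_window:]) < cfg.tol:
            disp = d.copy()
            return DeformationState(d, disp, step, True, np.asarray(energy), model)
    warnings.warn("MTLED did not reach the displacement-increment tolerance "
                  f"within {cfg.max_steps} steps")
    return DeformationState(d, d.copy(), cfg.max_steps, False,
                            np.asarray(energy), model)


def reaction_force(state: DeformationState, normal, cos_tol: float = 0.9):
    """Resultant nominal (first Piola-Kirchhoff) traction over the boundary
    faces whose outward normal aligns with ``normal``.

    Integrates P(F) N over the selected reference faces with a 3-point rule;
    exact for homogeneous deformation states, which makes it the appropriate
    reaction measurement for uniform-compression benchmarks.
    """
    model = state.model
    d = state.parameters
    nrm = np.asarray(normal, dtype=float)
    nrm = nrm / np.linalg.norm(nrm)
    faces = model.grid.boundary_faces()
    fx = model.nodes[faces]
    fn = np.cross(fx[:, 1] - fx[:, 0], fx[:, 2] - fx[:, 0]) / 2.0
    area = np.linalg.norm(fn, axis=1)
    sel = (fn @ nrm) / np.where(area > 0, area, 1) > cos_tol
    gauss = np.array([[2 / 3, 1 / 6, 1 / 6], [1 / 6, 2 / 3, 1 / 6],
                      [1 / 6, 1 / 6, 2 / 3]])
    from scipy.spatial import cKDTree as _KD
    ip_tree = _KD(model.ip_pos)
    force = np.zeros(3)
    for f in np.flatnonzero(sel):
        for gq in gauss:
            xg = gq @ fx[f]
            ids, _, g = mls_shape(xg, model.nodes, model.params, model.radii,
                                  tree=model.tree)
            F = np.eye(3) + np.einsum("sk,sl->kl", d[ids], g)
            _, nn = ip_tree.query(xg)  # material of the nearest integration point
            S = neo_hookean_pk2(F, float(model.E[nn]), model.nu)
            force += (F @ S) @ fn[f] / 3.0
    return force


# ---------------------------------------------------------------------------
# Material assignment from an intensity image
# ---------------------------------------------------------------------------

def assign_materials(model: MeshlessModel, intensity, mask, material_config):
    """Membership-weighted Young's modulus per integration point.

    ``material_config``: dict with keys ``class_E`` (list of per-class E, Pa),
    ``nu`` (float), ``n_clusters`` (defaults to len(class_E)).  Memberships
    come from fuzzy C-means on the image intensity within the mask.
    """
    from .tissue import FCMConfig, fcm

    class_E = np.asarray(material_config["class_E"], dtype=float)
    nu = float(material_config.get("nu", 0.49))
    ncl = int(material_config.get("n_clusters", len(class_E)))
    vals = intensity.values[mask.values][:, None]
    memb, centers = fcm(vals, FCMConfig(n_clusters=ncl,
                                        seed=int(material_config.get("seed", 0))))
    order = np.argsort(centers[:, 0])  # ascending intensity -> class_E order
    memb = memb[:, order]

    # voxel lookup per integration point (nearest voxel)
    grid = intensity.grid
    idx = np.rint(grid.world_to_index(model.ip_pos)).astype(int)
    dims = np.asarray(grid.dims)
    outside = np.any((idx < 0) | (idx >= dims), axis=1)
    if outside.any():
        warnings.warn(f"{int(outside.sum())} integration points outside the "
                      "image; clamped to nearest voxel")
        idx = np.clip(idx, 0, dims - 1)
    flat_memb = np.zeros(tuple(grid.dims) + (ncl,))
    flat_memb[mask.values] = memb
    # points over unmasked voxels: nearest masked voxel via distance transform
    from scipy import ndimage as ndi
    if not mask.values.all():
        _, nearest = ndi.distance_transform_edt(~mask.values,
                                                sampling=grid.spacing,
                                                return_indices=True)
        nm = ~mask.values[idx[:, 0], idx[:, 1], idx[:, 2]]
        if nm.any():
            ni = nearest[:, idx[nm, 0], idx[nm, 1], idx[nm, 2]]
            idx[nm] = ni.T
    u = flat_memb[idx[:, 0], idx[:, 1], idx[:, 2]]
    E = u @ class_E
    model.set_materials(E, nu)
    return model


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_abaqus_inp(path) -> TetBackgroundGrid:
    """Minimal Abaqus-style reader: *NODE and *ELEMENT (C3D4) blocks."""
    nodes, node_ids, tets = [], [], []
    section = None
    with open(path) as f:
        for raw in f:
            line = raw.strip()
            if not line or line.startswith("**"):
                continue
            if line.startswith("*"):
                kw = line.split(",")[0].strip().upper()
                if kw == "*NODE":
                    section = "node"
                elif kw == "*ELEMENT":
                    up = line.upper()
                    section = "elem" if "C3D4" in up or "TYPE" not in up else None
                else:
                    section = None
                continue
            parts = [p for p in line.replace(",", " ").split()]
            if section == "node":
                node_ids.append(int(parts[0]))
                nodes.append([float(x) for x in parts[1:4]])
            elif section == "elem":
                tets.append([int(x) for x in parts[1:5]])
    if not nodes:
        raise ValueError("no *NODE section found")
    remap = {nid: i for i, nid in enumerate(node_ids)}
    tets = np.asarray([[remap[i] for i in t] for t in tets])
    return TetBackgroundGrid(np.asarray(nodes), tets)


def write_vtu(path, points, cells=None, cell_type="tetra", point_data=None):
    """Minimal ASCII .vtu writer (unstructured grid, point data arrays)."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if cells is None:
        cells = np.arange(len(points)).reshape(-1, 1)
        vtk_type, npc = 1, 1  # vertex
    elif cell_type == "tetra":
        vtk_type, npc = 10, 4
    elif cell_type == "hexahedron":
        vtk_type, npc = 12, 8
    else:
        raise ValueError(f"unsupported cell type {cell_type}")
    cells = np.asarray(cells, dtype=np.int64).reshape(-1, npc)
    with open(path, "w") as f:
        f.write('<?xml version="1.0"?>\n')
        f.write('<VTKFile type="UnstructuredGrid" version="0.1" '
                'byte_order="LittleEndian">\n<UnstructuredGrid>\n')
        f.write(f'<Piece NumberOfPoints="{len(points)}" NumberOfCells="{len(cells)}">\n')
        f.write('<Points><DataArray type="Float64" NumberOfComponents="3" '
                'format="ascii">\n')
        np.savetxt(f, points, fmt="%.9g")
        f.write('</DataArray></Points>\n<Cells>\n')
        f.write('<DataArray type="Int64" Name="connectivity" format="ascii">\n')
        np.savetxt(f, cells, fmt="%d")
        f.write('</DataArray>\n<DataArray type="Int64" Name="offsets" format="ascii">\n')
        np.savetxt(f, np.arange(1, len(cells) + 1) * npc, fmt="%d")
        f.write('</DataArray>\n<DataArray type="UInt8" Name="types" format="ascii">\n')
        np.savetxt(f, np.full(len(cells), vtk_type), fmt="%d")
        f.write('</DataArray>\n</Cells>\n')
        if point_data:
            f.write("<PointData>\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr, dtype=float)
                nc = 1 if arr.ndim == 1 else arr.shape[1]
                f.write(f'<DataArray type="Float64" Name="{name}" '
                        f'NumberOfComponents="{nc}" format="ascii">\n')
                np.savetxt(f, arr.reshape(len(points), nc), fmt="%.9g")
                f.write("</DataArray>\n")
            f.write("</PointData>\n")
        f.write("</Piece>\n</UnstructuredGrid>\n</VTKFile>\n")
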