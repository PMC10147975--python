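"""Synthetic head phantoms and analytic dipole-potential oracles.

Generates concentric-sphere label images, synthetic diffusion-tensor images
and synthetic electrode grids emulating a real ECoG dataset, plus two
independent analytic solutions used to validate the forward solver:

* the dipole potential in an infinite homogeneous anisotropic medium
  (also the singularity potential of the full-subtraction source model), and
* the classical Legendre-series potential of a dipole inside a multilayer
  concentric sphere with insulating exterior.

Units: positions/radii in mm, conductivity in S/m, dipole moment in A*mm,
eigenvalues of diffusion tensors in mm^2/s.  Potentials are consistent across
the analytic and FEM paths (same unit system), which is all the shape/
magnitude metrics require.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .images import ImageGrid, LabelImage, TensorImage
from .surface import PointSet, TriSurface, closest_point_on_surface

__all__ = [
    "SpherePhantomSpec",
    "SyntheticDTISpec",
    "AnalyticSphereModel",
    "make_sphere_phantom",
    "make_synthetic_dti",
    "analytic_dipole_infinite",
    "analytic_dipole_infinite_gradient",
    "analytic_dipole_sphere",
    "make_electrode_grid",
]


# ---------------------------------------------------------------------------
# Sphere label phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpherePhantomSpec:
    """Concentric-sphere phantom: radii strictly decreasing, outer to inner.

    ``layer_labels[i]`` is the integer code of the shell between
    ``layer_radii[i]`` and ``layer_radii[i+1]`` (the last label fills the
    innermost sphere).  The sphere center defaults to the grid center.
    """

    layer_radii: tuple          # mm, outer to inner
    layer_labels: tuple         # integer codes, same length
    grid_dims: tuple = (64, 64, 64)
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple | None = None
    center: tuple | None = None

    def __post_init__(self):
        radii = tuple(float(r) for r in self.layer_radii)
        labels = tuple(int(l) for l in self.layer_labels)
        if len(radii) == 0:
            raise ValueError("at least one layer radius required")
        if len(radii) != len(labels):
            raise ValueError("layer_radii and layer_labels must have equal length")
        if any(r2 >= r1 for r1, r2 in zip(radii, radii[1:])):
            raise ValueError("radii must be strictly decreasing (outer to inner)")
        if len(set(labels)) != len(labels) or any(l <= 0 for l in labels):
            raise ValueError("labels must be distinct positive integers")
        object.__setattr__(self, "layer_radii", radii)
        object.__setattr__(self, "layer_labels", labels)
        object.__setattr__(self, "grid_dims", tuple(int(d) for d in self.grid_dims))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    def grid(self) -> ImageGrid:
        dims, sp = self.grid_dims, self.spacing
        if self.origin is not None:
            origin = tuple(self.origin)
        else:
            # grid centered on the world origin
            origin = tuple(-(d - 1) * s / 2 for d, s in zip(dims, sp))
        return ImageGrid(dims, sp, origin)

    def sphere_center(self) -> np.ndarray:
        if self.center is not None:
            return np.asarray(self.center, dtype=float)
        g = self.grid()
        return g.index_to_world([(d - 1) / 2 for d in g.dims])[0]


def make_sphere_phantom(spec: SpherePhantomSpec) -> LabelImage:
    """Label each voxel by the innermost layer containing its center."""
    grid = spec.grid()
    c = spec.sphere_center()
    rmax = spec.layer_radii[0]
    half_extent = np.array([(d - 1) * s / 2 for d, s in zip(grid.dims, grid.spacing)])
    if np.any(np.abs(c - np.asarray(grid.origin)) > half_extent * 2 + 1e-9) or \
            np.any(rmax > half_extent + min(grid.spacing) / 2 + 1e-9):
        raise ValueError("outer radius does not fit inside the grid extent")
    pts = grid.voxel_centers().reshape(-1, 3)
    r = np.linalg.norm(pts - c, axis=1)
    radii = np.asarray(spec.layer_radii)
    labels = np.asarray(spec.layer_labels)
    # number of layers whose sphere contains the point; innermost wins
    count = (r[:, None] <= radii[None, :] + 1e-12).sum(axis=1)
    out = np.zeros(len(pts), dtype=np.int64)
    inside = count > 0
    out[inside] = labels[count[inside] - 1]
    return LabelImage(grid, out.reshape(grid.dims))


# ---------------------------------------------------------------------------
# Synthetic diffusion tensors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticDTISpec:
    """Per-label tensor eigenvalues plus a fiber direction field.

    ``eigenvalues``: mapping label -> (l1, l2, l3) in mm^2/s, l1 along the
    fiber direction.  ``direction``: "constant" (uses ``direction_vector``),
    "radial" or "tangential" with respect to ``center``.  Additive Gaussian
    noise of standard deviation ``noise_sd`` (mm^2/s) is applied to the six
    unique tensor components (seeded, reproducible).
    """

    eigenvalues: dict
    direction: str = "constant"
    direction_vector: tuple = (1.0, 0.0, 0.0)
    center: tuple = (0.0, 0.0, 0.0)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for lab, ev in self.eigenvalues.items():
            if len(ev) != 3 or any(e < 0 for e in ev):
                raise ValueError(f"eigenvalues for label {lab} must be 3 nonnegative values")
        if self.direction not in ("constant", "radial", "tangential"):
            raise ValueError("direction must be constant|radial|tangential")
        v = np.linalg.norm(self.direction_vector)
        if self.direction == "constant" and not np.isclose(v, 1.0):
            raise ValueError("direction_vector must be unit norm")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _complete_frame(e1: np.ndarray) -> np.ndarray:
    """Orthonormal frames (..., 3, 3) with first column e1 (deterministic)."""
    e1 = np.asarray(e1, dtype=float)
    helper = np.broadcast_to(np.array([1.0, 0.0, 0.0]), e1.shape).copy()
    swap = np.abs(e1[..., 0]) > 0.9
    helper[swap] = [0.0, 1.0, 0.0]
    e2 = helper - np.einsum("...i,...i->...", helper, e1)[..., None] * e1
    e2 /= np.linalg.norm(e2, axis=-1, keepdims=True)
    e3 = np.cross(e1, e2)
    return np.stack([e1, e2, e3], axis=-1)


def make_synthetic_dti(labels: LabelImage, spec: SyntheticDTISpec) -> TensorImage:
    """Per-voxel D = R diag(lambda) R^T from the label map and direction field."""
    present = set(int(l) for l in labels.labels)
    missing = present - set(int(k) for k in spec.eigenvalues)
    if missing:
        raise ValueError(f"no eigenvalue triple for labels {sorted(missing)}")
    grid = labels.grid
    pts = grid.voxel_centers().reshape(-1, 3)
    c = np.asarray(spec.center, dtype=float)
    if spec.direction == "constant":
        e1 = np.broadcast_to(np.asarray(spec.direction_vector, float), pts.shape).copy()
    elif spec.direction == "radial":
        d = pts - c
        nrm = np.linalg.norm(d, axis=1, keepdims=True)
        e1 = np.where(nrm > 1e-12, d / np.where(nrm > 0, nrm, 1), [1.0, 0.0, 0.0])
    else:  # tangential: azimuthal around the z axis through the center
        d = pts - c
        t = np.stack([-d[:, 1], d[:, 0], np.zeros(len(d))], axis=1)
        nrm = np.linalg.norm(t, axis=1, keepdims=True)
        e1 = np.where(nrm > 1e-12, t / np.where(nrm > 0, nrm, 1), [1.0, 0.0, 0.0])
    R = _complete_frame(e1)  # (n, 3, 3)

    lam = np.zeros((len(pts), 3))
    flat = labels.values.ravel()
    for lab, ev in spec.eigenvalues.items():
        lam[flat == int(lab)] = ev
    D = np.einsum("nij,nj,nkj->nik", R, lam, R)
    comp = TensorImage.matrices_to_components(D)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        comp = comp + rng.normal(0.0, spec.noise_sd, comp.shape)
    comp[flat == 0] = 0.0
    return TensorImage(grid, comp.reshape(grid.dims + (6,)))


# ---------------------------------------------------------------------------
# Infinite-medium dipole (full-subtraction singularity potential)
# ---------------------------------------------------------------------------

def _prep_sigma(sigma):
    S = np.asarray(sigma, dtype=float)
    if S.shape == ():
        S = float(S) * np.eye(3)
    if S.shape != (3, 3) or not np.allclose(S, S.T, atol=1e-12):
        raise ValueError("sigma must be a symmetric 3x3 tensor (or scalar)")
    w = np.linalg.eigvalsh(S)
    if w.min() <= 0:
        raise ValueError("sigma must be positive definite")
    return S


def analytic_dipole_infinite(sigma, position, moment, points) -> np.ndarray:
    """Potential of a current dipole in an infinite homogeneous anisotropic
    medium::

        phi(r) = (1/4pi) det(S)^(-1/2) [m . S^-1 d] / (d^T S^-1 d)^(3/2),
        d = r - r0.
    """
    S = _prep_sigma(sigma)
    r0 = np.asarray(position, dtype=float)
    m = np.asarray(moment, dtype=float)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = pts - r0
    Sinv = np.linalg.inv(S)
    q = np.einsum("ni,ij,nj->n", d, Sinv, d)
    if np.any(q <= 0) or np.any(np.linalg.norm(d, axis=1) < 1e-12):
        raise ValueError("evaluation point coincides with the dipole position")
    num = d @ Sinv @ m
    return num / (4.0 * np.pi * np.sqrt(np.linalg.det(S)) * q ** 1.5)


def analytic_dipole_infinite_gradient(sigma, position, moment, points) -> np.ndarray:
    """Gradient of :func:`analytic_dipole_infinite` with respect to r."""
    S = _prep_sigma(sigma)
    r0 = np.asarray(position, dtype=float)
    m = np.asarray(moment, dtype=float)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = pts - r0
    Sinv = np.linalg.inv(S)
    q = np.einsum("ni,ij,nj->n", d, Sinv, d)
    if np.any(q <= 0):
        raise ValueError("evaluation point coincides with the dipole position")
    Sm = Sinv @ m
    Sd = d @ Sinv
    c = 1.0 / (4.0 * np.pi * np.sqrt(np.linalg.det(S)))
    return c * (Sm[None, :] * q[:, None] ** -1.5
                - 3.0 * (d @ Sm)[:, None] * Sd * q[:, None] ** -2.5)


# ---------------------------------------------------------------------------
# Multilayer sphere series oracle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalyticSphereModel:
    """Concentric-sphere volume conductor with insulating exterior.

    ``layer_radii``/``layer_conductivities`` are outer to inner (matching
    :class:`SpherePhantomSpec`); conductivities are isotropic per layer.  The
    dipole must lie strictly inside the innermost sphere.
    """

    layer_radii: tuple              # mm, outer to inner
    layer_conductivities: tuple     # S/m, outer to inner
    dipole_position: tuple          # mm
    dipole_moment: tuple            # A*mm
    n_terms: int = 80

    def __post_init__(self):
        radii = tuple(float(r) for r in self.layer_radii)
        sig = tuple(float(s) for s in self.layer_conductivities)
        if len(radii) != len(sig) or not radii:
            raise ValueError("radii and conductivities must be non-empty, equal length")
        if any(r2 >= r1 for r1, r2 in zip(radii, radii[1:])):
            raise ValueError("radii must be strictly decreasing")
        if any(s <= 0 for s in sig):
            raise ValueError("conductivities must be positive")
        if self.n_terms < 1:
            raise ValueError("n_terms >= 1 required")
        b = np.linalg.norm(self.dipole_position)
        if b >= radii[-1]:
            raise ValueError("dipole must lie strictly inside the innermost sphere")
        object.__setattr__(self, "layer_radii", radii)
        object.__setattr__(self, "layer_conductivities", sig)


def _series_coefficients(model: AnalyticSphereModel):
    """Per-degree layer coefficients for the radial and tangential channels.

    Returns (A, B, sR, sT, frame, b_scaled, R) where A/B have shape
    (n_terms+1, L) in scaled radius units (r' = r / outer radius), layer index
    0 = innermost region.
    """
    radii = np.asarray(model.layer_radii[::-1])   # increasing, r_1..r_L
    sig = np.asarray(model.layer_conductivities[::-1])
    L = len(radii)
    R = radii[-1]
    rs = radii / R

    p = np.asarray(model.dipole_position, dtype=float)
    m = np.asarray(model.dipole_moment, dtype=float)
    b = np.linalg.norm(p)
    if b > 1e-12:
        ez = p / b
    else:
        nm = np.linalg.norm(m)
        ez = m / nm if nm > 0 else np.array([0.0, 0.0, 1.0])
    m_r = float(m @ ez)
    mt_vec = m - m_r * ez
    m_t = float(np.linalg.norm(mt_vec))
    ex = mt_vec / m_t if m_t > 1e-15 else _complete_frame(ez[None])[0][:, 1]
    ey = np.cross(ez, ex)
    frame = np.stack([ex, ey, ez], axis=1)  # columns

    bs = b / R
    N = model.n_terms
    A = np.zeros((N + 1, L))
    B = np.zeros((N + 1, L))
    AT_arr = np.zeros((N + 1, L))
    BT_arr = np.zeros((N + 1, L))
    sR = np.zeros(N + 1)
    sT = np.zeros(N + 1)
    for n in range(1, N + 1):
        bpow = bs ** (n - 1) if (bs > 0 or n == 1) else 0.0
        s_r = n * m_r * bpow / (4 * np.pi * sig[0] * R ** 2)
        s_t = -m_t * bpow / (4 * np.pi * sig[0] * R ** 2)
        sR[n], sT[n] = s_r, s_t
        # unknowns x = [A_1, A_2, B_2, ..., A_L, B_L]  (scaled radii)
        dim = 2 * L - 1
        M = np.zeros((dim, dim))
        rhs = np.zeros((dim, 2))

        def a_idx(j):  # region j (0-based)
            return 0 if j == 0 else 2 * j - 1

        def b_idx(j):
            return 2 * j

        row = 0
        for i in range(L - 1):  # interface between region i and i+1 at rs[i]
            r = rs[i]
            rp, rm = r ** n, r ** -(n + 1)
            # continuity of phi
            M[row, a_idx(i)] += rp
            if i > 0:
                M[row, b_idx(i)] += rm
            M[row, a_idx(i + 1)] -= rp
            M[row, b_idx(i + 1)] -= rm
            if i == 0:
                rhs[row] -= [s_r * rm, s_t * rm]
            row += 1
            # continuity of sigma dphi/dr
            dp, dm = n * r ** (n - 1), -(n + 1) * r ** -(n + 2)
            M[row, a_idx(i)] += sig[i] * dp
            if i > 0:
                M[row, b_idx(i)] += sig[i] * dm
            M[row, a_idx(i + 1)] -= sig[i + 1] * dp
            M[row, b_idx(i + 1)] -= sig[i + 1] * dm
            if i == 0:
                rhs[row] -= [sig[0] * s_r * dm, sig[0] * s_t * dm]
            row += 1
        # insulating outer boundary at rs[-1] = 1
        M[row, a_idx(L - 1)] += n
        if L > 1:
            M[row, b_idx(L - 1)] += -(n + 1)
            rhs[row] -= [0.0, 0.0]
        else:
            rhs[row] -= [-(n + 1) * s_r, -(n + 1) * s_t]
        sol = np.linalg.solve(M, rhs)
        for j in range(L):
            A[n, j] = sol[a_idx(j), 0]
            AT_arr[n, j] = sol[a_idx(j), 1]
            if j > 0:
                B[n, j] = sol[b_idx(j), 0]
                BT_arr[n, j] = sol[b_idx(j), 1]
    return (A, B, AT_arr, BT_arr, sR, sT, frame, bs, R, rs)


def analytic_dipole_sphere(model: AnalyticSphereModel, points,
                           rtol: float = 1e-10) -> np.ndarray:
    """Series potential of a dipole in a multilayer sphere at given points.

    Points must satisfy ``|p| > |dipole|`` (series about the center converges
    outside the dipole radius) and lie inside the outer sphere.  Emits a
    warning when the truncated series has not reached ``rtol`` relative
    convergence.
    """
    A, B, AT, BT, sR, sT, frame, bs, R, rs = _series_coefficients(model)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    loc = pts @ frame  # coordinates in (ex, ey, ez)
    r = np.linalg.norm(loc, axis=1)
    rsc = r / R
    if np.any(rsc > 1.0 + 1e-9):
        raise ValueError("points must lie on or inside the outer sphere")
    if np.any(rsc <= bs + 1e-12):
        raise ValueError("points must lie at radius greater than the dipole radius")
    ct = np.where(r > 0, loc[:, 2] / np.where(r > 0, r, 1), 1.0)
    st = np.sqrt(np.clip(1 - ct ** 2, 0, None))
    rho = np.hypot(loc[:, 0], loc[:, 1])
    cphi = np.where(rho > 1e-15, loc[:, 0] / np.where(rho > 0, rho, 1), 0.0)

    # region index per point (0 = innermost)
    region = np.searchsorted(rs, rsc - 1e-12)
    region = np.clip(region, 0, len(rs) - 1)

    N = A.shape[0] - 1
    phi = np.zeros(len(pts))
    # Legendre recursions for P_n(ct) and P_n^1(ct) (Condon-Shortley phase)
    Pm1 = np.ones_like(ct)            # P_0
    P = ct.copy()                     # P_1
    P1m1 = np.zeros_like(ct)          # P_0^1
    P1 = -st                          # P_1^1
    converged = False
    for n in range(1, N + 1):
        rp = rsc ** n
        rm = rsc ** -(n + 1)
        radA = A[n, region] * rp + B[n, region] * rm
        radA = radA + np.where(region == 0, sR[n] * rm, 0.0)
        radT = AT[n, region] * rp + BT[n, region] * rm
        radT = radT + np.where(region == 0, sT[n] * rm, 0.0)
        term = radA * P + radT * P1 * cphi
        phi += term
        scale = np.abs(phi).max()
        if scale > 0 and np.abs(term).max() < rtol * scale and n >= 2:
            converged = True
            break
        if n < N:
            Pn1 = ((2 * n + 1) * ct * P - n * Pm1) / (n + 1)
            Pm1, P = P, Pn1
            P1n1 = ((2 * n + 1) * ct * P1 - (n + 1) * P1m1) / n
            P1m1, P1 = P1, P1n1
    if not converged and N >= 10:
        warnings.warn("analytic_dipole_sphere: series truncated before reaching "
                      f"relative tolerance {rtol:g} at n_terms={N}")
    return phi


# ---------------------------------------------------------------------------
# Synthetic electrode grids
# ---------------------------------------------------------------------------

def make_electrode_grid(surface: TriSurface, rows: int, cols: int, pitch: float,
                        inward_shift: float = 0.0, seed: int | None = None,
                        direction=None):
    """Synthetic rows x cols electrode grid on a closed surface.

    Returns ``(orig, proj)`` point sets: ``proj`` lies on the surface in a
    regular patch; ``orig`` is ``proj`` displaced *inward* (along the inward
    surface normal) by ``inward_shift`` mm, emulating the post-implantation
    brain shift recorded by a CT scan.
    """
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    if not surface.is_watertight():
        raise ValueError("electrode grid requires a closed surface")
    if direction is not None:
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
    elif seed is not None:
        rng = np.random.default_rng(seed)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
    else:
        d = np.array([0.0, 0.0, 1.0])

    # patch center: surface point nearest to a far point along d (the apex)
    c = surface.vertices.mean(axis=0)
    extent = np.linalg.norm(surface.vertices - c, axis=1).max()
    far = c + 3.0 * extent * d
    p0, _, _ = closest_point_on_surface(far[None], surface)
    p0 = p0[0]
    t1 = _complete_frame(d[None])[0][:, 1]
    t2 = np.cross(d, t1)
    gi = (np.arange(rows) - (rows - 1) / 2) * pitch
    gj = (np.arange(cols) - (cols - 1) / 2) * pitch
    gg1, gg2 = np.meshgrid(gi, gj, indexing="ij")
    plane_pts = p0 + gg1.ravel()[:, None] * t1 + gg2.ravel()[:, None] * t2

    proj_pts, dist, tri_idx = closest_point_on_surface(plane_pts, surface)
    # patch-fit check: projections must stay separated (no fold-over)
    from scipy.spatial.distance import pdist
    if len(proj_pts) > 1 and pdist(proj_pts).min() < 0.2 * pitch:
        raise ValueError("electrode patch does not fit on the surface")
    normals = surface.face_normals()[tri_idx]
    orig_pts = proj_pts - inward_shift * normals

    labels = [f"E{r + 1}_{c + 1}" for r in range(rows) for c in range(cols)]
    return PointSet(orig_pts, list(labels)), PointSet(proj_pts, list(labels))
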