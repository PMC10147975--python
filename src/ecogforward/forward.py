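"""Voxel-hexahedral FEM for the electrostatic ECoG forward problem.

One trilinear hexahedral element per masked voxel, a per-element conductivity
tensor, and a current-dipole source modeled with the full subtraction
approach: the total potential splits into the analytic singularity potential
of the dipole in an infinite homogeneous medium (conductivity sigma0 of the
source neighborhood) plus a numerically computed correction.  The resulting
pure-Neumann system is symmetric positive semidefinite with the constants as
null space; compatibility is enforced by projecting constants out of the
right-hand side, and the gauge is fixed by zero mean over the surface nodes.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg as sparse_cg

from .images import ImageGrid, LabelImage, MaskImage
from .phantom import analytic_dipole_infinite, analytic_dipole_infinite_gradient

__all__ = [
    "HexMesh",
    "ElementTensorField",
    "DipoleSource",
    "ForwardSolution",
    "voxels_to_hexmesh",
    "assemble_system",
    "full_subtraction_rhs",
    "solve_potential",
    "solve_forward",
    "sample_potentials",
    "rdm_mag",
    "write_legacy_vtk",
    "write_mesh_gz",
    "write_gf_gz",
    "write_pvd",
]

_G = 1.0 / np.sqrt(3.0)
# 2x2x2 Gauss points and trilinear corner signs on the reference cube [-1,1]^3
_GAUSS = np.array([[sx * _G, sy * _G, sz * _G]
                   for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)])
# local corner order: VTK hexahedron
_CORNERS = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                     [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]], dtype=float)
_CORNER_OFFSETS = ((_CORNERS + 1) // 2).astype(int)  # 0/1 voxel-corner offsets


def _shape_values(xi):
    """Trilinear N_a(xi) for all 8 corners at points xi (m, 3) -> (m, 8)."""
    xi = np.atleast_2d(xi)
    return np.prod(1.0 + xi[:, None, :] * _CORNERS[None, :, :], axis=2) / 8.0


def _shape_gradients_ref(xi):
    """dN_a/dxi at points xi -> (m, 8, 3)."""
    xi = np.atleast_2d(xi)
    g = np.empty((len(xi), 8, 3))
    for k in range(3):
        terms = [1.0 + xi[:, None, j] * _CORNERS[None, :, j] for j in range(3)]
        terms[k] = np.broadcast_to(_CORNERS[None, :, k], terms[k].shape)
        g[:, :, k] = terms[0] * terms[1] * terms[2] / 8.0
    return g


# ---------------------------------------------------------------------------
# Mesh
# ---------------------------------------------------------------------------

@dataclass
class HexMesh:
    """One hexahedron per masked voxel; shared vertices merged.

    ``voxel_ijk`` keeps the source voxel of every element and
    ``element_of_voxel`` the inverse map (-1 where unmasked), enabling O(1)
    point location on the underlying grid.
    """

    nodes: np.ndarray          # (n, 3) world mm
    hexes: np.ndarray          # (e, 8) int, VTK corner order
    grid: ImageGrid
    voxel_ijk: np.ndarray      # (e, 3) int
    labels: np.ndarray         # (e,) element attribute = source voxel label
    element_of_voxel: np.ndarray = field(repr=False, default=None)  # dims int

    @property
    def n_elements(self):
        return len(self.hexes)

    def total_volume(self) -> float:
        return self.n_elements * self.grid.voxel_volume

    def surface_node_mask(self) -> np.ndarray:
        """Nodes on the exterior (air) boundary of the masked region."""
        mask = self.element_of_voxel >= 0
        out = np.zeros(len(self.nodes), dtype=bool)
        for face_nodes, _, _ in _boundary_faces(self, mask):
            out[face_nodes.ravel()] = True
        return out


def voxels_to_hexmesh(labels_or_mask) -> HexMesh:
    """Build the voxel-conforming hexahedral mesh of all labeled/masked voxels."""
    if isinstance(labels_or_mask, MaskImage):
        sel = labels_or_mask.values
        lab = sel.astype(np.int64)
    elif isinstance(labels_or_mask, LabelImage):
        lab = labels_or_mask.values
        sel = lab > 0
    else:
        raise TypeError("expected a LabelImage or MaskImage")
    grid = labels_or_mask.grid
    if not sel.any():
        raise ValueError("empty mask: no voxels to mesh")
    if np.linalg.det(np.asarray(grid.direction)) <= 0:
        raise ValueError("grid direction must be right-handed")
    ijk = np.argwhere(sel)
    dims = np.asarray(grid.dims)
    nd = dims + 1  # corner lattice

    corner_ids = (ijk[:, None, :] + _CORNER_OFFSETS[None, :, :])  # (e, 8, 3)
    flat = (corner_ids[..., 0] * nd[1] + corner_ids[..., 1]) * nd[2] + corner_ids[..., 2]
    uniq, inv = np.unique(flat, return_inverse=True)
    hexes = inv.reshape(flat.shape).astype(np.int64)
    ci = np.empty((len(uniq), 3), dtype=float)
    ci[:, 2] = uniq % nd[2]
    rem = uniq // nd[2]
    ci[:, 1] = rem % nd[1]
    ci[:, 0] = rem // nd[1]
    nodes = grid.index_to_world(ci - 0.5)

    eov = np.full(tuple(dims), -1, dtype=np.int64)
    eov[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = np.arange(len(ijk))
    return HexMesh(nodes, hexes, grid, ijk, lab[ijk[:, 0], ijk[:, 1], ijk[:, 2]], eov)


@dataclass
class ElementTensorField:
    """Symmetric positive definite 3x3 conductivity per element (S/m)."""

    tensors: np.ndarray  # (e, 3, 3)

    def __post_init__(self):
        self.tensors = np.asarray(self.tensors, dtype=float).reshape(-1, 3, 3)
        if not np.allclose(self.tensors, np.swapaxes(self.tensors, 1, 2), atol=1e-12):
            raise ValueError("element tensors must be symmetric")

    @classmethod
    def from_tensor_image(cls, cond_image, mesh: HexMesh):
        T = cond_image.to_matrices()
        return cls(T[mesh.voxel_ijk[:, 0], mesh.voxel_ijk[:, 1], mesh.voxel_ijk[:, 2]])

    def check_spd(self):
        w = np.linalg.eigvalsh(self.tensors)
        bad = np.flatnonzero(w[:, 0] <= 0)
        if len(bad):
            raise ValueError(f"non-SPD conductivity tensor at element {int(bad[0])}")


@dataclass
class DipoleSource:
    """Current dipole: position (mm), moment (A*mm), and the homogeneous
    conductivity sigma0 (S/m) of its neighborhood."""

    position: np.ndarray
    moment: np.ndarray
    sigma0: np.ndarray | None = None  # set from the mesh if None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.moment = np.asarray(self.moment, dtype=float).reshape(3)
        if self.sigma0 is not None:
            s = np.asarray(self.sigma0, dtype=float)
            self.sigma0 = float(s) * np.eye(3) if s.ndim == 0 else s.reshape(3, 3)


@dataclass
class ForwardSolution:
    total: np.ndarray        # nodal total potential
    correction: np.ndarray   # nodal correction potential
    singularity: np.ndarray  # nodal singularity potential phi_inf
    iterations: int
    residual: float
    mesh: HexMesh = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def _element_gradients(grid: ImageGrid):
    """World-space shape gradients at the 8 Gauss points (same for every
    element of a regular voxel mesh): (8q, 8a, 3)."""
    J = 0.5 * grid.affine  # dx/dxi
    Jinv_T = np.linalg.inv(J).T
    return _shape_gradients_ref(_GAUSS) @ Jinv_T


def assemble_system(mesh: HexMesh, cond: ElementTensorField):
    """Stiffness K_ab = sum_e int grad(N_a) . sigma_e grad(N_b), 2x2x2 Gauss.

    Pure-Neumann operator: symmetric, row sums zero (constant null space).
    """
    cond.check_spd()
    G = _element_gradients(mesh.grid)  # (8, 8, 3)
    wdet = mesh.grid.voxel_volume / 8.0
    # Ke (e, 8, 8) = sum_q G[q] sigma_e G[q]^T * wdet
    Ke = np.einsum("qak,ekl,qbl->eab", G, cond.tensors, G) * wdet
    n = len(mesh.nodes)
    rows = np.repeat(mesh.hexes, 8, axis=1).ravel()
    cols = np.tile(mesh.hexes, (1, 8)).ravel()
    K = sparse.coo_matrix((Ke.ravel(), (rows.astype(np.int64), cols.astype(np.int64))),
                          shape=(n, n)).tocsr()
    return K


def _boundary_faces(mesh: HexMesh, mask):
    """Yield (face_nodes (f,4), outward unit normal (3,), face area) per
    axis/side: voxel faces adjacent to unmasked space."""
    # local corner indices of each hex face, by axis and side (VTK order)
    face_local = {
        (0, -1): [0, 3, 7, 4], (0, 1): [1, 2, 6, 5],
        (1, -1): [0, 1, 5, 4], (1, 1): [3, 2, 6, 7],
        (2, -1): [0, 1, 2, 3], (2, 1): [4, 5, 6, 7],
    }
    A = mesh.grid.affine
    sp = np.asarray(mesh.grid.spacing)
    areas = {0: sp[1] * sp[2], 1: sp[0] * sp[2], 2: sp[0] * sp[1]}
    for (axis, side), loc in face_local.items():
        shifted = np.roll(mask, -side, axis=axis)
        edge = np.zeros_like(mask)
        sl = [slice(None)] * 3
        sl[axis] = -1 if side == 1 else 0
        edge[tuple(sl)] = True
        exposed = mask & (edge | ~shifted)
        ev = mesh.element_of_voxel[exposed]
        if len(ev) == 0:
            continue
        fn = mesh.hexes[ev][:, loc]
        nrm = side * A[:, axis] / np.linalg.norm(A[:, axis])
        yield fn, nrm, areas[axis]


def full_subtraction_rhs(mesh: HexMesh, cond: ElementTensorField,
                         dipole: DipoleSource, homogeneity_radius_voxels: float = 3.0,
                         homogeneity_rtol: float = 1e-8, project: bool = True):
    """Full-subtraction load vector.

    b_a = -int grad(N_a) . (sigma - sigma0) grad(phi_inf) dOmega
          -oint N_a (sigma0 grad(phi_inf) . n) dGamma   (exterior faces).

    The dipole must sit in a neighborhood (``homogeneity_radius_voxels``)
    whose conductivity matches sigma0; with ``project`` the constant component
    is removed, enforcing the compatibility condition exactly.
    """
    grid = mesh.grid
    idx = grid.world_to_index(dipole.position)[0]
    vox = np.rint(idx).astype(int)
    if np.any(vox < 0) or np.any(vox >= np.asarray(grid.dims)) or \
            mesh.element_of_voxel[tuple(vox)] < 0:
        raise ValueError("dipole position is outside the meshed region")
    host = mesh.element_of_voxel[tuple(vox)]
    sigma0 = dipole.sigma0 if dipole.sigma0 is not None else cond.tensors[host]

    # homogeneity check around the dipole
    d_vox = np.linalg.norm((mesh.voxel_ijk - vox) * np.asarray(grid.spacing), axis=1)
    near = d_vox <= homogeneity_radius_voxels * max(grid.spacing)
    dev = np.abs(cond.tensors[near] - sigma0).max()
    if dev > homogeneity_rtol * max(np.abs(sigma0).max(), 1e-300):
        raise ValueError(
            "conductivity is inhomogeneous within the dipole neighborhood "
            f"(max deviation {dev:.3g} S/m); reposition the dipole or shrink "
            "the homogeneity radius")

    n = len(mesh.nodes)
    b = np.zeros(n)

    # volume term over elements with sigma != sigma0
    diff = cond.tensors - sigma0
    active = np.abs(diff).max(axis=(1, 2)) > 1e-14 * max(np.abs(sigma0).max(), 1e-300)
    if active.any():
        G = _element_gradients(grid)  # (8q, 8a, 3)
        wdet = grid.voxel_volume / 8.0
        centers = grid.index_to_world(mesh.voxel_ijk[active])
        # Gauss point world offsets (same for all elements)
        off = (_GAUSS * 0.5) @ grid.affine.T  # (8q, 3)
        ae = np.flatnonzero(active)
        chunk = 20000
        for s in range(0, len(ae), chunk):
            el = ae[s:s + chunk]
            xg = centers[s:s + chunk][:, None, :] + off[None, :, :]  # (c, 8q, 3)
            gphi = analytic_dipole_infinite_gradient(
                sigma0, dipole.position, dipole.moment, xg.reshape(-1, 3)
            ).reshape(len(el), 8, 3)
            flux = np.einsum("ekl,eql->eqk", diff[el], gphi)  # (c, 8q, 3)
            contrib = -wdet * np.einsum("qak,eqk->ea", G, flux)
            np.add.at(b, mesh.hexes[el], contrib)

    # boundary term over exterior faces
    mask = mesh.element_of_voxel >= 0
    gauss2 = np.array([[sx * _G, sy * _G] for sx in (-1, 1) for sy in (-1, 1)])
    bil = np.stack([(1 + gauss2[:, 0] * sx) * (1 + gauss2[:, 1] * sy) / 4.0
                    for sx, sy in [(-1, -1), (1, -1), (1, 1), (-1, 1)]], axis=1)
    for fn, nrm, area in _boundary_faces(mesh, mask):
        corners = mesh.nodes[fn]  # (f, 4, 3)
        w = area / 4.0
        for q in range(4):
            xg = np.einsum("a,fad->fd", bil[q], corners)
            gphi = analytic_dipole_infinite_gradient(
                sigma0, dipole.position, dipole.moment, xg)
            flux = gphi @ (sigma0 @ nrm)
            np.add.at(b, fn, -w * bil[q][None, :] * flux[:, None])

    if project:
        b -= b.mean()
    return b, sigma0


# ---------------------------------------------------------------------------
# Solve
# ---------------------------------------------------------------------------

def solve_potential(K, b, gauge_nodes=None, tol: float = 1e-8,
                    max_iter: int = 20000, preconditioner: str = "jacobi"):
    """Preconditioned CG on the gauge-fixed pure-Neumann system.

    Constants are projected out of the right-hand side and the final iterate;
    the returned potential has zero mean over ``gauge_nodes`` (all nodes if
    None).  Raises on non-convergence with the residual history tail.
    """
    n = K.shape[0]
    b = np.asarray(b, dtype=float) - np.mean(b)
    if preconditioner == "jacobi":
        d = K.diagonal().copy()
        d[d <= 0] = 1.0
        M = sparse.diags(1.0 / d)
    elif preconditioner is None or preconditioner == "none":
        M = None
    else:
        raise ValueError(f"unknown preconditioner {preconditioner!r}")
    hist = []

    def cb(xk):
        hist.append(1.0)

    x, info = sparse_cg(K, b, rtol=tol, maxiter=max_iter, M=M, callback=cb)
    res = float(np.linalg.norm(K @ x - b) / np.linalg.norm(b))
    if info > 0:
        raise RuntimeError(
            f"CG did not converge in {max_iter} iterations (relative residual "
            f"{res:.3e}); last iterations recorded: {len(hist)}")
    x -= x.mean()
    if gauge_nodes is not None:
        x -= x[gauge_nodes].mean()
    return x, len(hist), res


def solve_forward(mesh: HexMesh, cond: ElementTensorField, dipole: DipoleSource,
                  tol: float = 1e-8, max_iter: int = 20000,
                  homogeneity_radius_voxels: float = 3.0) -> ForwardSolution:
    """Assemble and solve the full-subtraction forward problem."""
    K = assemble_system(mesh, cond)
    b, sigma0 = full_subtraction_rhs(
        mesh, cond, dipole, homogeneity_radius_voxels=homogeneity_radius_voxels)
    surf = mesh.surface_node_mask()
    corr, iters, res = solve_potential(K, b, gauge_nodes=surf, tol=tol,
                                       max_iter=max_iter)
    phi_inf = analytic_dipole_infinite(sigma0, dipole.position, dipole.moment,
                                       mesh.nodes)
    total = corr + phi_inf
    total -= total[surf].mean()
    return ForwardSolution(total, corr, phi_inf, iters, res, mesh)


def sample_potentials(solution_or_values, mesh: HexMesh, points,
                      snap_voxels: float = 0.5) -> np.ndarray:
    """Trilinear evaluation of nodal potentials at world points.

    Points outside the mesh are snapped to the nearest masked voxel if within
    ``snap_voxels`` (in voxel units); farther points raise an error.
    """
    vals = solution_or_values.total if isinstance(solution_or_values, ForwardSolution) \
        else np.asarray(solution_or_values, dtype=float)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    grid = mesh.grid
    idx = grid.world_to_index(pts)
    vox = np.rint(idx).astype(int)
    dims = np.asarray(grid.dims)
    out = np.empty(len(pts))
    for i in range(len(pts)):
        v = vox[i].copy()
        if np.any(v < 0) or np.any(v >= dims) or mesh.element_of_voxel[tuple(v)] < 0:
            # search the 3^3 neighborhood for the nearest masked voxel
            best, bd = None, np.inf
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for dk in (-1, 0, 1):
                        w = v + (di, dj, dk)
                        if np.any(w < 0) or np.any(w >= dims):
                            continue
                        if mesh.element_of_voxel[tuple(w)] < 0:
                            continue
                        # distance from the point to the voxel's index-space box
                        d = np.linalg.norm(np.maximum(np.abs(idx[i] - w) - 0.5, 0))
                        if d < bd:
                            best, bd = w, d
            if best is None or bd > snap_voxels:
                raise ValueError(f"point {pts[i].tolist()} lies outside the mesh "
                                 f"(nearest masked voxel {bd:.2f} voxels away)")
            v = best
        e = mesh.element_of_voxel[tuple(v)]
        xi = np.clip(2.0 * (idx[i] - v), -1.0, 1.0)
        N = _shape_values(xi)[0]
        out[i] = N @ vals[mesh.hexes[e]]
    return out


def rdm_mag(computed, reference):
    """Relative difference measure and magnitude ratio.

    RDM = || u/||u|| - v/||v|| ||_2 (shape error, 0 is perfect);
    MAG = ||u|| / ||v|| (1 is perfect).
    """
    u = np.asarray(computed, dtype=float).ravel()
    v = np.asarray(reference, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    nv = np.linalg.norm(v)
    if nv == 0:
        raise ValueError("reference vector is zero")
    nu = np.linalg.norm(u)
    if nu == 0:
        return float(np.sqrt(2.0)), 0.0
    return float(np.linalg.norm(u / nu - v / nv)), float(nu / nv)


# ---------------------------------------------------------------------------
# Output formats
# ---------------------------------------------------------------------------

def write_legacy_vtk(path, mesh: HexMesh, point_data=None, cell_data=None):
    """Legacy ASCII VTK unstructured grid with hexahedral cells."""
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\necogforward hex mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {len(mesh.nodes)} double\n")
        np.savetxt(f, mesh.nodes, fmt="%.9g")
        e = mesh.n_elements
        f.write(f"CELLS {e} {e * 9}\n")
        np.savetxt(f, np.column_stack([np.full(e, 8), mesh.hexes]), fmt="%d")
        f.write(f"CELL_TYPES {e}\n")
        np.savetxt(f, np.full(e, 12), fmt="%d")
        if point_data:
            f.write(f"POINT_DATA {len(mesh.nodes)}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr, dtype=float)
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, arr.reshape(-1, 1), fmt="%.9g")
        if cell_data:
            f.write(f"CELL_DATA {e}\n")
            for name, arr in cell_data.items():
                arr = np.asarray(arr, dtype=float)
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, arr.reshape(-1, 1), fmt="%.9g")


def write_mesh_gz(path, mesh: HexMesh):
    """Gzip-compressed plain-text hex mesh (nodes + element list + attribute)."""
    with gzip.GzipFile(path, "wb", mtime=0) as gz:
        import io
        f = io.TextIOWrapper(gz)
        f.write(f"nodes {len(mesh.nodes)}\n")
        np.savetxt(f, mesh.nodes, fmt="%.9g")
        f.write(f"hexes {mesh.n_elements}\n")
        np.savetxt(f, np.column_stack([mesh.labels, mesh.hexes]), fmt="%d")
        f.flush()


def write_gf_gz(path, field_: ElementTensorField):
    """Gzip-compressed grid function: one symmetric tensor row per element."""
    T = field_.tensors
    rows = np.column_stack([T[:, 0, 0], T[:, 0, 1], T[:, 0, 2],
                            T[:, 1, 1], T[:, 1, 2], T[:, 2, 2]])
    with gzip.GzipFile(path, "wb", mtime=0) as gz:
        import io
        f = io.TextIOWrapper(gz)
        f.write(f"tensors {len(rows)} 6\n")
        np.savetxt(f, rows, fmt="%.9g")
        f.flush()


def write_pvd(path, vtu_files, times=None):
    """ParaView collection index referencing .vtu files."""
    times = times or list(range(len(vtu_files)))
    with open(path, "w") as f:
        f.write('<?xml version="1.0"?>\n<VTKFile type="Collection" version="0.1">\n')
        f.write("<Collection>\n")
        for t, name in zip(times, vtu_files):
            f.write(f'<DataSet timestep="{t}" file="{name}"/>\n')
        f.write("</Collection>\n</VTKFile>\n")
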