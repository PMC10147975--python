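"""Image-space transforms derived from the meshless solution.

Converts nodal displacements to a forward displacement field on the image
grid, inverts it by fixed-point iteration, and warps scalar and diffusion
tensor images (tensors with linear component interpolation followed by
preservation-of-principal-direction reorientation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .images import ScalarImage, TensorImage, VectorImage, resample_trilinear
from .mtled import DeformationState, mls_shape

__all__ = [
    "DisplacementField",
    "field_from_solution",
    "invert_field",
    "warp_scalar",
    "warp_dti",
    "ppd_reorient",
]


@dataclass
class DisplacementField:
    """Per-voxel world displacement (mm) with a direction flag.

    ``forward`` maps reference (preoperative) points to deformed points;
    ``backward`` maps deformed points to reference points.
    """

    field: VectorImage
    direction: str = "forward"

    def __post_init__(self):
        if self.direction not in ("forward", "backward"):
            raise ValueError("direction must be 'forward' or 'backward'")
        if not np.isfinite(self.field.vectors).all():
            raise ValueError("displacement field contains non-finite values")

    @property
    def grid(self):
        return self.field.grid

    @property
    def vectors(self):
        return self.field.vectors


def field_from_solution(state: DeformationState, grid, mask=None,
                        background: float = 0.0,
                        feather_mm: float | None = None) -> DisplacementField:
    """Forward displacement field at voxel centers via the solver's MLS shape
    functions.  Voxels outside the mask (or without MLS support) get the
    background value; unsupported in-mask voxels are counted in a warning.

    ``feather_mm`` smoothly extends the field past the mask (nearest-voxel
    value attenuated by a Gaussian of that length) instead of cutting to the
    background; a sharp cut makes the field non-invertible at the boundary.
    """
    model = state.model
    pts = grid.voxel_centers().reshape(-1, 3)
    sel = np.ones(len(pts), dtype=bool) if mask is None else mask.values.ravel()
    out = np.full((len(pts), 3), float(background))
    unsupported = 0
    d = state.parameters
    for i in np.flatnonzero(sel):
        try:
            ids, phi, _ = mls_shape(pts[i], model.nodes, model.params,
                                    model.radii, tree=model.tree)
            out[i] = phi @ d[ids]
        except ValueError:
            unsupported += 1
    if unsupported:
        warnings.warn(f"field_from_solution: {unsupported} masked voxels had "
                      "no MLS support (set to background)")
    out = out.reshape(tuple(grid.dims) + (3,))
    if feather_mm and mask is not None and not mask.values.all():
        from scipy import ndimage
        dist, nearest = ndimage.distance_transform_edt(
            ~mask.values, sampling=grid.spacing, return_indices=True)
        outside = ~mask.values
        ni, nj, nk = (nearest[k][outside] for k in range(3))
        atten = np.exp(-(dist[outside] / feather_mm) ** 2)
        out[outside] = out[ni, nj, nk] * atten[:, None]
    vec = VectorImage(grid, out)
    return DisplacementField(vec, "forward")


def invert_field(fwd: DisplacementField, tol: float = 0.05,
                 max_iter: int = 50) -> DisplacementField:
    """Backward field by fixed-point iteration v <- -u(x + v(x)).

    ``tol`` is the worst-voxel composition residual |u(x+v(x)) + v(x)| in mm.
    Raises on non-convergence, reporting the worst voxel.
    """
    if fwd.direction != "forward":
        raise ValueError("invert_field expects a forward field")
    grid = fwd.grid
    pts = grid.voxel_centers().reshape(-1, 3)
    u_img = fwd.field
    dims = np.asarray(grid.dims, dtype=float)

    def valid(src):
        """Fixed points whose pull-back stays inside the voxel-center hull;
        outside it the forward field is unknown and no inverse exists."""
        idx = grid.world_to_index(src)
        return np.all((idx > -1e-9) & (idx < dims - 1 + 1e-9), axis=1)

    v = np.zeros_like(pts)
    for _ in range(max_iter):
        u_at = resample_trilinear(u_img, pts + v)
        res = u_at + v
        v = v - res
        ok = valid(pts + v)
        if np.linalg.norm(res[ok], axis=1).max(initial=0.0) <= tol:
            break
    else:
        u_at = resample_trilinear(u_img, pts + v)
        res = u_at + v
        ok = valid(pts + v)
        rn = np.linalg.norm(res, axis=1)
        rn_ok = np.where(ok, rn, 0.0)
        worst = int(np.argmax(rn_ok))
        if rn_ok.max() > tol:
            raise RuntimeError(
                "invert_field did not converge: worst voxel at world "
                f"{pts[worst].tolist()} residual {rn_ok.max():.4g} mm > tol "
                f"{tol} mm")
    if not ok.all():
        warnings.warn(f"invert_field: {int((~ok).sum())} voxels pull back "
                      "outside the field domain (residual not enforced there)")
    vec = VectorImage(grid, v.reshape(tuple(grid.dims) + (3,)))
    return DisplacementField(vec, "backward")


def warp_scalar(img: ScalarImage, backward: DisplacementField,
                background: float = 0.0) -> ScalarImage:
    """out(x) = in(x + v(x)) with trilinear sampling."""
    if backward.direction != "backward":
        raise ValueError("warp_scalar expects a backward field")
    grid = backward.grid
    pts = grid.voxel_centers().reshape(-1, 3)
    src = pts + backward.vectors.reshape(-1, 3)
    vals = resample_trilinear(img, src, background=background)
    return ScalarImage(grid, vals.reshape(grid.dims))


def _field_jacobian(disp: DisplacementField) -> np.ndarray:
    """d(vector)/d(world) per voxel by central differences (one-sided at the
    borders), shape dims + (3, 3)."""
    v = disp.vectors
    grid = disp.grid
    # J[..., c, k] = dv_c / didx_k, central differences in index space
    J = np.empty(v.shape[:-1] + (3, 3))
    for c in range(3):
        grads = np.gradient(v[..., c], axis=(0, 1, 2))
        for k in range(3):
            J[..., c, k] = grads[k]
    Ainv = np.linalg.inv(grid.affine)
    return J @ Ainv  # chain rule: d/dworld = d/didx * didx/dworld


def ppd_reorient(tensors: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Preservation-of-principal-direction reorientation.

    Rotates each tensor's eigenframe: e1 -> F e1 / |F e1|, e2 -> the
    Gram-Schmidt projection of F e2, rebuilding with the original eigenvalues
    (eigenvalues are exactly preserved).  Singular local Jacobians fall back
    to the identity reorientation.
    """
    shp = tensors.shape[:-2]
    D = tensors.reshape(-1, 3, 3)
    Fm = np.broadcast_to(F, D.shape).reshape(-1, 3, 3)
    w, V = np.linalg.eigh(D)
    w = w[:, ::-1]
    V = V[:, :, ::-1]  # descending eigenvalues
    bad = ~np.isfinite(np.linalg.det(Fm)) | (np.abs(np.linalg.det(Fm)) < 1e-12)
    if bad.any():
        warnings.warn(f"ppd_reorient: {int(bad.sum())} voxels with singular "
                      "Jacobian; identity reorientation used")
        Fm = Fm.copy()
        Fm[bad] = np.eye(3)
    f1 = np.einsum("nij,nj->ni", Fm, V[:, :, 0])
    n1 = np.linalg.norm(f1, axis=1, keepdims=True)
    e1 = np.where(n1 > 1e-15, f1 / np.where(n1 > 0, n1, 1), V[:, :, 0])
    f2 = np.einsum("nij,nj->ni", Fm, V[:, :, 1])
    f2 = f2 - np.einsum("ni,ni->n", f2, e1)[:, None] * e1
    n2 = np.linalg.norm(f2, axis=1, keepdims=True)
    e2 = np.where(n2 > 1e-15, f2 / np.where(n2 > 0, n2, 1), V[:, :, 1])
    e3 = np.cross(e1, e2)
    R = np.stack([e1, e2, e3], axis=-1)
    out = np.einsum("nij,nj,nkj->nik", R, w, R)
    return out.reshape(shp + (3, 3))


def warp_dti(dti: TensorImage, backward: DisplacementField) -> TensorImage:
    """Warp a tensor image: linear component resampling at x + v(x), then PPD
    reorientation by the local forward-map Jacobian F = (I + grad v)^-1."""
    if backward.direction != "backward":
        raise ValueError("warp_dti expects a backward field")
    grid = backward.grid
    pts = grid.voxel_centers().reshape(-1, 3)
    src = pts + backward.vectors.reshape(-1, 3)
    comp = np.stack([
        resample_trilinear(ScalarImage(dti.grid, dti.components[..., c]), src)
        for c in range(6)
    ], axis=-1)
    D = TensorImage(grid, comp.reshape(tuple(grid.dims) + (6,))).to_matrices()

    Jv = _field_jacobian(backward).reshape(-1, 3, 3)
    A = np.eye(3) + Jv
    det = np.linalg.det(A)
    ok = np.abs(det) > 1e-12
    F = np.tile(np.eye(3), (len(A), 1, 1))
    F[ok] = np.linalg.inv(A[ok])
    if (~ok).any():
        warnings.warn(f"warp_dti: {int((~ok).sum())} voxels with singular "
                      "backward Jacobian; identity reorientation used")
    out = ppd_reorient(D.reshape(-1, 3, 3), F)
    return TensorImage(grid, TensorImage.matrices_to_components(
        out.reshape(tuple(grid.dims) + (3, 3))))
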