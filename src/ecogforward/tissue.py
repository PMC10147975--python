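"""DTI invariants, fuzzy C-means tissue classification and conductivity maps.

The head model distinguishes five tissue classes (plus the electrode sheet):
white matter, gray matter, cerebrospinal fluid, skull and scalp.  Brain
classes come from the diffusion tensors: mean diffusivity separates CSF from
parenchyma, fractional anisotropy separates WM from GM, each by two-cluster
fuzzy C-means with fuzziness m = 2.  Skull and scalp are shells obtained by
offsetting the brain surface (default 4.4 mm).  Conductivities are isotropic
per class except white matter, whose tensor shares the diffusion eigenvectors
(volume-normalized or linearly scaled eigenvalues).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .images import LabelImage, MaskImage, ScalarImage, TensorImage, dilate_mask

__all__ = [
    "CLASS_WM", "CLASS_GM", "CLASS_CSF", "CLASS_SKULL", "CLASS_SCALP",
    "CLASS_SHEET", "CLASS_NAMES",
    "FCMConfig",
    "ConductivitySpec",
    "tensor_invariants",
    "fcm",
    "classify_brain",
    "build_head_labelmap",
    "assign_conductivity",
    "write_color_table",
]

CLASS_WM, CLASS_GM, CLASS_CSF, CLASS_SKULL, CLASS_SCALP, CLASS_SHEET = 1, 2, 3, 4, 5, 6
CLASS_NAMES = {CLASS_WM: "white_matter", CLASS_GM: "gray_matter",
               CLASS_CSF: "csf", CLASS_SKULL: "skull", CLASS_SCALP: "scalp",
               CLASS_SHEET: "electrode_sheet"}


# ---------------------------------------------------------------------------
# Tensor invariants
# ---------------------------------------------------------------------------

def tensor_invariants(dti: TensorImage, mask: MaskImage | None = None):
    """Mean diffusivity and fractional anisotropy images.

    MD = tr(D)/3; FA = sqrt(3/2) * ||D - MD I||_F / ||D||_F, with FA = 0
    where the tensor vanishes.  Both formulas are eigenvalue-free identities
    of the symmetric tensor (Frobenius form equals the eigenvalue form).
    """
    c = dti.components
    md = (c[..., 0] + c[..., 3] + c[..., 5]) / 3.0
    # ||D||_F^2 = sum lambda_i^2; off-diagonals count twice
    fro2 = (c[..., 0] ** 2 + c[..., 3] ** 2 + c[..., 5] ** 2
            + 2 * (c[..., 1] ** 2 + c[..., 2] ** 2 + c[..., 4] ** 2))
    dev2 = fro2 - 3.0 * md ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * np.clip(dev2, 0, None) / np.where(fro2 > 0, fro2, 1))
    fa = np.where(fro2 > 0, fa, 0.0)
    if mask is not None:
        md = np.where(mask.values, md, 0.0)
        fa = np.where(mask.values, fa, 0.0)
    return ScalarImage(dti.grid, md), ScalarImage(dti.grid, fa)


# ---------------------------------------------------------------------------
# Fuzzy C-means
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FCMConfig:
    n_clusters: int = 2
    fuzziness: float = 2.0
    tolerance: float = 1e-6
    max_iter: int = 300
    seed: int = 0

    def __post_init__(self):
        if self.fuzziness <= 1:
            raise ValueError("fuzziness m must exceed 1")
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")


def _fcm_memberships(X, centers, m):
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    zero = d2 < 1e-300
    if zero.any():
        u = np.zeros_like(d2)
        rows = zero.any(axis=1)
        u[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
        inv = d2[~rows] ** (-1.0 / (m - 1.0))
        u[~rows] = inv / inv.sum(axis=1, keepdims=True)
        return u
    inv = d2 ** (-1.0 / (m - 1.0))
    return inv / inv.sum(axis=1, keepdims=True)


def fcm(features, config: FCMConfig):
    """Fuzzy C-means clustering.

    Alternates the membership update u_ik = 1 / sum_j (d_ik/d_jk)^(2/(m-1))
    and the center update c_i = sum_k u_ik^m x_k / sum_k u_ik^m until the
    center shift drops below the tolerance.  Initial centers sit at feature
    quantiles (deterministic); on a degenerate center collapse one seeded
    random restart is attempted before raising.

    Returns ``(memberships (n, c), centers (c, d))``.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    c, m = config.n_clusters, config.fuzziness
    if len(np.unique(X, axis=0)) < c:
        raise ValueError("fewer distinct feature points than clusters")

    def run(centers):
        for _ in range(config.max_iter):
            u = _fcm_memberships(X, centers, m)
            um = u ** m
            new = (um.T @ X) / um.sum(axis=0)[:, None]
            shift = np.linalg.norm(new - centers, axis=1).max()
            centers = new
            if shift < config.tolerance:
                break
        # collapse check: distinct centers required
        from scipy.spatial.distance import pdist
        scale = np.linalg.norm(X.max(axis=0) - X.min(axis=0)) + 1e-300
        if c > 1 and pdist(centers).min() < 1e-9 * scale:
            return None, None
        return _fcm_memberships(X, centers, m), centers

    # deterministic quantile initialization along the dominant axis
    axis = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(axis, full_matrices=False)
    proj = axis @ Vt[0]
    qs = np.quantile(proj, (np.arange(c) + 0.5) / c)
    centers0 = X.mean(axis=0) + qs[:, None] * Vt[0]
    u, centers = run(centers0)
    if u is None:
        rng = np.random.default_rng(config.seed)
        centers0 = X[rng.choice(len(X), size=c, replace=False)]
        u, centers = run(centers0)
        if u is None:
            raise RuntimeError("fuzzy C-means centers collapsed after re-seed")
    return u, centers


def fcm_objective(features, memberships, centers, m: float = 2.0) -> float:
    """J = sum_ik u_ik^m ||x_k - c_i||^2 (monotone non-increasing in FCM)."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return float((memberships ** m * d2).sum())


# ---------------------------------------------------------------------------
# Classification and label-map fusion
# ---------------------------------------------------------------------------

def classify_brain(dti: TensorImage, brain_mask: MaskImage,
                   config: FCMConfig | None = None) -> LabelImage:
    """Two-stage diffusion-based tissue labels inside the brain mask.

    Stage 1: two-cluster FCM on mean diffusivity; the high-MD cluster is CSF.
    Stage 2: two-cluster FCM on fractional anisotropy within the remaining
    parenchyma; the high-FA cluster is WM, the rest GM.  Hard labels by
    maximum membership.
    """
    cfg = config or FCMConfig()
    if not brain_mask.values.any():
        raise ValueError("empty brain mask")
    md_img, fa_img = tensor_invariants(dti)
    md = md_img.values[brain_mask.values]
    if np.ptp(md) < 1e-300:
        raise ValueError("degenerate (constant) mean diffusivity in mask")
    u, centers = fcm(md, cfg)
    csf_cluster = int(np.argmax(centers[:, 0]))
    hard = u.argmax(axis=1)
    is_csf = hard == csf_cluster

    labels = np.zeros(tuple(dti.grid.dims), dtype=np.int64)
    flat_idx = np.flatnonzero(brain_mask.values.ravel())
    lv = labels.ravel()
    lv[flat_idx[is_csf]] = CLASS_CSF

    par_idx = flat_idx[~is_csf]
    fa = fa_img.values.ravel()[par_idx]
    if np.ptp(fa) < 1e-300:
        raise ValueError("degenerate (constant) fractional anisotropy in parenchyma")
    u2, centers2 = fcm(fa, cfg)
    wm_cluster = int(np.argmax(centers2[:, 0]))
    hard2 = u2.argmax(axis=1)
    lv[par_idx[hard2 == wm_cluster]] = CLASS_WM
    lv[par_idx[hard2 != wm_cluster]] = CLASS_GM
    return LabelImage(dti.grid, labels.reshape(dti.grid.dims))


def build_head_labelmap(brain_labels: LabelImage, brain_mask: MaskImage,
                        sheet_mask: MaskImage | None = None,
                        shell_mm: float = 4.4) -> LabelImage:
    """Fuse brain tissue labels with skull/scalp shells and electrode sheet.

    skull = dilate(brain, shell) - brain; scalp = dilate(brain, 2*shell) -
    dilate(brain, shell); the sheet mask (if given) overrides whatever class
    lies underneath.  Classes are disjoint by construction.
    """
    if shell_mm <= 0:
        raise ValueError("shell_mm must be positive")
    grid = brain_labels.grid
    b = brain_mask.values
    d1 = dilate_mask(brain_mask, shell_mm).values
    d2 = dilate_mask(brain_mask, 2 * shell_mm).values
    # clipped shells are permitted but reported
    if d2[0].any() or d2[-1].any() or d2[:, 0].any() or d2[:, -1].any() \
            or d2[:, :, 0].any() or d2[:, :, -1].any():
        warnings.warn("build_head_labelmap: shells reach the grid boundary "
                      "and are clipped")
    out = np.zeros(tuple(grid.dims), dtype=np.int64)
    out[b] = brain_labels.values[b]
    out[d1 & ~b] = CLASS_SKULL
    out[d2 & ~d1] = CLASS_SCALP
    if sheet_mask is not None:
        out[sheet_mask.values] = CLASS_SHEET
    return LabelImage(grid, out)


# ---------------------------------------------------------------------------
# Conductivity assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConductivitySpec:
    """Per-class isotropic conductivities (S/m) plus the WM anisotropy mode.

    Defaults follow standard head-model values: scalp 0.33, skull 0.012,
    CSF 1.79, gray matter 0.33, electrode sheet substrate 1e-6 S/m.  White
    matter is anisotropic, sharing eigenvectors with the diffusion tensor:

    * ``volume_normalized``: sigma_i = sigma_ref * d_i / (d1 d2 d3)^(1/3),
      preserving det(sigma) = sigma_ref^3 per voxel;
    * ``linear``: sigma_i = k_linear * d_i.
    """

    class_sigma: dict = field(default_factory=lambda: {
        CLASS_GM: 0.33, CLASS_CSF: 1.79, CLASS_SKULL: 0.012,
        CLASS_SCALP: 0.33, CLASS_SHEET: 1e-6})
    wm_mode: str = "volume_normalized"
    sigma_ref: float = 0.14      # S/m, WM reference conductivity
    k_linear: float = 0.844      # (S/m) per (mm^2/s) scaling for linear mode
    eigenvalue_floor: float = 1e-6

    def __post_init__(self):
        if any(v <= 0 for v in self.class_sigma.values()):
            raise ValueError("conductivities must be positive")
        if self.wm_mode not in ("volume_normalized", "linear"):
            raise ValueError("wm_mode must be volume_normalized|linear")
        if self.sigma_ref <= 0 or self.k_linear <= 0:
            raise ValueError("sigma_ref and k_linear must be positive")


def assign_conductivity(labels: LabelImage, dti: TensorImage | None,
                        spec: ConductivitySpec | None = None) -> TensorImage:
    """Per-voxel conductivity tensors (S/m) from a head label map.

    Non-WM classes get sigma_class * I.  WM voxels share eigenvectors with
    the diffusion tensor; eigenvalues are floored at ``eigenvalue_floor`` so
    the result is symmetric positive definite.  Non-finite or absent diffusion
    tensors fall back to sigma_ref * I with a warning.
    """
    sp = spec or ConductivitySpec()
    grid = labels.grid
    lv = labels.values
    present = set(int(l) for l in labels.labels)
    covered = set(sp.class_sigma) | {CLASS_WM}
    if not present <= covered:
        raise ValueError(f"no conductivity for classes {sorted(present - covered)}")
    comp = np.zeros(tuple(grid.dims) + (6,))
    for cls, sig in sp.class_sigma.items():
        sel = lv == cls
        comp[sel, 0] = comp[sel, 3] = comp[sel, 5] = sig

    wm = lv == CLASS_WM
    if wm.any():
        if dti is None:
            warnings.warn("assign_conductivity: WM present but no DTI given; "
                          "isotropic sigma_ref used")
            comp[wm, 0] = comp[wm, 3] = comp[wm, 5] = sp.sigma_ref
        else:
            D = dti.to_matrices()[wm]
            bad = ~np.isfinite(D).all(axis=(1, 2))
            if bad.any():
                warnings.warn(f"assign_conductivity: {int(bad.sum())} WM voxels "
                              "with non-finite tensors; isotropic fallback")
                D[bad] = sp.sigma_ref * np.eye(3)
            w, V = np.linalg.eigh(D)
            w = np.clip(w, sp.eigenvalue_floor * np.max(w, axis=1, keepdims=True)
                        + 1e-300, None)
            if sp.wm_mode == "volume_normalized":
                gm = np.prod(w, axis=1) ** (1.0 / 3.0)
                sig_eigs = sp.sigma_ref * w / gm[:, None]
            else:
                sig_eigs = sp.k_linear * w
            sig_eigs = np.clip(sig_eigs, sp.eigenvalue_floor, None)
            S = np.einsum("nij,nj,nkj->nik", V, sig_eigs, V)
            S[bad] = sp.sigma_ref * np.eye(3)
            comp[wm] = TensorImage.matrices_to_components(S)
    return TensorImage(grid, comp)


def write_color_table(path, class_names=None, colors=None):
    """Slicer-style color table (label, name, R G B A) for the class codes."""
    names = class_names or CLASS_NAMES
    default_colors = {CLASS_WM: (255, 255, 255, 255), CLASS_GM: (128, 128, 128, 255),
                      CLASS_CSF: (0, 128, 255, 255), CLASS_SKULL: (241, 214, 145, 255),
                      CLASS_SCALP: (177, 122, 101, 255), CLASS_SHEET: (255, 0, 0, 255)}
    colors = colors or default_colors
    with open(path, "w") as f:
        f.write("# label name R G B A\n")
        for code in sorted(names):
            r, g, b, a = colors.get(code, (200, 200, 200, 255))
            f.write(f"{code} {names[code]} {r} {g} {b} {a}\n")
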