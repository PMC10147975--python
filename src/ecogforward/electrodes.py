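"""Electrode extraction from CT-like images and prescribed-displacement loads.

The post-implantation electrode positions come from thresholding a registered
CT image, splitting the mask into connected components and taking component
centroids.  Pairing each centroid with its projection onto the preoperative
brain surface yields the displacement boundary conditions for the
biomechanical model; moving least squares interpolation spreads those
displacements onto the selected brain-surface nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .images import LabelImage, MaskImage, ScalarImage, connected_components, otsu_threshold
from .mtled import LoadTable, MLSParams, mls_shape
from .surface import PointSet

__all__ = [
    "ElectrodeSet",
    "LoadTable",
    "segment_electrodes",
    "centroids",
    "electrode_displacements",
    "mls_interpolate",
    "build_load_table",
    "save_centroids_txt",
    "load_centroids_txt",
]


@dataclass
class ElectrodeSet:
    """Paired electrode positions: post-implantation (orig, from CT) and
    projected onto the preoperative brain surface (proj).  Pairing by label."""

    orig: PointSet
    proj: PointSet

    def __post_init__(self):
        if sorted(self.orig.labels) != sorted(self.proj.labels):
            raise ValueError("orig/proj electrode labels do not match")


def segment_electrodes(ct: ScalarImage, exclusion_mask: MaskImage | None = None,
                       min_voxels: int = 2, connectivity: int = 26,
                       n_bins: int = 128) -> LabelImage:
    """Electrode components from a CT-like image.

    Otsu threshold -> binary mask -> connected components; components smaller
    than ``min_voxels`` are discarded and the remainder relabeled 1..K.  An
    optional exclusion mask (e.g. a skull shell) removes voxels from the
    electrode mask before splitting.
    """
    _, mask = otsu_threshold(ct, n_bins=n_bins)
    m = mask.values
    if exclusion_mask is not None:
        m = m & ~exclusion_mask.values
    comp = connected_components(MaskImage(ct.grid, m), connectivity)
    lv = comp.values
    out = np.zeros_like(lv)
    nxt = 0
    for lab in comp.labels:
        sel = lv == lab
        if sel.sum() >= min_voxels:
            nxt += 1
            out[sel] = nxt
    if nxt == 0:
        raise ValueError("no electrode components found after size filtering")
    return LabelImage(ct.grid, out)


def centroids(labels: LabelImage) -> PointSet:
    """World-coordinate center of mass of each labeled component."""
    labs = labels.labels
    if len(labs) == 0:
        raise ValueError("label image has no components")
    pts = np.empty((len(labs), 3))
    centers = labels.grid.voxel_centers().reshape(-1, 3)
    flat = labels.values.ravel()
    for i, lab in enumerate(labs):
        pts[i] = centers[flat == lab].mean(axis=0)
    return PointSet(pts, [f"E{int(l)}" for l in labs])


def electrode_displacements(es: ElectrodeSet):
    """Displacement vector orig - proj at each projected electrode.

    Returns ``(points, vectors)``: the projected positions and the matching
    displacement vectors, ordered by the proj labels.
    """
    by_label = {lab: p for lab, p in zip(es.orig.labels, es.orig.points)}
    vec = np.array([by_label[lab] for lab in es.proj.labels]) - es.proj.points
    return PointSet(es.proj.points.copy(), list(es.proj.labels)), vec


def _mls_weights_point(x2, pts2, radius, interpolating, dim):
    """MLS shape values at one point for a (possibly 2-D) linear basis."""
    d = pts2 - x2
    r = np.linalg.norm(d, axis=1)
    sel = np.flatnonzero(r < radius)
    if len(sel) < dim + 1:
        return None, None
    q = r[sel] / radius
    w = 1.0 - 6.0 * q ** 2 + 8.0 * q ** 3 - 3.0 * q ** 4
    if interpolating:
        near = q < 1e-9
        if near.any():
            phi = np.zeros(len(sel))
            phi[np.argmin(q)] = 1.0
            return sel, phi
        w = w / q ** 2
    P = np.concatenate([np.ones((len(sel), 1)), d[sel]], axis=1)
    A = (w[:, None] * P).T @ P
    e0 = np.zeros(dim + 1)
    e0[0] = 1.0
    try:
        c = np.linalg.solve(A, e0)
    except np.linalg.LinAlgError:
        return None, None
    return sel, w * (P @ c)


def mls_interpolate(src_points, src_values, dst_points,
                    params: MLSParams | None = None,
                    support_scale: float | None = None) -> np.ndarray:
    """Moving-least-squares interpolation of scattered vector data.

    Electrode centroids lie (nearly) on a 2-D sheet, so when the source cloud
    is planar the fit runs in the best-fit plane with a 2-D linear basis;
    otherwise the full 3-D linear basis is used.  The support radius starts at
    ``support_scale`` times the mean nearest-neighbor spacing and grows until
    each destination point has enough support (raising after a few doublings).
    """
    src = np.asarray(src_points, dtype=float).reshape(-1, 3)
    vals = np.asarray(src_values, dtype=float)
    dst = np.atleast_2d(np.asarray(dst_points, dtype=float))
    p = params or MLSParams(interpolating=True)
    if len(src) < 3:
        raise ValueError("need at least 3 source points")

    ctr = src.mean(axis=0)
    _, s, Vt = np.linalg.svd(src - ctr, full_matrices=False)
    planar = s[2] < 1e-3 * max(s[0], 1e-300) if len(s) > 2 else True
    dim = 2 if planar else 3
    B = Vt[:dim]
    src_c = (src - ctr) @ B.T
    dst_c = (dst - ctr) @ B.T

    tree = cKDTree(src_c)
    d_nn, _ = tree.query(src_c, k=min(2, len(src_c)))
    h = float(np.mean(d_nn[:, -1])) if len(src_c) > 1 else 1.0
    scale = support_scale if support_scale is not None else p.support_scale
    r0 = max(scale, 2.05) * h
    out = np.empty((len(dst),) + vals.shape[1:])
    for i, x in enumerate(dst_c):
        radius = r0
        for _ in range(6):
            sel, phi = _mls_weights_point(x, src_c, radius, p.interpolating, dim)
            if sel is not None:
                out[i] = phi @ vals[sel]
                break
            radius *= 1.5
        else:
            raise ValueError(f"insufficient MLS support at destination point "
                             f"{dst[i].tolist()}")
    return out


def build_load_table(node_ids, node_coords, es: ElectrodeSet,
                     params: MLSParams | None = None) -> LoadTable:
    """Prescribed displacements for the biomechanical model.

    One row per selected brain-surface node, with the electrode displacement
    field MLS-interpolated from the projected centroids.
    """
    node_ids = np.asarray(node_ids, dtype=np.int64)
    if len(node_ids) == 0:
        raise ValueError("empty node selection")
    pts, vec = electrode_displacements(es)
    dst = np.asarray(node_coords, dtype=float).reshape(-1, 3)
    if len(dst) != len(node_ids):
        raise ValueError("node_ids / node_coords length mismatch")
    disp = mls_interpolate(pts.points, vec, dst, params)
    return LoadTable(node_ids, disp)


def save_centroids_txt(points: PointSet, path):
    np.savetxt(path, points.points, fmt="%.9g")


def load_centroids_txt(path, labels=None) -> PointSet:
    pts = np.loadtxt(path, ndmin=2)
    return PointSet(pts[:, :3], labels or [])
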