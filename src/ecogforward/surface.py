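"""Triangulated surfaces: extraction, projection, electrode sheets, voxelization.

World coordinates are LPS everywhere; STL and .fcsv files written by 3D Slicer
in RAS are converted on read by negating x and y.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .images import ImageGrid, MaskImage

__all__ = [
    "TriSurface",
    "PointSet",
    "marching_cubes",
    "project_points_to_surface",
    "closest_point_on_surface",
    "triangulate_centroids",
    "extrude_sheet",
    "voxelize_surface",
    "select_nodes_under_sheet",
    "read_stl",
    "write_stl",
    "read_fcsv",
    "write_fcsv",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class TriSurface:
    """Triangle mesh in world (LPS) mm coordinates."""

    vertices: np.ndarray  # (n, 3) float
    triangles: np.ndarray  # (m, 3) int

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if self.triangles.size and self.triangles.max() >= len(self.vertices):
            raise ValueError("triangle index out of range")

    # -- geometry ----------------------------------------------------------
    def corners(self) -> np.ndarray:
        """Triangle corner coordinates, shape (m, 3, 3)."""
        return self.vertices[self.triangles]

    def face_normals(self, normalized=True) -> np.ndarray:
        c = self.corners()
        n = np.cross(c[:, 1] - c[:, 0], c[:, 2] - c[:, 0])
        if normalized:
            ln = np.linalg.norm(n, axis=1, keepdims=True)
            n = n / np.where(ln > 0, ln, 1.0)
        return n

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted vertex normals (unit)."""
        fn = self.face_normals(normalized=False)  # area-weighted
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.triangles[:, k], fn)
        ln = np.linalg.norm(vn, axis=1, keepdims=True)
        return vn / np.where(ln > 0, ln, 1.0)

    def area(self) -> float:
        return float(np.linalg.norm(self.face_normals(normalized=False), axis=1).sum() / 2)

    def volume(self) -> float:
        """Signed enclosed volume by the divergence theorem (outward > 0)."""
        c = self.corners()
        return float(np.einsum("ij,ij->i", c[:, 0],
                               np.cross(c[:, 1], c[:, 2])).sum() / 6.0)

    def edges(self, directed=False) -> np.ndarray:
        e = np.concatenate([self.triangles[:, [0, 1]],
                            self.triangles[:, [1, 2]],
                            self.triangles[:, [2, 0]]])
        return e if directed else np.sort(e, axis=1)

    def is_watertight(self) -> bool:
        """Every undirected edge shared by exactly two triangles, consistently
        oriented (each directed edge appears once)."""
        e = self.edges(directed=True)
        key = e[:, 0] * (len(self.vertices) + 1) + e[:, 1]
        if len(np.unique(key)) != len(key):
            return False
        und = np.sort(e, axis=1)
        key = und[:, 0] * (len(self.vertices) + 1) + und[:, 1]
        _, counts = np.unique(key, return_counts=True)
        return bool((counts == 2).all())

    def euler_characteristic(self) -> int:
        und = self.edges()
        ne = len(np.unique(und[:, 0] * (len(self.vertices) + 1) + und[:, 1]))
        nv = len(np.unique(self.triangles))
        return nv - ne + len(self.triangles)

    def remove_degenerate(self, min_area: float = 1e-12) -> "TriSurface":
        areas = np.linalg.norm(self.face_normals(normalized=False), axis=1) / 2
        return TriSurface(self.vertices, self.triangles[areas > min_area])

    def flipped(self) -> "TriSurface":
        return TriSurface(self.vertices, self.triangles[:, [0, 2, 1]])


@dataclass
class PointSet:
    """Labeled fiducial points in world (LPS) mm coordinates."""

    points: np.ndarray  # (n, 3)
    labels: list = field(default_factory=list)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.isfinite(self.points).all():
            raise ValueError("points must be finite")
        if not self.labels:
            self.labels = [f"P{i + 1}" for i in range(len(self.points))]
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != len(self.points):
            raise ValueError("labels/points length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")

    def __len__(self):
        return len(self.points)


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def marching_cubes(field_or_mask, isovalue: float | None = None,
                   smooth_sigma_voxels: float = 0.8) -> TriSurface:
    """Isosurface of a scalar image (or 0.5-level of a mask) in world mm.

    Binary masks are Gaussian-smoothed (``smooth_sigma_voxels``, 0 disables)
    before extraction, otherwise the staircase surface overestimates areas.
    The surface is oriented outward (positive enclosed volume).
    """
    from scipy import ndimage
    from skimage import measure

    img = field_or_mask
    if isinstance(img, MaskImage):
        vol = img.values.astype(float)
        if smooth_sigma_voxels > 0:
            vol = ndimage.gaussian_filter(vol, smooth_sigma_voxels)
        iso = 0.5 if isovalue is None else isovalue
    else:
        vol = img.values
        if isovalue is None:
            raise ValueError("isovalue required for scalar images")
        iso = isovalue
    if vol.min() >= iso or vol.max() <= iso:
        raise ValueError("isosurface is empty: isovalue outside data range")
    verts, faces, _, _ = measure.marching_cubes(vol, level=iso)
    world = img.grid.index_to_world(verts)
    surf = TriSurface(world, faces).remove_degenerate()
    if surf.volume() < 0:
        surf = surf.flipped()
    return surf


# ---------------------------------------------------------------------------
# Closest-point projection
# ---------------------------------------------------------------------------

def _closest_on_triangles(p, tri):
    """Closest point to ``p`` (3,) on each triangle in ``tri`` (m,3,3).

    Vectorized version of the Ericson point/triangle algorithm; returns
    (points (m,3), squared distances (m,)).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(a)
    done = np.zeros(len(a), dtype=bool)

    def setwhere(cond, val):
        nonlocal done
        m = cond & ~done
        out[m] = val[m] if val.ndim == 2 else val
        done |= m

    setwhere((d1 <= 0) & (d2 <= 0), a)
    setwhere((d3 >= 0) & (d4 <= d3), b)
    setwhere((d6 >= 0) & (d5 <= d6), c)
    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = d1 / (d1 - d3)
    setwhere((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + np.nan_to_num(v_ab)[:, None] * ab)
    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = d2 / (d2 - d6)
    setwhere((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + np.nan_to_num(w_ac)[:, None] * ac)
    va = d3 * d6 - d5 * d4
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    setwhere((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
             b + np.nan_to_num(w_bc)[:, None] * (c - b))
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = vb / denom
        w = vc / denom
    inner = a + np.nan_to_num(v)[:, None] * ab + np.nan_to_num(w)[:, None] * ac
    out[~done] = inner[~done]
    d2out = np.einsum("ij,ij->i", out - p, out - p)
    return out, d2out


def closest_point_on_surface(points, surface: TriSurface, k: int = 48):
    """Closest surface point, distance and triangle index for each query point.

    A centroid KD-tree prefilters candidate triangles; the candidate set is
    guaranteed correct by widening to all triangles whose centroid lies within
    the best candidate distance plus the largest triangle circumradius.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    tri = surface.corners()
    if len(tri) == 0:
        raise ValueError("empty surface")
    cent = tri.mean(axis=1)
    rad = np.linalg.norm(tri - cent[:, None, :], axis=2).max(axis=1)
    rmax = rad.max()
    tree = cKDTree(cent)
    k = min(k, len(tri))
    out_p = np.empty_like(pts)
    out_d = np.empty(len(pts))
    out_t = np.empty(len(pts), dtype=np.int64)
    dists, nbrs = tree.query(pts, k=k)
    if k == 1:
        dists, nbrs = dists[:, None], nbrs[:, None]
    for i, p in enumerate(pts):
        cand = nbrs[i]
        cp, d2 = _closest_on_triangles(p, tri[cand])
        jbest = int(np.argmin(d2))
        dbest = np.sqrt(d2[jbest])
        # widen: any triangle whose centroid is within dbest + rmax could win
        extra = tree.query_ball_point(p, dbest + rmax + 1e-9)
        extra = np.setdiff1d(np.asarray(extra, dtype=np.int64), cand)
        best_pt, best_tri = cp[jbest], cand[jbest]
        if len(extra):
            cp2, d22 = _closest_on_triangles(p, tri[extra])
            j2 = int(np.argmin(d22))
            if d22[j2] < dbest ** 2:
                dbest = np.sqrt(d22[j2])
                best_pt, best_tri = cp2[j2], extra[j2]
        out_p[i], out_d[i], out_t[i] = best_pt, dbest, best_tri
    return out_p, out_d, out_t


def project_points_to_surface(points: PointSet, surface: TriSurface) -> PointSet:
    """Map each point to its closest point on the surface (labels preserved)."""
    proj, _, _ = closest_point_on_surface(points.points, surface)
    return PointSet(proj, list(points.labels))


# ---------------------------------------------------------------------------
# Electrode sheet construction
# ---------------------------------------------------------------------------

def triangulate_centroids(points: PointSet) -> TriSurface:
    """Delaunay-triangulate points in their best-fit plane, lifted back to 3D."""
    P = points.points
    if len(P) < 3:
        raise ValueError("need at least 3 points")
    c = P.mean(axis=0)
    _, s, Vt = np.linalg.svd(P - c, full_matrices=False)
    if len(s) < 2 or s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("points are collinear; cannot triangulate")
    uv = (P - c) @ Vt[:2].T
    tri = Delaunay(uv)
    surf = TriSurface(P, tri.simplices).remove_degenerate()
    # orient consistently with the fit-plane normal
    n_plane = np.cross(Vt[0], Vt[1])
    fn = surf.face_normals()
    if (fn @ n_plane < 0).sum() > len(fn) / 2:
        surf = surf.flipped()
    return surf


def _boundary_loops(sheet: TriSurface):
    """Directed boundary edges (appearing once) of an open sheet."""
    e = sheet.edges(directed=True)
    und = np.sort(e, axis=1)
    key = und[:, 0] * (len(sheet.vertices) + 1) + und[:, 1]
    uniq, inv, counts = np.unique(key, return_inverse=True, return_counts=True)
    return e[counts[inv] == 1]


def extrude_sheet(sheet: TriSurface, thickness: float) -> TriSurface:
    """Extrude an open sheet by +-thickness/2 along vertex normals.

    Produces a closed (watertight) slab with side walls along the boundary.
    """
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    n = sheet.vertex_normals()
    nv = len(sheet.vertices)
    top = sheet.vertices + 0.5 * thickness * n
    bot = sheet.vertices - 0.5 * thickness * n
    verts = np.vstack([top, bot])
    tris = [sheet.triangles,                        # top, original orientation
            sheet.triangles[:, [0, 2, 1]] + nv]     # bottom, reversed
    for a, b in _boundary_loops(sheet):
        # boundary edge a->b is CCW seen from +n; outward wall = (b-a) x n
        tris.append([[a + nv, b + nv, b], [a + nv, b, a]])
    out = TriSurface(verts, np.vstack([np.asarray(t).reshape(-1, 3) for t in tris]))
    out = out.remove_degenerate()
    if not out.is_watertight():
        raise ValueError("extrusion self-intersected or sheet was not manifold")
    if out.volume() < 0:
        out = out.flipped()
    return out


# ---------------------------------------------------------------------------
# Voxelization and node selection
# ---------------------------------------------------------------------------

def voxelize_surface(closed: TriSurface, grid: ImageGrid, axis: int = 0) -> MaskImage:
    """Mask of voxels whose center lies inside a watertight surface.

    Ray-parity test in index space along ``axis``; voxel centers sit at
    integer index coordinates.  A tiny irrational offset of the transverse
    test coordinates avoids exact edge/vertex hits.
    """
    if not closed.is_watertight():
        raise ValueError("voxelize_surface requires a watertight surface")
    V = grid.world_to_index(closed.vertices)
    ax = axis
    t1, t2 = [a for a in range(3) if a != ax]
    eps = (1e-7, 1e-7 * np.sqrt(2.0))

    tri = V[closed.triangles]  # (m,3,3) in index coords
    mask = np.zeros(grid.dims, dtype=bool)
    d1, d2v = grid.dims[t1], grid.dims[t2]
    # crossing x-positions accumulated per transverse row
    crossings = [[] for _ in range(d1 * d2v)]

    A, B, C = tri[:, 0], tri[:, 1], tri[:, 2]
    lo1 = np.floor(np.minimum.reduce([A[:, t1], B[:, t1], C[:, t1]])).astype(int)
    hi1 = np.ceil(np.maximum.reduce([A[:, t1], B[:, t1], C[:, t1]])).astype(int)
    lo2 = np.floor(np.minimum.reduce([A[:, t2], B[:, t2], C[:, t2]])).astype(int)
    hi2 = np.ceil(np.maximum.reduce([A[:, t2], B[:, t2], C[:, t2]])).astype(int)
    lo1 = np.clip(lo1, 0, d1 - 1); hi1 = np.clip(hi1, 0, d1 - 1)
    lo2 = np.clip(lo2, 0, d2v - 1); hi2 = np.clip(hi2, 0, d2v - 1)

    for m in range(len(tri)):
        a, b, c = A[m], B[m], C[m]
        i1 = np.arange(lo1[m], hi1[m] + 1)
        i2 = np.arange(lo2[m], hi2[m] + 1)
        if len(i1) == 0 or len(i2) == 0:
            continue
        g1, g2 = np.meshgrid(i1, i2, indexing="ij")
        p1 = g1.ravel() + eps[0]
        p2 = g2.ravel() + eps[1]
        # 2D barycentric in (t1,t2)
        v0 = (b[t1] - a[t1], b[t2] - a[t2])
        v1 = (c[t1] - a[t1], c[t2] - a[t2])
        den = v0[0] * v1[1] - v1[0] * v0[1]
        if den == 0:
            continue  # triangle projects to a line along the ray
        w0 = p1 - a[t1]
        w1 = p2 - a[t2]
        u = (w0 * v1[1] - v1[0] * w1) / den
        v = (v0[0] * w1 - w0 * v0[1]) / den
        inside = (u >= 0) & (v >= 0) & (u + v <= 1)
        if not inside.any():
            continue
        x = a[ax] + u[inside] * (b[ax] - a[ax]) + v[inside] * (c[ax] - a[ax])
        rows = g1.ravel()[inside] * d2v + g2.ravel()[inside]
        for r, xv in zip(rows, x):
            crossings[r].append(xv)

    nax = grid.dims[ax]
    line = np.zeros((d1, d2v, nax), dtype=bool)
    for r, xs in enumerate(crossings):
        if not xs:
            continue
        xs = np.sort(xs)
        # parity fill between pairs of crossings
        for s in range(0, len(xs) - 1, 2):
            j0 = int(np.ceil(xs[s]))
            j1 = int(np.floor(xs[s + 1]))
            j0 = max(j0, 0)
            j1 = min(j1, nax - 1)
            if j1 >= j0:
                line[r // d2v, r % d2v, j0:j1 + 1] = True
    mask = np.moveaxis(line, -1, ax)
    return MaskImage(grid, mask)


def select_nodes_under_sheet(nodes, sheet: TriSurface, tol: float = 5.0):
    """Indices of nodes within ``tol`` mm (closest-point distance) of the sheet."""
    if tol < 0:
        raise ValueError("tol must be >= 0")
    pts = nodes.points if isinstance(nodes, PointSet) else np.asarray(nodes, dtype=float)
    _, d, _ = closest_point_on_surface(pts, sheet)
    idx = np.flatnonzero(d <= tol + 1e-12)
    if len(idx) == 0:
        warnings.warn("select_nodes_under_sheet: empty selection")
    return idx


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_stl(path, ras_to_lps: bool = False) -> TriSurface:
    import trimesh

    mesh = trimesh.load_mesh(str(path), process=False)
    mesh.merge_vertices()  # STL stores an unindexed triangle soup
    v = np.asarray(mesh.vertices, dtype=float)
    if ras_to_lps:
        v = v * np.array([-1.0, -1.0, 1.0])
    surf = TriSurface(v, np.asarray(mesh.faces))
    if ras_to_lps:
        surf = surf.flipped()  # the reflection reverses orientation
    return surf


def write_stl(surface: TriSurface, path, lps_to_ras: bool = False):
    import trimesh

    v = surface.vertices
    f = surface.triangles
    if lps_to_ras:
        v = v * np.array([-1.0, -1.0, 1.0])
        f = f[:, [0, 2, 1]]
    trimesh.Trimesh(vertices=v, faces=f, process=False).export(str(path))


def read_fcsv(path) -> PointSet:
    """Read a 3D Slicer markups fiducial CSV; RAS files are converted to LPS."""
    coord = "LPS"
    pts, labels = [], []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                low = line.lower()
                if "coordinatesystem" in low.replace(" ", ""):
                    coord = "RAS" if ("ras" in low or "= 0" in low) else "LPS"
                continue
            cols = line.split(",")
            x, y, z = float(cols[1]), float(cols[2]), float(cols[3])
            label = cols[11] if len(cols) > 11 and cols[11] else cols[0]
            pts.append((x, y, z))
            labels.append(label)
    pts = np.asarray(pts, dtype=float).reshape(-1, 3)
    if coord == "RAS":
        pts[:, 0] *= -1
        pts[:, 1] *= -1
    return PointSet(pts, labels)


def write_fcsv(points: PointSet, path, coordinate_system: str = "LPS"):
    pts = points.points.copy()
    if coordinate_system.upper() == "RAS":
        pts[:, 0] *= -1
        pts[:, 1] *= -1
    with open(path, "w") as f:
        f.write("# Markups fiducial file version = 4.11\n")
        f.write(f"# CoordinateSystem = {coordinate_system.upper()}\n")
        f.write("# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID\n")
        for i, (p, lab) in enumerate(zip(pts, points.labels)):
            f.write(f"vtkMRMLMarkupsFiducialNode_{i},{p[0]:.6f},{p[1]:.6f},{p[2]:.6f},"
                    f"0,0,0,1,1,1,0,{lab},,\n")
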