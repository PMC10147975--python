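"""Voxel image containers, NRRD I/O and basic image operations.

All images live on an :class:`ImageGrid`: a regular voxel lattice with a
world-coordinate affine (LPS frame throughout the package).  Voxel centers sit
at ``origin + direction @ diag(spacing) @ index`` with 0-based indices
(node-centered NRRD convention).

The NRRD reader/writer implemented here covers the subset of NRRD0005 used by
this pipeline: 3-D scalar/label/mask volumes, per-voxel 3-vectors and
symmetric 3x3 tensors (kind ``3D-symmetric-matrix``), raw/gzip/ascii
encodings, ``space directions``, ``space origin`` and ``measurement frame``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ImageGrid",
    "ScalarImage",
    "LabelImage",
    "MaskImage",
    "VectorImage",
    "TensorImage",
    "read_nrrd",
    "write_nrrd",
    "otsu_threshold",
    "connected_components",
    "dilate_mask",
    "resample_trilinear",
]

# Index order of the six unique tensor components, matching NRRD's
# 3D-symmetric-matrix layout: Dxx Dxy Dxz Dyy Dyz Dzz.
SYM6 = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageGrid:
    """Regular voxel lattice with world affine (LPS).

    Parameters
    ----------
    dims : (3,) int
        Number of voxels per axis.
    spacing : (3,) float, mm
    origin : (3,) float, mm — world position of voxel (0,0,0) center.
    direction : (3,3) float — unit-norm columns; world axis of each index axis.
    """

    dims: tuple
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)
    direction: tuple = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))

    def __post_init__(self):
        dims = tuple(int(d) for d in self.dims)
        spacing = tuple(float(s) for s in self.spacing)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise ValueError(f"dims must be three positive integers, got {dims}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive floats, got {spacing}")
        D = np.asarray(self.direction, dtype=float)
        if D.shape != (3, 3):
            raise ValueError("direction must be 3x3")
        norms = np.linalg.norm(D, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("direction columns must be unit norm")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(self, "direction", tuple(map(tuple, D)))

    # -- affine helpers ----------------------------------------------------
    @property
    def affine(self) -> np.ndarray:
        """3x3 matrix mapping index steps to world steps (direction*spacing)."""
        return np.asarray(self.direction) @ np.diag(self.spacing)

    @property
    def voxel_volume(self) -> float:
        return abs(float(np.linalg.det(self.affine)))

    def index_to_world(self, idx) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return np.asarray(self.origin) + idx @ self.affine.T

    def world_to_index(self, pts) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return (pts - np.asarray(self.origin)) @ np.linalg.inv(self.affine).T

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape dims + (3,)."""
        ii, jj, kk = np.meshgrid(*(np.arange(d) for d in self.dims), indexing="ij")
        idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        return self.index_to_world(idx).reshape(self.dims + (3,))


def _check_shape(grid, values, extra=()):
    want = tuple(grid.dims) + tuple(extra)
    if values.shape != want:
        raise ValueError(f"value array shape {values.shape} != {want}")


@dataclass
class ScalarImage:
    grid: ImageGrid
    values: np.ndarray  # float, shape dims

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        _check_shape(self.grid, self.values)


@dataclass
class LabelImage:
    grid: ImageGrid
    values: np.ndarray  # int >= 0, shape dims

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("labels must be integers")
        if self.values.min(initial=0) < 0:
            raise ValueError("labels must be nonnegative")
        _check_shape(self.grid, self.values)

    @property
    def labels(self) -> np.ndarray:
        lab = np.unique(self.values)
        return lab[lab > 0]


@dataclass
class MaskImage:
    grid: ImageGrid
    values: np.ndarray  # bool, shape dims

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)
        _check_shape(self.grid, self.values)


@dataclass
class VectorImage:
    """Per-voxel world-frame 3-vectors (e.g. displacement in mm)."""
    grid: ImageGrid
    vectors: np.ndarray  # shape dims + (3,)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        _check_shape(self.grid, self.vectors, (3,))


@dataclass
class TensorImage:
    """Per-voxel symmetric 3x3 tensors stored as 6 unique components.

    Component order is Dxx, Dxy, Dxz, Dyy, Dyz, Dzz; symmetry is exact by
    storage.  ``measurement_frame`` records the frame the components were
    acquired in; the reader rotates components into the world frame on load,
    after which the frame is identity.
    """
    grid: ImageGrid
    components: np.ndarray  # shape dims + (6,)
    measurement_frame: np.ndarray = field(
        default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.components = np.asarray(self.components, dtype=float)
        _check_shape(self.grid, self.components, (6,))
        self.measurement_frame = np.asarray(self.measurement_frame, dtype=float)

    def to_matrices(self) -> np.ndarray:
        """Full symmetric 3x3 tensors, shape dims + (3, 3)."""
        c = self.components
        M = np.empty(c.shape[:-1] + (3, 3))
        for n, (i, j) in enumerate(SYM6):
            M[..., i, j] = c[..., n]
            M[..., j, i] = c[..., n]
        return M

    @staticmethod
    def matrices_to_components(M: np.ndarray) -> np.ndarray:
        c = np.empty(M.shape[:-2] + (6,))
        for n, (i, j) in enumerate(SYM6):
            c[..., n] = 0.5 * (M[..., i, j] + M[..., j, i])
        return c

    @classmethod
    def from_matrices(cls, grid, M):
        return cls(grid, cls.matrices_to_components(np.asarray(M, dtype=float)))


# ---------------------------------------------------------------------------
# NRRD I/O
# ---------------------------------------------------------------------------

_LPS = "left-posterior-superior"


def _fmt_vec(v):
    return "(" + ",".join(repr(float(x)) for x in v) + ")"


def _parse_vecs(s):
    out = []
    for tok in s.replace(")", ") ").split():
        tok = tok.strip()
        if not tok:
            continue
        if tok.lower() == "none":
            out.append(None)
        else:
            out.append([float(x) for x in tok.strip("()").split(",")])
    return out


def write_nrrd(image, path, encoding: str = "gzip"):
    """Write an image to NRRD.  Space is always left-posterior-superior."""
    grid = image.grid
    if isinstance(image, ScalarImage):
        data, dtype, kinds, rng = image.values, "double", None, 0
    elif isinstance(image, MaskImage):
        data, dtype, kinds, rng = image.values.astype(np.uint8), "uint8", None, 0
    elif isinstance(image, LabelImage):
        data, dtype, kinds, rng = image.values.astype(np.int32), "int32", None, 0
    elif isinstance(image, VectorImage):
        data = np.moveaxis(image.vectors, -1, 0)
        dtype, kinds, rng = "double", "vector domain domain domain", 3
    elif isinstance(image, TensorImage):
        data = np.moveaxis(image.components, -1, 0)
        dtype, kinds, rng = "double", "3D-symmetric-matrix domain domain domain", 6
    else:
        raise TypeError(f"cannot write {type(image).__name__}")

    sd = (np.asarray(grid.direction) @ np.diag(grid.spacing)).T  # rows: per index axis
    lines = ["NRRD0005", "# generated by ecogforward"]
    lines.append(f"type: {dtype}")
    lines.append(f"dimension: {data.ndim}")
    lines.append("sizes: " + " ".join(str(s) for s in data.shape))
    if kinds:
        lines.append(f"kinds: {kinds}")
    lines.append(f"encoding: {encoding}")
    lines.append("endian: little")
    lines.append(f"space: {_LPS}")
    sdirs = ([ "none" ] if rng else []) + [_fmt_vec(row) for row in sd]
    lines.append("space directions: " + " ".join(sdirs))
    lines.append("space origin: " + _fmt_vec(grid.origin))
    if isinstance(image, TensorImage):
        mf = np.asarray(image.measurement_frame)
        lines.append("measurement frame: " + " ".join(_fmt_vec(mf[:, c]) for c in range(3)))
    header = "\n".join(lines) + "\n\n"

    raw = np.ascontiguousarray(data.T).astype(f"<{data.dtype.str[1:]}")
    # data.T makes the first NRRD axis fastest (NRRD is fastest-first).
    buf = raw.tobytes()
    if encoding == "gzip":
        buf = gzip.compress(buf, mtime=0)  # fixed mtime: bit-reproducible output
    elif encoding == "ascii":
        buf = " ".join(format(v, ".17g") for v in raw.ravel().tolist()).encode()
    elif encoding != "raw":
        raise ValueError(f"unsupported encoding {encoding!r}")
    with open(path, "wb") as f:
        f.write(header.encode())
        f.write(buf)


_DTYPES = {
    "double": "<f8", "float": "<f4", "int": "<i4", "int32": "<i4",
    "short": "<i2", "ushort": "<u2", "uchar": "|u1", "uint8": "|u1",
    "unsigned char": "|u1", "int64": "<i8", "long": "<i8",
    "signed char": "|i1", "int16": "<i2", "uint16": "<u2", "uint32": "<u4",
}


def read_nrrd(path):
    """Read an NRRD file into the appropriate image container.

    Tensor components are rotated into the world frame using the measurement
    frame on load (D_world = F D F^T) so downstream code never sees a
    non-identity frame.
    """
    with open(path, "rb") as f:
        blob = f.read()
    head_end = blob.find(b"\n\n")
    if head_end < 0:
        raise ValueError("not a detached-free NRRD: no blank line after header")
    header_lines = blob[:head_end].decode("ascii", "replace").splitlines()
    if not header_lines or not header_lines[0].startswith("NRRD"):
        raise ValueError("missing NRRD magic")
    fields = {}
    for ln in header_lines[1:]:
        if ln.startswith("#") or not ln.strip():
            continue
        key, _, val = ln.partition(":")
        fields[key.strip().lower()] = val.strip()

    if "sizes" not in fields or "type" not in fields:
        raise ValueError("NRRD header missing required field 'sizes' or 'type'")
    sizes = [int(s) for s in fields["sizes"].split()]
    dtype = _DTYPES.get(fields["type"])
    if dtype is None:
        raise ValueError(f"unsupported NRRD field: type = {fields['type']!r}")
    space = fields.get("space", _LPS)
    if space not in (_LPS, "LPS"):
        raise ValueError(f"unsupported NRRD field: space = {space!r}")
    enc = fields.get("encoding", "raw")
    payload = blob[head_end + 2:]
    if enc in ("ascii", "txt", "text"):
        arr = np.fromiter(
            (float(t) for t in payload.split()), dtype=np.float64
        ).astype(dtype)
    else:
        if enc in ("gzip", "gz"):
            payload = gzip.decompress(payload)
        elif enc != "raw":
            raise ValueError(f"unsupported NRRD field: encoding = {enc!r}")
        arr = np.frombuffer(payload, dtype=dtype)
    n = int(np.prod(sizes))
    if arr.size < n:
        raise ValueError("NRRD payload truncated")
    arr = arr[:n].reshape(sizes[::-1]).T  # fastest-first file order -> sizes order

    kinds = fields.get("kinds", "").split()
    rng = 0
    if kinds and kinds[0] in ("vector", "3D-symmetric-matrix", "covariant-vector"):
        rng = sizes[0]
        if kinds[0] == "vector" and rng != 3:
            raise ValueError(f"unsupported NRRD field: kinds vector of size {rng}")
        if kinds[0] == "3D-symmetric-matrix" and rng != 6:
            raise ValueError("3D-symmetric-matrix axis must have size 6")
    elif kinds and kinds[0] not in ("domain", "space"):
        raise ValueError(f"unsupported NRRD field: kinds = {fields['kinds']!r}")
    elif len(sizes) == 4:
        raise ValueError("4-D NRRD without a recognized non-domain kind")

    sd = _parse_vecs(fields.get("space directions", ""))
    sd = [v for v in sd if v is not None]
    if len(sd) != 3:
        raise ValueError("unsupported NRRD field: space directions (need 3 domain axes)")
    A = np.asarray(sd).T  # columns = world step per index axis
    spacing = np.linalg.norm(A, axis=0)
    direction = A / spacing
    origin = _parse_vecs(fields.get("space origin", "(0,0,0)"))[0]
    dims = sizes[1:] if rng else sizes
    grid = ImageGrid(tuple(dims), tuple(spacing), tuple(origin), direction)

    if rng == 3:
        return VectorImage(grid, np.moveaxis(arr, 0, -1).astype(float))
    if rng == 6:
        comps = np.moveaxis(arr, 0, -1).astype(float)
        img = TensorImage(grid, comps)
        mf = fields.get("measurement frame")
        if mf:
            F = np.asarray(_parse_vecs(mf)).T
            if not np.allclose(F, np.eye(3)):
                D = img.to_matrices()
                Dw = np.einsum("ab,...bc,dc->...ad", F, D, F)
                img = TensorImage(grid, TensorImage.matrices_to_components(Dw))
        return img
    if np.issubdtype(np.dtype(dtype), np.integer):
        if fields["type"] in ("uchar", "uint8", "unsigned char") and arr.max(initial=0) <= 1:
            return MaskImage(grid, arr.astype(bool))
        return LabelImage(grid, arr.astype(np.int64))
    return ScalarImage(grid, arr.astype(float))


# ---------------------------------------------------------------------------
# Basic operations
# ---------------------------------------------------------------------------

def otsu_threshold(image: ScalarImage, mask: MaskImage | None = None,
                   n_bins: int = 128):
    """Otsu's threshold over an ``n_bins`` histogram of the (masked) image.

    Returns ``(threshold, out_mask)`` where the output mask marks voxels with
    value strictly greater than the threshold (restricted to ``mask`` if
    given).  The threshold maximizes the between-class variance
    ``w0*w1*(mu0-mu1)^2`` over all histogram cut points and is reported as the
    midpoint of the optimal cut (bin edge).
    """
    vals = image.values[mask.values] if mask is not None else image.values.ravel()
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmin == vmax:
        raise ValueError("otsu_threshold: image is constant within the mask")
    hist, edges = np.histogram(vals, bins=n_bins, range=(vmin, vmax))
    hist = hist.astype(float)
    w0 = np.cumsum(hist)
    w1 = w0[-1] - w0
    centers = 0.5 * (edges[:-1] + edges[1:])
    m = hist * centers
    mu0 = np.cumsum(m)
    mu1 = mu0[-1] - mu0
    with np.errstate(invalid="ignore", divide="ignore"):
        sb = np.where((w0 > 0) & (w1 > 0),
                      w0 * w1 * (mu0 / np.where(w0 > 0, w0, 1)
                                 - mu1 / np.where(w1 > 0, w1, 1)) ** 2, -1.0)
    k = int(np.argmax(sb[:-1]))  # cut after bin k
    threshold = float(edges[k + 1])
    out = image.values > threshold
    if mask is not None:
        out &= mask.values
    return threshold, MaskImage(image.grid, out)


_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def connected_components(mask: MaskImage, connectivity: int = 26) -> LabelImage:
    """Label maximal connected components 1..K.

    Labels are assigned deterministically by raster order (C order) of each
    component's first voxel.
    """
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 6, 18 or 26")
    lab, k = ndimage.label(mask.values, structure=_STRUCTS[connectivity])
    if k:
        flat = lab.ravel()
        first = np.full(k + 1, flat.size, dtype=np.int64)
        nz = np.flatnonzero(flat)
        # first occurrence per label in raster order
        np.minimum.at(first, flat[nz], nz)
        order = np.argsort(first[1:], kind="stable")
        remap = np.zeros(k + 1, dtype=np.int64)
        remap[1 + order] = np.arange(1, k + 1)
        lab = remap[lab]
    return LabelImage(mask.grid, lab.astype(np.int64))


def dilate_mask(mask: MaskImage, distance_mm: float) -> MaskImage:
    """Dilate by a world-space distance via the Euclidean distance transform.

    Output marks voxels whose center lies within ``distance_mm`` of some input
    voxel center; the input is always contained in the output.
    """
    if distance_mm < 0:
        raise ValueError("distance must be >= 0")
    if distance_mm == 0 or not mask.values.any():
        return MaskImage(mask.grid, mask.values.copy())
    dt = ndimage.distance_transform_edt(~mask.values, sampling=mask.grid.spacing)
    return MaskImage(mask.grid, dt <= distance_mm + 1e-12)


def resample_trilinear(image, points_world, background: float = 0.0):
    """Trilinearly sample a scalar or vector image at world points.

    Points outside the voxel-center hull get the ``background`` value.
    """
    pts = np.atleast_2d(np.asarray(points_world, dtype=float))
    idx = image.grid.world_to_index(pts).T  # (3, n)
    if isinstance(image, VectorImage):
        out = np.stack([
            ndimage.map_coordinates(image.vectors[..., c], idx, order=1,
                                    mode="constant", cval=background)
            for c in range(3)
        ], axis=-1)
    else:
        out = ndimage.map_coordinates(image.values, idx, order=1,
                                      mode="constant", cval=background)
    return out
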