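"""Image containers, NRRD round trips and basic voxel operations."""

import numpy as np
import pytest

from ecogforward.images import (ImageGrid, LabelImage, MaskImage, ScalarImage,
                                TensorImage, VectorImage, connected_components,
                                dilate_mask, otsu_threshold, read_nrrd,
                                resample_trilinear, write_nrrd)

GRID = ImageGrid((8, 7, 6), (1.0, 1.09375, 1.09375), (-3.0, 2.0, 1.0))


class TestNrrdRoundTrip:
    @pytest.mark.parametrize("encoding", ["raw", "gzip", "ascii"])
    def test_scalar_lossless(self, tmp_path, rng, encoding):
        img = ScalarImage(GRID, rng.normal(size=GRID.dims))
        write_nrrd(img, tmp_path / "s.nrrd", encoding=encoding)
        back = read_nrrd(tmp_path / "s.nrrd")
        assert isinstance(back, ScalarImage)
        np.testing.assert_array_equal(back.values, img.values)
        np.testing.assert_allclose(back.grid.spacing, GRID.spacing)
        np.testing.assert_allclose(back.grid.origin, GRID.origin)

    def test_label_vector_tensor_lossless(self, tmp_path, rng):
        lab = LabelImage(GRID, rng.integers(0, 5, GRID.dims))
        vec = VectorImage(GRID, rng.normal(size=GRID.dims + (3,)))
        M = rng.normal(size=GRID.dims + (3, 3))
        ten = TensorImage.from_matrices(GRID, M + np.swapaxes(M, -1, -2))
        for name, img in [("l", lab), ("v", vec), ("t", ten)]:
            write_nrrd(img, tmp_path / f"{name}.nrrd")
            back = read_nrrd(tmp_path / f"{name}.nrrd")
            assert type(back) is type(img)
        np.testing.assert_array_equal(read_nrrd(tmp_path / "l.nrrd").values,
                                      lab.values)
        np.testing.assert_array_equal(read_nrrd(tmp_path / "v.nrrd").vectors,
                                      vec.vectors)
        np.testing.assert_array_equal(read_nrrd(tmp_path / "t.nrrd").components,
                                      ten.components)

    def test_measurement_frame_applied_on_load(self, tmp_path, rng):
        """Loaded tensors equal R D R^T of the stored components."""
        M = rng.normal(size=GRID.dims + (3, 3))
        ten = TensorImage.from_matrices(GRID, M + np.swapaxes(M, -1, -2))
        th = 0.3
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        ten.measurement_frame = R
        write_nrrd(ten, tmp_path / "f.nrrd")
        back = read_nrrd(tmp_path / "f.nrrd")
        D = ten.to_matrices()
        expect = np.einsum("ab,...bc,dc->...ad", R, D, R)
        np.testing.assert_allclose(back.to_matrices(), expect, atol=1e-12)
        # identity frame leaves tensors unchanged
        ten.measurement_frame = np.eye(3)
        write_nrrd(ten, tmp_path / "i.nrrd")
        np.testing.assert_allclose(read_nrrd(tmp_path / "i.nrrd").components,
                                   ten.components, atol=0)

    def test_unsupported_fields_raise(self, tmp_path, rng):
        img = ScalarImage(GRID, rng.normal(size=GRID.dims))
        write_nrrd(img, tmp_path / "s.nrrd")
        text = (tmp_path / "s.nrrd").read_bytes()
        bad = text.replace(b"left-posterior-superior", b"right-anterior-superior")
        (tmp_path / "bad.nrrd").write_bytes(bad)
        with pytest.raises(ValueError, match="space"):
            read_nrrd(tmp_path / "bad.nrrd")


class TestOtsu:
    def test_two_delta_histogram(self):
        vals = np.concatenate([np.full(100, 10.0), np.full(100, 100.0)])
        img = ScalarImage(ImageGrid((200, 1, 1), (1, 1, 1)),
                          vals.reshape(200, 1, 1))
        t, out = otsu_threshold(img)
        assert 10.0 < t < 100.0
        assert out.values.sum() == 100
        assert (img.values[out.values] == 100.0).all()

    def test_matches_exhaustive_search(self, rng):
        """Otsu equals brute-force maximization of between-class variance."""
        vals = np.concatenate([rng.normal(30, 5, 4000), rng.normal(90, 12, 2500)])
        img = ScalarImage(ImageGrid((len(vals), 1, 1), (1, 1, 1)),
                          vals.reshape(-1, 1, 1))
        n_bins = 64
        t, _ = otsu_threshold(img, n_bins=n_bins)
        hist, edges = np.histogram(vals, bins=n_bins)
        best, best_t = -1.0, None
        for k in range(1, n_bins):
            lo, hi = vals[vals <= edges[k]], vals[vals > edges[k]]
            if len(lo) == 0 or len(hi) == 0:
                continue
            sb = len(lo) * len(hi) * (lo.mean() - hi.mean()) ** 2
            if sb > best:
                best, best_t = sb, edges[k]
        # same cut point up to binning of the means (bin-center vs exact means)
        assert abs(t - best_t) <= (edges[1] - edges[0]) + 1e-9

    def test_mask_restricts_and_contains(self, rng):
        vals = np.zeros((10, 10, 10))
        vals[:5] = 100.0
        vals[5:] = rng.normal(10, 1, (5, 10, 10))
        img = ScalarImage(ImageGrid((10, 10, 10), (1, 1, 1)), vals)
        mask = MaskImage(img.grid, np.ones((10, 10, 10), dtype=bool))
        mask.values[:2] = False
        t, out = otsu_threshold(img, mask=mask)
        assert not out.values[~mask.values].any()  # out is a subset of the mask

    def test_constant_image_raises(self):
        img = ScalarImage(ImageGrid((4, 4, 4), (1, 1, 1)), np.ones((4, 4, 4)))
        with pytest.raises(ValueError):
            otsu_threshold(img)


def _flood_fill_labels(mask, connectivity):
    """Independent BFS flood-fill oracle."""
    offs = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                n_nz = sum(x != 0 for x in (di, dj, dk))
                if n_nz == 0:
                    continue
                if (connectivity == 6 and n_nz > 1) or \
                        (connectivity == 18 and n_nz > 2):
                    continue
                offs.append((di, dj, dk))
    lab = np.zeros(mask.shape, dtype=int)
    nxt = 0
    for idx in np.ndindex(mask.shape):
        if mask[idx] and lab[idx] == 0:
            nxt += 1
            stack = [idx]
            lab[idx] = nxt
            while stack:
                i, j, k = stack.pop()
                for di, dj, dk in offs:
                    w = (i + di, j + dj, k + dk)
                    if all(0 <= w[a] < mask.shape[a] for a in range(3)) \
                            and mask[w] and lab[w] == 0:
                        lab[w] = nxt
                        stack.append(w)
    return lab


class TestConnectedComponents:
    def test_two_cubes_and_single_voxel(self):
        m = np.zeros((8, 8, 8), dtype=bool)
        m[:2, :2, :2] = True
        m[5:7, 5:7, 5:7] = True
        lab = connected_components(MaskImage(ImageGrid((8, 8, 8), (1, 1, 1)), m))
        assert len(lab.labels) == 2
        single = np.zeros((3, 3, 3), dtype=bool)
        single[1, 1, 1] = True
        lab1 = connected_components(
            MaskImage(ImageGrid((3, 3, 3), (1, 1, 1)), single))
        assert list(lab1.labels) == [1]

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        m = rng.random((12, 12, 12)) < 0.3
        lab = connected_components(
            MaskImage(ImageGrid((12, 12, 12), (1, 1, 1)), m), connectivity)
        oracle = _flood_fill_labels(m, connectivity)
        # identical partition: same membership, same first-voxel ordering
        np.testing.assert_array_equal(lab.values, oracle)


class TestDilate:
    def _one_voxel(self, spacing):
        m = np.zeros((17, 17, 17), dtype=bool)
        m[8, 8, 8] = True
        return MaskImage(ImageGrid((17, 17, 17), (spacing,) * 3), m)

    def test_zero_distance_identity(self):
        m = self._one_voxel(1.0)
        out = dilate_mask(m, 0.0)
        np.testing.assert_array_equal(out.values, m.values)

    def test_four_point_four_mm_is_four_voxels(self):
        """A 4.4 mm offset at 1.1 mm spacing spans exactly 4 voxel steps."""
        m = self._one_voxel(1.1)
        out = dilate_mask(m, 4.4)
        ii = np.argwhere(out.values) - 8
        r = np.abs(ii).max()
        assert r == 4
        assert out.values[8, 8, 12] and not out.values[8, 8, 13]

    def test_extensive_and_monotone(self, rng):
        m = MaskImage(ImageGrid((10, 10, 10), (1, 1, 1)),
                      rng.random((10, 10, 10)) < 0.1)
        d1 = dilate_mask(m, 1.0)
        d2 = dilate_mask(m, 2.5)
        assert (d1.values | m.values == d1.values).all()   # input subset output
        assert (d2.values | d1.values == d2.values).all()  # monotone


class TestResample:
    def test_voxel_centers_exact(self, rng):
        img = ScalarImage(GRID, rng.normal(size=GRID.dims))
        idx = np.stack(np.meshgrid(*(np.arange(d) for d in GRID.dims),
                                   indexing="ij"), axis=-1).reshape(-1, 3)
        pts = GRID.index_to_world(idx)
        np.testing.assert_allclose(resample_trilinear(img, pts),
                                   img.values.ravel(), atol=1e-12)

    def test_linear_ramp_exact(self, rng):
        a, b = np.array([0.3, -1.2, 2.0]), 5.0
        centers = GRID.voxel_centers()
        img = ScalarImage(GRID, centers @ a + b)
        pts = GRID.index_to_world(rng.uniform(0.5, 4.5, (50, 3)))
        np.testing.assert_allclose(resample_trilinear(img, pts),
                                   pts @ a + b, atol=1e-12)

    def test_outside_returns_background(self):
        img = ScalarImage(GRID, np.ones(GRID.dims))
        out = resample_trilinear(img, [[1e4, 1e4, 1e4]], background=-7.0)
        assert out[0] == -7.0
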