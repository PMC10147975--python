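"""DTI invariants, fuzzy C-means, label fusion and conductivity tensors."""

import numpy as np
import pytest

from ecogforward.images import ImageGrid, LabelImage, MaskImage, TensorImage
from ecogforward.phantom import (SpherePhantomSpec, SyntheticDTISpec,
                                 make_sphere_phantom, make_synthetic_dti)
from ecogforward.tissue import (CLASS_CSF, CLASS_GM, CLASS_SCALP, CLASS_SHEET,
                                CLASS_SKULL, CLASS_WM, ConductivitySpec,
                                FCMConfig, assign_conductivity,
                                build_head_labelmap, classify_brain, fcm,
                                fcm_objective, tensor_invariants)

GRID = ImageGrid((8, 8, 8), (1, 1, 1))

# literature-style diffusion eigenvalues (mm^2/s)
EIGS = {CLASS_CSF: (3.0e-3, 3.0e-3, 3.0e-3),
        CLASS_GM: (0.9e-3, 0.7e-3, 0.7e-3),
        CLASS_WM: (1.6e-3, 0.4e-3, 0.4e-3)}


def brain_phantom(seed=0, noise=5e-5):
    spec = SpherePhantomSpec((14.0, 11.0, 7.0), (CLASS_CSF, CLASS_GM, CLASS_WM),
                             (32, 32, 32), (1, 1, 1))
    labels = make_sphere_phantom(spec)
    dti = make_synthetic_dti(labels, SyntheticDTISpec(
        EIGS, direction="tangential", center=tuple(spec.sphere_center()),
        noise_sd=noise, seed=seed))
    mask = MaskImage(labels.grid, labels.values > 0)
    return labels, dti, mask


class TestInvariants:
    def test_isotropic_and_planar_limits(self):
        comp = np.zeros(GRID.dims + (6,))
        comp[..., [0, 3, 5]] = 2.5e-3  # D = d I
        md, fa = tensor_invariants(TensorImage(GRID, comp))
        np.testing.assert_allclose(md.values, 2.5e-3, atol=1e-18)
        np.testing.assert_allclose(fa.values, 0.0, atol=1e-12)
        comp2 = np.zeros(GRID.dims + (6,))
        comp2[..., 0] = 1.0  # D = diag(1,0,0)
        _, fa2 = tensor_invariants(TensorImage(GRID, comp2))
        np.testing.assert_allclose(fa2.values, 1.0, atol=1e-12)

    def test_matches_eigenvalue_formula(self, rng):
        A = rng.normal(size=GRID.dims + (3, 3))
        M = np.einsum("...ij,...kj->...ik", A, A) + 0.1 * np.eye(3)
        ten = TensorImage.from_matrices(GRID, M)
        md, fa = tensor_invariants(ten)
        w = np.linalg.eigvalsh(M)
        md_ref = w.mean(axis=-1)
        fa_ref = np.sqrt(1.5 * ((w - md_ref[..., None]) ** 2).sum(-1)
                         / (w ** 2).sum(-1))
        np.testing.assert_allclose(md.values, md_ref, atol=1e-12)
        np.testing.assert_allclose(fa.values, fa_ref, atol=1e-12)


class TestFCM:
    def test_separated_clouds_recovered(self, rng):
        a = rng.normal(0.0, 0.05, (300, 2))
        b = rng.normal(5.0, 0.05, (200, 2))
        X = np.vstack([a, b])
        u, centers = fcm(X, FCMConfig(n_clusters=2))
        order = np.argsort(centers[:, 0])
        np.testing.assert_allclose(centers[order][0], a.mean(axis=0), atol=0.02)
        np.testing.assert_allclose(centers[order][1], b.mean(axis=0), atol=0.02)
        hard = u.argmax(axis=1)
        assert (u.max(axis=1)[np.r_[0:300, 300:500]] > 0.99).mean() > 0.99
        assert len(set(hard[:300])) == 1 and len(set(hard[300:])) == 1

    def test_memberships_sum_to_one(self, rng):
        X = rng.normal(size=(100, 1))
        u, _ = fcm(X, FCMConfig(n_clusters=3))
        np.testing.assert_allclose(u.sum(axis=1), 1.0, atol=1e-12)

    def test_large_fuzziness_approaches_uniform(self, rng):
        X = rng.normal(size=(50, 1))
        u, _ = fcm(X, FCMConfig(n_clusters=2, fuzziness=50.0))
        np.testing.assert_allclose(u, 0.5, atol=0.15)

    def test_objective_monotone_nonincreasing(self, rng):
        X = np.vstack([rng.normal(0, 1, (100, 1)), rng.normal(4, 1, (100, 1))])
        cfg = FCMConfig(n_clusters=2, tolerance=0.0, max_iter=1)
        # run the alternation manually, tracking the objective
        centers = np.array([[X.min()], [X.max()]])
        from ecogforward.tissue import _fcm_memberships
        prev = np.inf
        for _ in range(20):
            u = _fcm_memberships(X, centers, 2.0)
            obj = fcm_objective(X, u, centers)
            assert obj <= prev + 1e-12
            prev = obj
            um = u ** 2
            centers = (um.T @ X) / um.sum(axis=0)[:, None]
            obj2 = fcm_objective(X, u, centers)
            assert obj2 <= obj + 1e-12


class TestClassifyBrain:
    @pytest.mark.parametrize("seed", range(5))
    def test_accuracy_across_seeds(self, seed):
        labels, dti, mask = brain_phantom(seed=seed)
        seg = classify_brain(dti, mask, FCMConfig(seed=seed))
        acc = (seg.values[mask.values] == labels.values[mask.values]).mean()
        assert acc >= 0.99

    def test_partitions_the_mask(self):
        labels, dti, mask = brain_phantom()
        seg = classify_brain(dti, mask)
        assert (seg.values[mask.values] > 0).all()
        assert (seg.values[~mask.values] == 0).all()

    def test_constant_feature_raises(self):
        labels, _, mask = brain_phantom()
        iso = make_synthetic_dti(labels, SyntheticDTISpec(
            {k: (1e-3, 1e-3, 1e-3) for k in EIGS}))
        with pytest.raises(ValueError, match="degenerate|constant"):
            classify_brain(iso, mask)


class TestHeadLabelmap:
    def _brain(self):
        labels, _, mask = brain_phantom()
        return labels, mask

    def test_shell_thickness_four_voxels(self):
        spec = SpherePhantomSpec((12.0,), (CLASS_GM,), (40, 40, 40),
                                 (1.1, 1.1, 1.1))
        labels = make_sphere_phantom(spec)
        mask = MaskImage(labels.grid, labels.values > 0)
        lm = build_head_labelmap(labels, mask, shell_mm=4.4)
        # along the +x axis from the surface, the skull shell spans 4 voxels
        i0 = 19  # nearly central row (grid center between indices 19 and 20)
        row = lm.values[:, i0, i0]
        right = np.flatnonzero(row[20:] == CLASS_SKULL)
        assert len(right) == 4  # 4.4 mm at 1.1 mm spacing = 4 voxel steps
        assert np.all(np.diff(right) == 1)  # contiguous shell

    def test_five_classes_without_sheet_and_conservation(self):
        labels, mask = self._brain()
        lm = build_head_labelmap(labels, mask, shell_mm=2.0)
        got = set(int(c) for c in lm.labels)
        assert got == {CLASS_WM, CLASS_GM, CLASS_CSF, CLASS_SKULL, CLASS_SCALP}
        total = (lm.values > 0).sum()
        per_class = sum(int((lm.values == c).sum()) for c in got)
        assert per_class == total

    def test_sheet_overrides(self):
        labels, mask = self._brain()
        sheet = MaskImage(labels.grid, np.zeros(labels.grid.dims, dtype=bool))
        sheet.values[16, 16, 28:31] = True
        lm = build_head_labelmap(labels, mask, sheet, shell_mm=2.0)
        assert (lm.values[16, 16, 28:31] == CLASS_SHEET).all()


class TestConductivity:
    def _labelmap(self):
        labels, dti, mask = brain_phantom()
        lm = build_head_labelmap(labels, mask, shell_mm=2.0)
        return lm, dti

    def test_isotropic_wm_gives_sigma_ref_identity(self):
        lm, _ = self._labelmap()
        iso = TensorImage(lm.grid, np.zeros(tuple(lm.grid.dims) + (6,)))
        iso.components[..., [0, 3, 5]] = 1e-3
        cond = assign_conductivity(lm, iso, ConductivitySpec(sigma_ref=0.14))
        M = cond.to_matrices()[lm.values == CLASS_WM]
        np.testing.assert_allclose(M, np.broadcast_to(0.14 * np.eye(3), M.shape),
                                   atol=1e-12)

    def test_volume_normalized_determinant_identity(self):
        """det(sigma) = sigma_ref^3 for every WM voxel."""
        lm, dti = self._labelmap()
        cond = assign_conductivity(lm, dti, ConductivitySpec(sigma_ref=0.14))
        M = cond.to_matrices()[lm.values == CLASS_WM]
        np.testing.assert_allclose(np.linalg.det(M), 0.14 ** 3, atol=1e-10)

    def test_class_values_exact(self):
        lm, dti = self._labelmap()
        sheet = MaskImage(lm.grid, np.zeros(lm.grid.dims, dtype=bool))
        sheet.values[16, 16, 29] = True
        lm.values[sheet.values] = CLASS_SHEET
        cond = assign_conductivity(lm, dti, ConductivitySpec())
        M = cond.to_matrices()
        for cls, sig in [(CLASS_GM, 0.33), (CLASS_CSF, 1.79),
                         (CLASS_SKULL, 0.012), (CLASS_SCALP, 0.33),
                         (CLASS_SHEET, 1e-6)]:
            sel = lm.values == cls
            got = M[sel]
            np.testing.assert_allclose(
                got, np.broadcast_to(sig * np.eye(3), got.shape), atol=0,
                err_msg=f"class {cls}")

    def test_spd_everywhere_in_head(self):
        lm, dti = self._labelmap()
        cond = assign_conductivity(lm, dti, ConductivitySpec())
        M = cond.to_matrices()[lm.values > 0]
        w = np.linalg.eigvalsh(M)
        assert (w[:, 0] > 0).all()

    def test_missing_class_raises(self):
        lm, dti = self._labelmap()
        with pytest.raises(ValueError):
            assign_conductivity(lm, dti, ConductivitySpec(class_sigma={}))
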