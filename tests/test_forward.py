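"""Hexahedral FEM: meshing, assembly, full-subtraction source and sampling."""

import numpy as np
import pytest

from ecogforward.images import ImageGrid, LabelImage, MaskImage
from ecogforward.forward import (DipoleSource, ElementTensorField, HexMesh,
                                 assemble_system, full_subtraction_rhs,
                                 rdm_mag, sample_potentials, solve_forward,
                                 solve_potential, voxels_to_hexmesh)


def _mask(dims, fill=True):
    g = ImageGrid(dims, (1.0, 1.0, 1.0))
    m = np.full(dims, fill, dtype=bool)
    return MaskImage(g, m)


def _uniform_cond(mesh, sigma=1.0):
    return ElementTensorField(np.tile(sigma * np.eye(3),
                                      (mesh.n_elements, 1, 1)))


class TestHexMesh:
    def test_full_2x2x2_counts(self):
        mesh = voxels_to_hexmesh(_mask((2, 2, 2)))
        assert mesh.n_elements == 8
        assert len(mesh.nodes) == 27

    def test_element_count_and_volume_random_mask(self, rng):
        g = ImageGrid((9, 8, 7), (1.0, 1.25, 0.8))
        m = MaskImage(g, rng.random((9, 8, 7)) < 0.4)
        if not m.values.any():
            m.values[0, 0, 0] = True
        mesh = voxels_to_hexmesh(m)
        assert mesh.n_elements == m.values.sum()
        np.testing.assert_allclose(mesh.total_volume(),
                                   m.values.sum() * g.voxel_volume, atol=1e-9)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            voxels_to_hexmesh(_mask((3, 3, 3), fill=False))


class TestAssembly:
    def test_single_cube_matches_symbolic_assembly(self):
        """K for one unit cube with sigma = I vs independent sympy integral."""
        import sympy as sp

        mesh = voxels_to_hexmesh(_mask((1, 1, 1)))
        K = assemble_system(mesh, _uniform_cond(mesh)).toarray()
        x, y, z = sp.symbols("x y z")
        corners = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
                   (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)]
        N = [((1 - x) if cx == 0 else x) * ((1 - y) if cy == 0 else y)
             * ((1 - z) if cz == 0 else z) for cx, cy, cz in corners]
        # map symbolic corners to mesh node indices
        idx = []
        for c in corners:
            d = np.linalg.norm(mesh.nodes - (np.array(c) - 0.5), axis=1)
            idx.append(int(np.argmin(d)))
        hx = mesh.hexes[0]
        Kref = np.zeros((8, 8))
        for a in range(8):
            ga = [sp.diff(N[a], v) for v in (x, y, z)]
            for b in range(a, 8):
                gb = [sp.diff(N[b], v) for v in (x, y, z)]
                val = sp.integrate(sum(p * q for p, q in zip(ga, gb)),
                                   (x, 0, 1), (y, 0, 1), (z, 0, 1))
                Kref[a, b] = Kref[b, a] = float(val)
        got = np.zeros((8, 8))
        for a in range(8):
            for b in range(8):
                got[a, b] = K[idx[a], idx[b]]
        np.testing.assert_allclose(got, Kref, atol=1e-12)

    def test_constant_null_space_and_linearity(self, rng):
        g = ImageGrid((4, 4, 4), (1.0, 1.2, 0.9))
        m = MaskImage(g, rng.random((4, 4, 4)) < 0.7)
        m.values[1, 1, 1] = True
        mesh = voxels_to_hexmesh(m)
        K1 = assemble_system(mesh, _uniform_cond(mesh, 0.33))
        K2 = assemble_system(mesh, _uniform_cond(mesh, 0.66))
        ones = np.ones(K1.shape[0])
        assert np.abs(K1 @ ones).max() < 1e-10
        np.testing.assert_allclose(K2.toarray(), 2 * K1.toarray(), atol=1e-12)
        assert np.abs((K1 - K1.T).data).max() < 1e-12 if (K1 - K1.T).nnz else True

    def test_non_spd_tensor_raises(self):
        mesh = voxels_to_hexmesh(_mask((2, 2, 2)))
        T = np.tile(np.eye(3), (8, 1, 1))
        T[3] = -np.eye(3)
        with pytest.raises(ValueError, match="element"):
            assemble_system(mesh, ElementTensorField(T))


class TestFullSubtractionRHS:
    def _setup(self, dims=(12, 12, 12)):
        mesh = voxels_to_hexmesh(_mask(dims))
        cond = _uniform_cond(mesh, 0.33)
        dip = DipoleSource((5.8, 5.5, 5.5), (1.0, 0.0, 0.5))
        return mesh, cond, dip

    def test_homogeneous_medium_boundary_term_only(self):
        """With sigma = sigma0 everywhere the volume term vanishes: interior
        nodes receive no load before the compatibility projection."""
        mesh, cond, dip = self._setup()
        b, _ = full_subtraction_rhs(mesh, cond, dip, project=False)
        surf = mesh.surface_node_mask()
        assert np.abs(b[~surf]).max() == 0.0
        assert np.abs(b[surf]).max() > 0.0

    def test_compatibility_condition(self):
        mesh, cond, dip = self._setup()
        b_raw, _ = full_subtraction_rhs(mesh, cond, dip, project=False)
        # the closed-surface flux of a dipole field integrates to ~0 already
        assert abs(b_raw.sum()) < 1e-6 * np.abs(b_raw).max()
        b, _ = full_subtraction_rhs(mesh, cond, dip, project=True)
        assert abs(b.sum()) < 1e-10 * max(np.abs(b).max(), 1e-300)

    def test_moment_flip_negates(self):
        mesh, cond, dip = self._setup()
        b1, _ = full_subtraction_rhs(mesh, cond, dip)
        b2, _ = full_subtraction_rhs(
            mesh, cond, DipoleSource(dip.position, -dip.moment))
        np.testing.assert_allclose(b2, -b1, atol=1e-14)

    def test_inhomogeneous_neighborhood_raises(self):
        mesh, cond, dip = self._setup()
        T = cond.tensors.copy()
        # contaminate an element adjacent to the dipole
        host = mesh.element_of_voxel[6, 5, 5]
        T[host] = 5.0 * np.eye(3)
        dip0 = DipoleSource(dip.position, dip.moment, sigma0=0.33)
        with pytest.raises(ValueError, match="inhomogeneous"):
            full_subtraction_rhs(mesh, ElementTensorField(T), dip0)


class TestSolve:
    def test_zero_rhs_zero_solution(self):
        mesh = voxels_to_hexmesh(_mask((4, 4, 4)))
        K = assemble_system(mesh, _uniform_cond(mesh))
        x, iters, res = solve_potential(K, np.zeros(K.shape[0]))
        assert np.abs(x).max() == 0.0

    def test_residual_contract(self, rng):
        mesh = voxels_to_hexmesh(_mask((6, 6, 6)))
        K = assemble_system(mesh, _uniform_cond(mesh, 0.33))
        b = rng.normal(size=K.shape[0])
        b -= b.mean()
        tol = 1e-9
        x, iters, res = solve_potential(K, b, tol=tol)
        assert res < tol
        assert abs(x.mean()) < 1e-9

    def test_gauge_fixed_spd_on_small_mesh(self):
        """Smallest nonzero eigenvalue of K is positive (SPD modulo constants)."""
        mesh = voxels_to_hexmesh(_mask((3, 3, 3)))
        K = assemble_system(mesh, _uniform_cond(mesh)).toarray()
        w = np.linalg.eigvalsh(K)
        assert abs(w[0]) < 1e-10       # the constant mode
        assert w[1] > 1e-8             # everything else strictly positive

    def test_solution_invariant_under_node_renumbering(self, rng):
        mesh = voxels_to_hexmesh(_mask((6, 6, 6)))
        cond = _uniform_cond(mesh, 0.33)
        dip = DipoleSource((3.1, 2.9, 3.0), (0.5, 0.2, 1.0))
        sol = solve_forward(mesh, cond, dip, tol=1e-10)
        perm = rng.permutation(len(mesh.nodes))
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        mesh2 = HexMesh(mesh.nodes[perm], inv[mesh.hexes], mesh.grid,
                        mesh.voxel_ijk, mesh.labels, mesh.element_of_voxel)
        sol2 = solve_forward(mesh2, cond, dip, tol=1e-10)
        np.testing.assert_allclose(sol2.total[inv], sol.total, atol=1e-7)


class TestSampling:
    def _solved_linear(self):
        mesh = voxels_to_hexmesh(_mask((5, 5, 5)))
        a, c = np.array([0.7, -0.3, 1.1]), 2.0
        vals = mesh.nodes @ a + c
        return mesh, vals, a, c

    def test_nodal_and_linear_exactness(self, rng):
        mesh, vals, a, c = self._solved_linear()
        node = mesh.nodes[17]
        got = sample_potentials(vals, mesh, [node])
        np.testing.assert_allclose(got, [node @ a + c], atol=1e-12)
        pts = rng.uniform(-0.4, 3.9, (20, 3))
        np.testing.assert_allclose(sample_potentials(vals, mesh, pts),
                                   pts @ a + c, atol=1e-12)

    def test_far_point_raises(self):
        mesh, vals, _, _ = self._solved_linear()
        with pytest.raises(ValueError, match="outside"):
            sample_potentials(vals, mesh, [[50.0, 50.0, 50.0]])


class TestRdmMag:
    @pytest.mark.parametrize("scale,expect_rdm,expect_mag",
                             [(1.0, 0.0, 1.0), (2.0, 0.0, 2.0)])
    def test_identical_and_scaled(self, rng, scale, expect_rdm, expect_mag):
        v = rng.normal(size=50)
        rdm, mag = rdm_mag(scale * v, v)
        assert rdm == pytest.approx(expect_rdm, abs=1e-12)
        assert mag == pytest.approx(expect_mag, abs=1e-12)

    def test_orthogonal_unit_vectors(self):
        rdm, mag = rdm_mag([1.0, 0.0], [0.0, 1.0])
        assert rdm == pytest.approx(np.sqrt(2.0))

    def test_zero_reference_raises(self):
        with pytest.raises(ValueError):
            rdm_mag([1.0], [0.0])
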