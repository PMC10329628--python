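"""Neo-Hookean hexahedral FE solver: element kernels, Newton solves,
registration, and the mechanical invariants."""

import numpy as np
import pytest

from attachnet.fe_solver import (BoundaryConditions, HexFE, Material,
                                 SolveOptions, element_energy_force_stiffness,
                                 register, solve_static)
from attachnet.geometry import HEX_OFFSETS, HexModel, RegularGrid

NAN = np.nan


def single_hex_model(h=0.02):
    grid = RegularGrid(origin=np.zeros(3), spacing=h, dims=(3, 3, 3))
    return HexModel(grid=grid, nodes=(HEX_OFFSETS * h).astype(float),
                    hexes=np.arange(8).reshape(1, 8),
                    kept_cells=np.array([[0, 0, 0]]),
                    surface_nodes=np.arange(8),
                    node_to_voxel=HEX_OFFSETS.copy(),
                    surface_faces=None)


def test_material_lame_constants():
    m = Material()
    assert m.lame_mu == pytest.approx(1689.19, abs=0.01)
    assert m.lame_lambda == pytest.approx(40540.54, abs=0.01)
    with pytest.raises(ValueError):
        Material(poisson_ratio=0.5)
    with pytest.raises(ValueError):
        Material(young_modulus=-1)


class TestElementKernels:
    def test_reference_state_zero_energy_zero_force(self):
        X = HEX_OFFSETS * 0.02
        e, f, _ = element_energy_force_stiffness(X, np.zeros((8, 3)), Material())
        assert e == pytest.approx(0.0, abs=1e-14)
        np.testing.assert_allclose(f, 0.0, atol=1e-10)

    def test_force_matches_energy_gradient(self, rng):
        X = HEX_OFFSETS * 0.02 + rng.normal(0, 0.001, (8, 3))
        u = rng.normal(0, 0.002, (8, 3))
        mat = Material()
        _, f, _ = element_energy_force_stiffness(X, u, mat)
        h = 1e-7
        fd = np.zeros((8, 3))
        for a in range(8):
            for c in range(3):
                up, um = u.copy(), u.copy()
                up[a, c] += h
                um[a, c] -= h
                ep = element_energy_force_stiffness(X, up, mat)[0]
                em = element_energy_force_stiffness(X, um, mat)[0]
                fd[a, c] = (ep - em) / (2 * h)
        assert np.abs(f - fd).max() / np.abs(f).max() < 1e-5

    def test_tangent_matches_force_jacobian(self, rng):
        X = HEX_OFFSETS * 0.02 + rng.normal(0, 0.001, (8, 3))
        u = rng.normal(0, 0.002, (8, 3))
        mat = Material()
        _, _, K = element_energy_force_stiffness(X, u, mat)
        h = 1e-7
        fd = np.zeros((24, 24))
        for a in range(8):
            for c in range(3):
                up, um = u.copy(), u.copy()
                up[a, c] += h
                um[a, c] -= h
                fp = element_energy_force_stiffness(X, up, mat)[1]
                fm = element_energy_force_stiffness(X, um, mat)[1]
                fd[:, 3 * a + c] = (fp - fm).ravel() / (2 * h)
        assert np.abs(K - fd).max() / np.abs(K).max() < 1e-4
        assert np.abs(K - K.T).max() / np.abs(K).max() < 1e-8

    def test_inverted_element_raises(self):
        X = HEX_OFFSETS * 0.02
        u = np.zeros((8, 3))
        u[:4, 2] = 0.05  # push bottom face through the top
        with pytest.raises(FloatingPointError):
            element_energy_force_stiffness(X, u, Material())

    def test_batch_assembly_matches_element_kernel(self, hex_model, rng):
        fe = HexFE(hex_model, Material())
        u = rng.normal(0, 1e-4, 3 * hex_model.n_nodes)
        e_batch = fe.energy(u)
        f_batch = fe.internal_forces(u)
        e_sum = 0.0
        f_sum = np.zeros_like(f_batch)
        un = u.reshape(-1, 3)
        for cell in range(min(hex_model.n_cells, 25)):
            idx = hex_model.hexes[cell]
            e, f, _ = element_energy_force_stiffness(hex_model.nodes[idx],
                                                     un[idx], Material())
            e_sum += e
            for a, n in enumerate(idx):
                f_sum[3 * n:3 * n + 3] += f[a]
        if hex_model.n_cells <= 25:
            assert e_batch == pytest.approx(e_sum, rel=1e-10)
        # spot check a few elements' force contribution via a tiny model
        model1 = single_hex_model()
        fe1 = HexFE(model1, Material())
        u1 = rng.normal(0, 1e-4, 24)
        e1, f1, _ = element_energy_force_stiffness(model1.nodes, u1.reshape(8, 3),
                                                   Material())
        assert fe1.energy(u1) == pytest.approx(e1, rel=1e-12)
        np.testing.assert_allclose(fe1.internal_forces(u1), f1.ravel(), rtol=1e-10)


class TestSolve:
    def test_zero_load_zero_displacement(self):
        model = single_hex_model()
        res = solve_static(model, Material(),
                           BoundaryConditions(fixed_nodes=np.array([0, 3, 4, 7])))
        assert res.converged
        assert res.iterations <= 1
        assert res.max_displacement == 0.0

    def test_uniaxial_traction_small_strain_matches_linear_elasticity(self):
        model = single_hex_model(h=0.02)
        E, strain = 5000.0, 0.001
        F_total = E * strain * 0.02 ** 2
        bcs = BoundaryConditions(
            prescribed={0: [0., 0., 0.], 3: [0., NAN, 0.],
                        4: [0., 0., NAN], 7: [0., NAN, NAN]},
            loads={i: [F_total / 4, 0, 0] for i in (1, 2, 5, 6)})
        res = solve_static(model, Material(E, 0.48), bcs)
        assert res.converged
        tip = res.displacements[[1, 2, 5, 6], 0].mean()
        assert tip / 0.02 == pytest.approx(strain, rel=0.01)

    def test_young_modulus_invariance_under_pure_displacement_constraints(self):
        model = single_hex_model()
        bcs = BoundaryConditions(fixed_nodes=np.array([0, 3, 4, 7]),
                                 prescribed={6: [0.004, 0.002, -0.001]})
        r1 = solve_static(model, Material(5000.0, 0.48), bcs)
        r2 = solve_static(model, Material(10000.0, 0.48), bcs)
        assert r1.converged and r2.converged
        np.testing.assert_allclose(r1.displacements, r2.displacements, atol=1e-10)

    def test_translation_invariance(self, rng):
        m0 = single_hex_model()
        shifted = HexModel(grid=m0.grid, nodes=m0.nodes + np.array([0.3, -0.2, 0.1]),
                           hexes=m0.hexes, kept_cells=m0.kept_cells,
                           surface_nodes=m0.surface_nodes,
                           node_to_voxel=m0.node_to_voxel, surface_faces=None)
        bcs = BoundaryConditions(fixed_nodes=np.array([0, 3, 4, 7]),
                                 loads={6: [0.05, 0.02, 0.01]})
        r0 = solve_static(m0, Material(), bcs)
        r1 = solve_static(shifted, Material(), bcs)
        np.testing.assert_allclose(r0.displacements, r1.displacements, atol=1e-9)

    def test_underconstrained_rejected(self):
        model = single_hex_model()
        with pytest.raises(ValueError, match="underconstrained"):
            solve_static(model, Material(),
                         BoundaryConditions(loads={6: [0.1, 0, 0]}))

    def test_overlapping_bc_sets_rejected(self):
        model = single_hex_model()
        with pytest.raises(ValueError, match="disjoint"):
            solve_static(model, Material(),
                         BoundaryConditions(fixed_nodes=np.array([0]),
                                            loads={0: [1, 0, 0]}))

    def test_global_tangent_symmetric(self, hex_model, rng):
        fe = HexFE(hex_model, Material())
        u = rng.normal(0, 1e-4, fe.n_dof)
        K = fe.tangent(u)
        diff = (K - K.T)
        assert abs(diff).max() < 1e-8 * abs(K).max()

    def test_potential_energy_does_not_increase(self, hex_model):
        fe = HexFE(hex_model, Material())
        surf = hex_model.surface_nodes
        att = surf[:len(surf) // 4]
        loaded = [int(n) for n in surf[-5:]]
        bcs = BoundaryConditions(fixed_nodes=att,
                                 loads={n: [0.05, 0.0, 0.1] for n in loaded})
        res = fe.solve(bcs, SolveOptions(n_steps=2))
        assert res.converged
        f_ext = fe._external(bcs)
        u = res.displacements.ravel()
        assert fe.energy(u) - f_ext @ u <= 0.0 + 1e-12  # rest state has potential 0

    def test_small_strain_limit_matches_linear_fe(self, hex_model):
        from scipy.sparse.linalg import spsolve
        fe = HexFE(hex_model, Material())
        surf = hex_model.surface_nodes
        att = surf[:len(surf) // 3]
        loaded = [int(n) for n in surf[-4:]]
        # tiny loads -> < 0.5% strain
        bcs = BoundaryConditions(fixed_nodes=att,
                                 loads={n: [0.002, 0.001, 0.003] for n in loaded})
        res = fe.solve(bcs, SolveOptions(n_steps=1))
        assert res.converged
        # independent linear-elastic oracle: one solve with the tangent at rest
        fixed, _ = fe._dirichlet(bcs)
        free = ~fixed
        K0 = fe.tangent(np.zeros(fe.n_dof)).tocsc()
        f = fe._external(bcs)
        u_lin = np.zeros(fe.n_dof)
        u_lin[free] = spsolve(K0[free][:, free], f[free])
        nl = res.displacements.ravel()
        denom = np.linalg.norm(u_lin)
        assert np.linalg.norm(nl - u_lin) / denom < 0.02


class TestRegister:
    def test_rest_targets_give_zero_displacement(self, hex_model):
        surf = hex_model.surface_nodes
        att = surf[:30]
        controls = {int(n): np.zeros(3) for n in surf[50:70]}
        res = register(hex_model, Material(), att, controls)
        assert res.converged
        assert res.max_displacement == pytest.approx(0.0, abs=1e-12)

    def test_control_inside_attachments_rejected(self, hex_model):
        surf = hex_model.surface_nodes
        att = surf[:30]
        with pytest.raises(ValueError, match="attachment"):
            register(hex_model, Material(), att, {int(att[0]): np.zeros(3)})

    def test_prescribed_nodes_reach_targets(self, hex_model):
        surf = hex_model.surface_nodes
        att = surf[:len(surf) // 3]
        tgt_nodes = [int(n) for n in surf[-8:]]
        h = hex_model.grid.spacing
        targets = {n: np.array([0.2 * h, -0.1 * h, 0.3 * h]) for n in tgt_nodes}
        res = register(hex_model, Material(), att, targets)
        assert res.converged
        for n, t in targets.items():
            np.testing.assert_allclose(res.displacements[n], t, atol=1e-10)
        np.testing.assert_allclose(res.displacements[att], 0.0, atol=1e-14)
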