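"""Explicit growth solver: assembly oracles, loads, contact, integration."""

import numpy as np
import pytest

from cardiogrowth.constitutive import GrowthParams, MaterialParams
from cardiogrowth.geometry import box_mesh, build_pericardium, element_volumes
from cardiogrowth.solver import (
    BoundaryConditions,
    SolverSettings,
    apply_pressure_load,
    assemble_internal_forces,
    contact_penalty,
    run_growth_simulation,
)

from conftest import random_states


@pytest.fixture(scope="module")
def one_element(request):
    mesh = box_mesh(1, 1, 1)
    return mesh


class TestInternalForces:
    def test_zero_at_reference(self, one_element, uniform_fibers, material):
        ff = uniform_fibers(1)
        u = np.zeros((8, 3))
        f, e, bad = assemble_internal_forces(one_element, ff, material, u, GrowthParams(0, 0))
        assert bad == -1
        assert np.abs(f).max() < 1e-12
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_energy_gradient_oracle_single_element(self, one_element, uniform_fibers, material):
        """Nodal forces equal central finite differences of the assembled
        strain energy for random inhomogeneous displacements."""
        rng = np.random.default_rng(5)
        ff = uniform_fibers(1)
        g = GrowthParams(0.25, 0.1)
        u0 = 0.05 * rng.standard_normal((8, 3))
        f, _, _ = assemble_internal_forces(one_element, ff, material, u0, g)
        h = 1e-6
        f_fd = np.zeros_like(u0)
        for a in range(8):
            for i in range(3):
                up, um = u0.copy(), u0.copy()
                up[a, i] += h
                um[a, i] -= h
                _, ep, _ = assemble_internal_forces(one_element, ff, material, up, g)
                _, em, _ = assemble_internal_forces(one_element, ff, material, um, g)
                f_fd[a, i] = (ep - em) / (2 * h)
        assert np.abs(f - f_fd).max() < 1e-5 * max(1.0, np.abs(f).max())

    def test_homogeneous_deformation_matches_reference_constitutive(self, one_element, uniform_fibers, material):
        """For a homogeneous F the kernel's strain energy equals the numpy
        constitutive module exactly (mean dilatation is exact there)."""
        from cardiogrowth.constitutive import DeformationState, reference_energy

        rng = np.random.default_rng(8)
        F, _, _ = random_states(1, rng)
        F = F[0]
        g = GrowthParams(0.3, 0.2)
        u = one_element.nodes @ (F - np.eye(3)).T
        ff = uniform_fibers(1)
        _, e_kernel, _ = assemble_internal_forces(one_element, ff, material, u, g)
        st = DeformationState.make(F, g, ff.f[0], ff.s[0])
        e_ref = float(reference_energy(st, material))  # per unit volume, V=1
        offset = np.linalg.det(st.Fg) * material.a / (2 * material.b)
        assert e_kernel == pytest.approx(e_ref - offset, rel=1e-10)

    def test_translation_invariance(self, one_element, uniform_fibers, material):
        rng = np.random.default_rng(6)
        ff = uniform_fibers(1)
        u = 0.05 * rng.standard_normal((8, 3))
        f1, e1, _ = assemble_internal_forces(one_element, ff, material, u, GrowthParams(0.1, 0.2))
        f2, e2, _ = assemble_internal_forces(one_element, ff, material, u + [1.0, -2.0, 0.5], GrowthParams(0.1, 0.2))
        np.testing.assert_allclose(f1, f2, atol=1e-10)
        assert e1 == pytest.approx(e2)

    def test_inverted_element_reported(self, one_element, uniform_fibers, material):
        u = np.zeros((8, 3))
        u[one_element.nodes[:, 2] == 0.0, 2] = 2.0  # fold bottom face above top
        _, _, bad = assemble_internal_forces(one_element, uniform_fibers(1), material, u, GrowthParams(0, 0))
        assert bad == 0


class TestPressureLoad:
    def test_closed_surface_equilibrium(self, hemisphere_mesh):
        """Uniform pressure on a closed surface exerts no net force."""
        quads = np.vstack(
            [hemisphere_mesh.surface_sets["endo"], hemisphere_mesh.surface_sets["epi"], hemisphere_mesh.surface_sets["base"]]
        )
        from cardiogrowth.geometry import surface_area

        p = 2.0
        f = apply_pressure_load(hemisphere_mesh.nodes, quads, p)
        area = surface_area(hemisphere_mesh.nodes, quads)
        assert np.abs(f.sum(axis=0)).max() < 1e-8 * p * area

    def test_flat_facet_carries_p_times_area(self):
        nodes = np.array([[0.0, 0, 0], [2, 0, 0], [2, 3, 0], [0, 3, 0]])
        quad = np.array([[0, 1, 2, 3]])
        f = apply_pressure_load(nodes, quad, 1.5)
        # outward normal +z; the applied traction is -p n
        np.testing.assert_allclose(f.sum(axis=0), [0, 0, -1.5 * 6.0], atol=1e-12)

    def test_zero_pressure(self, hemisphere_mesh):
        f = apply_pressure_load(hemisphere_mesh.nodes, hemisphere_mesh.surface_sets["endo"], 0.0)
        assert np.abs(f).max() == 0.0


class TestContact:
    def _flat_shell(self):
        sh_nodes = np.array([[-2.0, -2, 0], [2, -2, 0], [2, 2, 0], [-2, 2, 0]])
        sh_quads = np.array([[0, 1, 2, 3]])  # normal +z (away from the LV below)
        return sh_nodes, sh_quads

    def test_separated_surfaces_inactive(self):
        sh_nodes, sh_quads = self._flat_shell()
        pts = np.array([[0.0, 0, -0.5]])  # below the shell: h < 0
        f_lv, f_sh, e = contact_penalty(pts, np.array([0]), np.array([1.0]), sh_nodes, sh_quads, 2.0)
        assert np.abs(f_lv).max() == 0 and np.abs(f_sh).max() == 0 and e == 0

    def test_single_node_penetration_pressure(self):
        """h = 0.5 mm overclosure at slope 2 gives pressure 1.0 and force
        pressure x tributary area."""
        sh_nodes, sh_quads = self._flat_shell()
        pts = np.array([[0.0, 0, 0.5]])
        trib = np.array([3.0])
        f_lv, f_sh, e = contact_penalty(pts, np.array([0]), trib, sh_nodes, sh_quads, 2.0)
        np.testing.assert_allclose(f_lv[0], [0, 0, -1.0 * 3.0], atol=1e-12)
        assert e == pytest.approx(0.5 * 2.0 * 0.5**2 * 3.0)

    def test_newtons_third_law(self, lv_mesh):
        shell = build_pericardium(lv_mesh, clearance=0.0)
        coords = lv_mesh.nodes * 1.02  # inflate the wall into the shell
        epi = lv_mesh.node_sets["epi_surface"].astype(np.int64)
        trib = np.ones(epi.size)
        f_lv, f_sh, e = contact_penalty(coords, epi, trib, shell.nodes, shell.elements, 2.0)
        assert e > 0  # contact active
        np.testing.assert_allclose(f_lv.sum(axis=0) + f_sh.sum(axis=0), 0.0, atol=1e-10)


class TestGrowthSimulation:
    def test_no_load_no_growth_stays_at_rest(self, tiny_lv_mesh, material):
        from cardiogrowth.fibers import assign_fibers

        ff = assign_fibers(tiny_lv_mesh)
        st = SolverSettings(n_increments_per_step=200)
        res = run_growth_simulation(
            tiny_lv_mesh, ff, material, None, BoundaryConditions(p_ed=0.0), st, GrowthParams(0, 0)
        )
        _, _, coords = res.checkpoints[-1]
        assert np.linalg.norm(coords - tiny_lv_mesh.nodes, axis=1).max() < 1e-6

    def test_free_isotropic_growth_volume_ratio(self, free_block, material):
        """Compatible homogeneous growth is stress-free: the final volume is
        (1 + alpha)^3 times the initial volume within 1%."""
        mesh, ff = free_block
        alpha = 0.3
        st = SolverSettings(n_increments_per_step=2000)
        res = run_growth_simulation(
            mesh, ff, material, None, BoundaryConditions(p_ed=0.0), st, GrowthParams(alpha, alpha)
        )
        assert not res.diverged
        _, _, coords = res.checkpoints[-1]
        v = element_volumes(coords, mesh.elements).sum()
        assert v / 8.0 == pytest.approx((1 + alpha) ** 3, rel=0.01)

    def test_checkpoints_report_scaled_parameters(self, free_block, material):
        mesh, ff = free_block
        st = SolverSettings(n_increments_per_step=500)
        res = run_growth_simulation(
            mesh, ff, material, None, BoundaryConditions(p_ed=0.0), st, GrowthParams(0.8, 0.4)
        )
        fracs = [g for g, _, _ in res.checkpoints]
        assert fracs == sorted(fracs) == [0.2, 0.4, 0.6, 0.8, 1.0]
        for g, eff, _ in res.checkpoints:
            assert eff.alpha_f == pytest.approx(0.8 * g)
            assert eff.alpha_n == pytest.approx(0.4 * g)

    def test_bitwise_determinism(self, tiny_lv_mesh, material):
        from cardiogrowth.fibers import assign_fibers

        ff = assign_fibers(tiny_lv_mesh)
        shell = build_pericardium(tiny_lv_mesh)
        st = SolverSettings(n_increments_per_step=300)
        bc = BoundaryConditions()
        r1 = run_growth_simulation(tiny_lv_mesh, ff, material, shell, bc, st, GrowthParams(0.4, 0.2))
        r2 = run_growth_simulation(tiny_lv_mesh, ff, material, shell, bc, st, GrowthParams(0.4, 0.2))
        assert np.array_equal(r1.checkpoints[-1][2], r2.checkpoints[-1][2])
        assert np.array_equal(r1.energy_trace, r2.energy_trace)

    def test_pseudo_time_refinement_convergence(self, lv_mesh, lv_fibers, material):
        """Halving the increment (doubling the count) moves the final
        configuration by < 0.5% of the displacement scale on the standard
        pressurized + growing LV."""
        bc = BoundaryConditions()
        out = []
        for n in (6000, 12000):
            st = SolverSettings(n_increments_per_step=n)
            r = run_growth_simulation(lv_mesh, lv_fibers, material, None, bc, st, GrowthParams(0.5, 0.2))
            out.append(r.checkpoints[-1][2])
        disp = np.linalg.norm(out[1] - lv_mesh.nodes, axis=1).max()
        diff = np.linalg.norm(out[1] - out[0], axis=1).max()
        assert diff / disp < 0.005

    def test_divergence_reported_with_time(self, free_block):
        mesh, ff = free_block
        # absurdly soft material + huge pressure on the tiny block: collapse
        mat = MaterialParams(bulk_modulus=200.0, a=0.001)
        bc = BoundaryConditions(p_ed=500.0)
        st = SolverSettings(n_increments_per_step=300)
        res = run_growth_simulation(mesh, ff, mat, None, bc, st, GrowthParams(0, 0))
        assert res.diverged
        assert res.failure_time is not None and res.failure_time > 0
        assert not res.converged
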