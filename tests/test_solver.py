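"""Electro-quasi-static solver: assembly, closed-form solutions, invariances."""

import dataclasses

import numpy as np
import pytest
import scipy.sparse.linalg as spla

import ccdosim as cd
from ccdosim.contact import BodyModelMode
from ccdosim.paths import CurrentPath
from ccdosim.solver import (
    ContactScenario, ConvergenceError, assemble_system, derive_fields,
    solve_potential,
)

from conftest import BLOCK_PATH, block_phantom, constant_materials, solve_block


class TestAssembly:
    def test_two_voxel_bar_stencil_by_hand(self):
        # off-diagonal coupling = sigma * A / d = 1 S/m * (1mm^2/1mm) * 1e-3 m
        labels = np.ones((2, 1, 1), np.uint8)
        mats = constant_materials(m1=1.0)
        phantom = block_phantom(labels, 1.0, {1: "m1"})
        scen = ContactScenario(path=BLOCK_PATH, frequency=0.0,
                               touch_voltage=1.0, mode=BodyModelMode.INTERN)
        system = assemble_system(phantom, mats, scen)
        # both voxels are electrodes here -> fully Dirichlet, empty free set
        assert system.matrix.shape == (0, 0)
        # a three-voxel bar leaves one unknown with the hand-computed diagonal
        labels = np.ones((3, 1, 1), np.uint8)
        system = assemble_system(block_phantom(labels, 1.0, {1: "m1"}),
                                 mats, scen)
        g = 1.0 * 1e-3  # sigma * (s_j*s_k/s_i) * 1e-3
        assert system.matrix.shape == (1, 1)
        assert system.matrix[0, 0] == pytest.approx(2 * g)
        assert system.rhs[0] == pytest.approx(g * 1.0)  # source at 1 V

    def test_harmonic_mean_face_conductance(self):
        # face between sigma=1 and sigma=3 voxels uses 2*1*3/(1+3) = 1.5
        from ccdosim.solver import _face_conductance

        sig = np.array([1.0, 3.0]).reshape(2, 1, 1)
        g = _face_conductance(sig, 0, np.array([1.0, 1.0, 1.0]))
        assert g[0, 0, 0] == pytest.approx(1.5 * 1e-3)

    def test_faces_to_air_carry_no_flux(self):
        from ccdosim.solver import _face_conductance

        sig = np.array([1.0, 0.0]).reshape(2, 1, 1)
        g = _face_conductance(sig, 0, np.array([1.0, 1.0, 1.0]))
        assert g[0, 0, 0] == 0.0

    def test_dc_system_real_symmetric(self):
        labels = np.ones((6, 3, 3), np.uint8)
        labels[3, 1, 1] = 2
        mats = constant_materials(m1=0.5, m2=0.1)
        phantom = block_phantom(labels, 2.0, {1: "m1", 2: "m2"})
        scen = ContactScenario(path=BLOCK_PATH, frequency=0.0,
                               touch_voltage=1.0, mode=BodyModelMode.INTERN)
        system = assemble_system(phantom, mats, scen)
        A = system.matrix
        assert not np.iscomplexobj(A.data)
        assert abs(A - A.T).max() == 0.0

    def test_missing_electrode_rejected(self):
        labels = np.ones((4, 2, 2), np.uint8)
        phantom = block_phantom(labels, 1.0, {1: "m1"})
        phantom = dataclasses.replace(phantom, electrodes={})
        scen = ContactScenario(path=BLOCK_PATH, frequency=0.0,
                               touch_voltage=1.0, mode=BodyModelMode.INTERN)
        with pytest.raises(ValueError, match="not placed"):
            assemble_system(phantom, constant_materials(m1=1.0), scen)

    def test_unmaterialized_label_rejected(self):
        labels = np.ones((4, 2, 2), np.uint8)
        labels[2] = 9
        phantom = block_phantom(labels, 1.0, {1: "m1", 9: "mystery"})
        scen = ContactScenario(path=BLOCK_PATH, frequency=0.0,
                               touch_voltage=1.0, mode=BodyModelMode.INTERN)
        with pytest.raises(KeyError, match="mystery"):
            assemble_system(phantom, constant_materials(m1=1.0), scen)


class TestPotentialSolutions:
    def test_homogeneous_bar_gives_affine_profile(self, bar_solution):
        sol, system, _ = bar_solution
        phi = sol.potential.real
        nx = phi.shape[0]
        expected = 1.0 - np.arange(nx) / (nx - 1)
        profile = phi[:, 2, 2]
        assert np.max(np.abs(profile - expected)) < 1e-8

    def test_orientation_invariance(self):
        # the same bar solved along x and along z yields the same profile
        mats = constant_materials(m1=0.5)
        labels = np.ones((9, 4, 4), np.uint8)
        sol_x, _ = solve_block(labels, 2.0, mats, {1: "m1"})
        labels_z = np.ones((4, 4, 9), np.uint8)
        phantom = block_phantom(labels_z, 2.0, {1: "m1"})
        vox = np.argwhere(labels_z != 0)
        src = vox[vox[:, 2] == 0]
        snk = vox[vox[:, 2] == 8]
        from ccdosim.phantom import ElectrodePlacement

        phantom = dataclasses.replace(phantom, electrodes={
            "SRC": ElectrodePlacement("SRC", BodyModelMode.INTERN, 1.0, src, src),
            "SNK": ElectrodePlacement("SNK", BodyModelMode.INTERN, 1.0, snk, snk)})
        scen = ContactScenario(path=BLOCK_PATH, frequency=0.0,
                               touch_voltage=1.0, mode=BodyModelMode.INTERN)
        sol_z = solve_potential(assemble_system(phantom, mats, scen))
        assert np.allclose(sol_x.potential[:, 1, 1],
                           sol_z.potential[1, 1, :], atol=1e-9)

    def test_two_layer_bar_interface_voltage_divider(self):
        # series slabs: potential at the last sigma1 voxel follows the divider
        mats = constant_materials(m1=1.0, m2=0.25)
        labels = np.ones((13, 4, 4), np.uint8)
        labels[6:] = 2
        sol, _ = solve_block(labels, 2.0, mats, {1: "m1", 2: "m2"})
        s, A = 2e-3, (8e-3) ** 2
        r_total = s / A * (5.5 / 1.0 + 6.5 / 0.25)
        current = 1.0 / r_total
        expected = 1.0 - current * (5 * s) / (1.0 * A)
        assert sol.potential[5, 1, 1].real == pytest.approx(expected, rel=1e-10)

    def test_linearity_in_touch_voltage(self, bar_solution):
        sol1, _, mats = bar_solution
        labels = np.ones((11, 5, 5), np.uint8)
        sol2, _ = solve_block(labels, 2.0, mats, {1: "m1"}, voltage=2.0)
        body = labels != 0
        assert np.allclose(sol2.potential[body], 2.0 * sol1.potential[body],
                           rtol=1e-10, atol=1e-12)

    def test_sparse_solution_matches_dense_oracle(self):
        # heterogeneous block <= 20^3: sparse solve vs numpy dense solve
        rng = np.random.default_rng(7)
        labels = np.ones((10, 9, 8), np.uint8)
        labels[rng.random((10, 9, 8)) < 0.3] = 2
        labels[0] = 1
        labels[-1] = 1
        mats = constant_materials(m1=0.4, m2=0.05)
        sol, system = solve_block(labels, 2.0, mats, {1: "m1", 2: "m2"},
                                  method="direct", with_fields=False)
        dense = np.linalg.solve(system.matrix.toarray(), system.rhs)
        sparse = sol.potential.reshape(-1)[system.free_flat]
        assert np.max(np.abs(sparse - dense)) < 1e-8

    def test_iterative_matches_direct(self):
        labels = np.ones((15, 6, 6), np.uint8)
        labels[7:, :, :3] = 2
        mats = constant_materials(m1=0.3, m2=0.02)
        sol_d, _ = solve_block(labels, 2.0, mats, {1: "m1", 2: "m2"},
                               method="direct")
        sol_i, _ = solve_block(labels, 2.0, mats, {1: "m1", 2: "m2"},
                               method="iterative", tolerance=1e-12)
        body = labels != 0
        assert np.allclose(sol_i.potential[body], sol_d.potential[body],
                           rtol=1e-8, atol=1e-12)

    def test_dc_complex_input_equals_real_arithmetic(self):
        # a complex-dtype zero-imag system reproduces the real fast path
        labels = np.ones((9, 4, 4), np.uint8)
        mats = constant_materials(m1=0.5)
        sol_r, system = solve_block(labels, 2.0, mats, {1: "m1"})
        xc = spla.spsolve(system.matrix.astype(complex).tocsc(),
                          system.rhs.astype(complex))
        xr = sol_r.potential.reshape(-1)[system.free_flat]
        assert np.allclose(xc, xr, rtol=1e-12)

    def test_nonconvergence_raises_with_diagnostics(self):
        labels = np.ones((20, 6, 6), np.uint8)
        mats = constant_materials(m1=0.5)
        phantom = block_phantom(labels, 2.0, {1: "m1"})
        scen = ContactScenario(path=BLOCK_PATH, frequency=0.0,
                               touch_voltage=1.0, mode=BodyModelMode.INTERN)
        system = assemble_system(phantom, mats, scen)
        with pytest.raises(ConvergenceError):
            solve_potential(system, tolerance=1e-14, max_iter=2,
                            method="iterative")

    def test_reciprocity_source_sink_swap(self, tiny_phantom, materials):
        fwd = cd.expand_paths(["LH-RH"])[0]
        rev = CurrentPath("RH-LH", fwd.sink_sites, fwd.source_sites)
        mags = []
        for path in (fwd, rev):
            scen = ContactScenario(path=path, frequency=0.0,
                                   touch_voltage=100.0,
                                   mode=BodyModelMode.INTERN)
            sol = cd.solve_scenario(tiny_phantom, materials, scen,
                                    method="direct")
            rep = cd.evaluate_solution(sol)
            mags.append(abs(rep.z_total))
        assert abs(mags[0] - mags[1]) / mags[0] < 1e-8


class TestDerivedFields:
    def test_uniform_field_from_linear_potential(self, bar_solution):
        sol, _, _ = bar_solution
        interior = np.zeros(sol.potential.shape, bool)
        interior[1:-1, 1:-1, 1:-1] = True
        k = 1.0 / (10 * 2e-3)  # U / L in V/m
        Ex = sol.e_field[..., 0]
        assert np.allclose(Ex[interior].real, k, rtol=1e-8)
        assert np.allclose(sol.e_field[interior][:, 1:], 0.0, atol=1e-8 * k)

    def test_interface_conditions_on_two_layer_bar(self):
        # normal J continuous, E jumps by the conductivity ratio
        mats = constant_materials(m1=1.0, m2=0.25)
        labels = np.ones((13, 5, 5), np.uint8)
        labels[6:] = 2
        sol, _ = solve_block(labels, 2.0, mats, {1: "m1", 2: "m2"})
        Jx = sol.j_field[..., 0]
        Ex = sol.e_field[..., 0]
        # away from the interface the central differences are exact
        j1 = Jx[2, 2, 2].real
        j2 = Jx[10, 2, 2].real
        assert j2 == pytest.approx(j1, rel=1e-9)
        assert Ex[10, 2, 2].real == pytest.approx(Ex[2, 2, 2].real * 4.0,
                                                  rel=1e-9)

    def test_discrete_divergence_vanishes_in_uniform_bar(self, bar_solution):
        sol, _, _ = bar_solution
        J = sol.j_field.real
        div = np.zeros(J.shape[:3])
        h = 2e-3
        div[1:-1, :, :] += (J[2:, :, :, 0] - J[:-2, :, :, 0]) / (2 * h)
        div[:, 1:-1, :] += (J[:, 2:, :, 1] - J[:, :-2, :, 1]) / (2 * h)
        div[:, :, 1:-1] += (J[:, :, 2:, 2] - J[:, :, :-2, 2]) / (2 * h)
        inner = np.zeros(div.shape, bool)
        inner[2:-2, 2:-2, 2:-2] = True
        assert np.max(np.abs(div[inner])) < 1e-6 * np.abs(J[..., 0]).mean()


class TestScenarioValidation:
    def test_case_by_case_mode_rejected(self):
        with pytest.raises(ValueError, match="CASE_BY_CASE"):
            ContactScenario(path=BLOCK_PATH, frequency=5e3, touch_voltage=100.0,
                            mode=BodyModelMode.CASE_BY_CASE)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            ContactScenario(path=BLOCK_PATH, frequency=-1.0,
                            touch_voltage=100.0, mode=BodyModelMode.INTERN)
        with pytest.raises(ValueError):
            ContactScenario(path=BLOCK_PATH, frequency=50.0, touch_voltage=0.0,
                            mode=BodyModelMode.INTERN)
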