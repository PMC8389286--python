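"""Volume-conductor solver: assembly identities, boundary conditions,
conservation, symmetry and mesh convergence."""
import numpy as np
import pytest

from ocufield.fem import (MontageError, assemble_system,
                          compute_element_fields, solve_unit_channel)
from ocufield.meshing import VolumeMesh, generate_homogeneous_box
from ocufield.tissues import ConductivityTable

UNIT = ConductivityTable({"medium": 1.0})


def one_tet_mesh():
    nodes = np.array([[0.0, 0, 0], [10.0, 0, 0], [0, 10.0, 0], [0, 0, 10.0]])
    return VolumeMesh(nodes=nodes, tets=np.array([[0, 1, 2, 3]], dtype=np.int32),
                      tet_labels=np.zeros(1, dtype=np.int16),
                      label_names={0: "medium"})


class TestAssembly:
    def test_single_tet_stiffness_has_zero_row_sums(self):
        system = assemble_system(one_tet_mesh(), UNIT)
        K = system.stiffness.toarray()
        assert K.shape == (4, 4)
        assert np.abs(K.sum(axis=1)).max() < 1e-15 * np.abs(K).max()
        assert np.allclose(K, K.T)

    def test_operator_linear_in_sigma(self, small_box):
        mesh, _ = small_box
        k1 = assemble_system(mesh, ConductivityTable({"medium": 1.0})).stiffness
        k3 = assemble_system(mesh, ConductivityTable({"medium": 3.0})).stiffness
        assert abs(k3 - 3.0 * k1).max() < 1e-12 * abs(k1).max()

    def test_dirichlet_energy_of_linear_potential(self):
        # phi = x (metres): integral of sigma |grad phi|^2 = sigma * volume
        mesh = generate_homogeneous_box(100.0, 1.0, 20.0)
        system = assemble_system(mesh, UNIT)
        phi = mesh.nodes[:, 0] * 1e-3
        energy = phi @ (system.stiffness @ phi)
        assert energy == pytest.approx(1.0 * 0.1 ** 3, rel=1e-10)

    def test_missing_label_raises(self, small_box):
        mesh, _ = small_box
        with pytest.raises(KeyError):
            assemble_system(mesh, ConductivityTable({"other": 1.0}))


class TestElementFields:
    def test_constant_potential_gives_zero_field(self, small_box):
        mesh, _ = small_box
        E = compute_element_fields(np.full(mesh.n_nodes, 3.7), mesh)
        assert np.abs(E).max() < 1e-12

    def test_linear_potential_exact_on_every_element(self, small_box):
        # phi equal to the x coordinate in mm -> E = (-1000, 0, 0) V/m
        mesh, _ = small_box
        E = compute_element_fields(mesh.nodes[:, 0].astype(float), mesh)
        assert np.allclose(E[:, 0], -1000.0, rtol=1e-9)
        assert np.abs(E[:, 1:]).max() < 1e-6

    def test_field_linear_in_potential(self, small_box, rng):
        mesh, _ = small_box
        phi = rng.normal(size=mesh.n_nodes)
        E1 = compute_element_fields(phi, mesh)
        E2 = compute_element_fields(2.0 * phi, mesh)
        assert np.allclose(E2, 2.0 * E1, rtol=1e-12)


class TestUnitChannelSolve:
    def test_calibrated_to_one_milliamp(self, small_box):
        mesh, table = small_box
        sol = solve_unit_channel(mesh, table, "x_min", "x_max")
        assert sol.delivered_current == pytest.approx(1.0, rel=1e-9)
        reac = (assemble_system(mesh, table).stiffness @ sol.phi)
        assert reac[sol.anode_nodes].sum() == pytest.approx(1e-3, rel=1e-6)

    def test_anode_cathode_flux_agreement(self, small_box):
        mesh, table = small_box
        sol = solve_unit_channel(mesh, table, "x_min", "x_max")
        assert sol.diagnostics["flux_asymmetry_rel"] < 1e-6

    def test_face_flux_diagnostic_close_to_reaction_flux(self, small_box):
        mesh, table = small_box
        sol = solve_unit_channel(mesh, table, "x_min", "x_max")
        # first-order surface integration; on the uniform box it is exact
        assert sol.diagnostics["face_flux_anode_mA"] == pytest.approx(
            1.0, rel=1e-6)

    def test_discrete_maximum_principle(self, small_box):
        # homogeneous medium, well-shaped mesh: extrema on the electrodes
        mesh, table = small_box
        sol = solve_unit_channel(mesh, table, "x_min", "x_max")
        electrodes = np.concatenate([sol.anode_nodes, sol.cathode_nodes])
        interior = np.setdiff1d(np.arange(mesh.n_nodes), electrodes)
        assert sol.phi[interior].max() <= sol.phi[electrodes].max() + 1e-12
        assert sol.phi[interior].min() >= sol.phi[electrodes].min() - 1e-12

    def test_antisymmetry_on_mirror_symmetric_mesh(self):
        # antipodal congruent electrodes on an exactly x-mirror-symmetric
        # tessellation: phi(x) = -phi(mirror(x)) to solver tolerance
        mesh = generate_homogeneous_box(80.0, 1.0, 10.0, mirror_x=True)
        sol = solve_unit_channel(mesh, UNIT, "x_min", "x_max")
        lookup = {tuple(np.round(p, 9)): i for i, p in enumerate(mesh.nodes)}
        mirror = np.array([lookup[tuple(np.round(p * [-1, 1, 1], 9))]
                           for p in mesh.nodes])
        resid = np.abs(sol.phi + sol.phi[mirror]).max()
        assert resid <= 1e-6 * np.abs(sol.phi).max()

    def test_empty_patch_rejected(self, small_box):
        mesh, table = small_box
        with pytest.raises(MontageError):
            solve_unit_channel(mesh, table, np.array([], dtype=int), "x_max")

    def test_overlapping_patches_rejected(self, small_box):
        mesh, table = small_box
        with pytest.raises(MontageError):
            solve_unit_channel(mesh, table, "x_min", "x_min")


class TestMeshConvergence:
    def test_probe_potentials_change_under_2pct_on_refinement(self):
        # fixed square electrode regions on opposite faces (half-width a
        # common multiple of both spacings so the discrete electrodes
        # coincide), probes at nodes shared by both grids
        def solve(h):
            mesh = generate_homogeneous_box(160.0, 1.0, h)
            nodes = mesh.nodes
            def face_patch(sign):
                on_face = np.abs(nodes[:, 0] - sign * 80.0) < 1e-9
                inside = (np.abs(nodes[:, 1]) <= 32 + 1e-9) & \
                         (np.abs(nodes[:, 2]) <= 32 + 1e-9)
                return np.flatnonzero(on_face & inside)
            sol = solve_unit_channel(mesh, UNIT, face_patch(-1), face_patch(+1))
            lookup = {tuple(np.round(p, 6)): i for i, p in enumerate(nodes)}
            probes = [(0, 0, 0), (16, 16, 0), (32, 0, 16), (0, 48, 0),
                      (-32, 0, 0)]
            return np.array([sol.phi[lookup[p]] for p in probes])

        coarse, fine = solve(8.0), solve(4.0)
        rel = np.abs(fine - coarse) / np.abs(fine).max()
        assert rel.max() < 0.02
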