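"""Periodic cell problems and effective tensors."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from cytodiffuse.accessibility import BlockedGeometry, inaccessible_region, slice_cross_sections
from cytodiffuse.homogenization import (
    effective_tensor,
    fractional_anisotropy,
    hill_mandel_residual,
    homogenize_blocked_geometry,
    mesh_sampling_domain,
    solve_cell_problems,
)
from cytodiffuse.network import NetworkSpec, generate_network


def empty_geometry(edge=1.0):
    return BlockedGeometry(0.0, 0.0, [], Polygon(), 0.0, edge)


def circular_hole_geometry(phi=0.05, edge=1.0):
    r = np.sqrt(phi / np.pi) * edge
    hole = Point(edge / 2, edge / 2).buffer(r, quad_segs=128)
    return BlockedGeometry(0.0, 0.0, [], hole, phi, edge)


@pytest.fixture(scope="module")
def cortical_blocked():
    net = generate_network(NetworkSpec(1430, seed=1))
    return inaccessible_region(slice_cross_sections(net, 0.5), 0.010, 1.0, 0.5)


class TestCellProblems:
    def test_empty_domain_correctors_vanish(self):
        mesh = mesh_sampling_domain(empty_geometry(), 1 / 32, D_micro=3.0)
        sol = solve_cell_problems(mesh)
        assert np.abs(sol.chi).max() < 1e-10
        et = effective_tensor(mesh, sol)
        assert np.allclose(et.D0, 3.0 * np.eye(2), atol=1e-10)

    def test_laminate_closed_form(self):
        # piecewise coefficient in x only: χ² ≡ 0, D0 = diag(harmonic, arithmetic)
        mesh = mesh_sampling_domain(empty_geometry(), 1 / 64, D_micro=1.0)
        cen = mesh.nodes[mesh.triangles].mean(axis=1)
        mesh.D_elem = np.where(cen[:, 0] < 0.5, 1.0, 10.0)
        sol = solve_cell_problems(mesh)
        assert np.abs(sol.chi[1]).max() < 1e-10
        et = effective_tensor(mesh, sol, normalizer="cell")
        assert et.D0[0, 0] == pytest.approx(20 / 11, rel=1e-9)
        assert et.D0[1, 1] == pytest.approx(5.5, rel=1e-9)
        assert abs(et.D0[0, 1]) < 1e-10

    def test_zero_mean_constraint(self, cortical_blocked):
        mesh = mesh_sampling_domain(cortical_blocked, 1 / 96)
        sol = solve_cell_problems(mesh)
        # area-weighted mean over the free domain
        from cytodiffuse.homogenization import _assemble

        _, _, area, _, dofs = _assemble(mesh)
        w = np.zeros(mesh.n_dofs)
        np.add.at(w, dofs.ravel(), np.repeat(area / 3.0, 3))
        for j in range(2):
            assert abs((sol.chi[j] * w).sum() / w.sum()) < 1e-10

    def test_periodicity_via_dof_identification(self, cortical_blocked):
        mesh = mesh_sampling_domain(cortical_blocked, 1 / 64)
        pairs = mesh.periodic_pairs()
        d = mesh.dof_of_node
        assert np.all(d[pairs[:, 0]] == d[pairs[:, 1]])


class TestEffectiveTensor:
    def test_dilute_circular_hole_maxwell_garnett(self):
        bg = circular_hole_geometry(0.05)
        et = homogenize_blocked_geometry(bg, 1 / 256, 1.0, normalizer="cell")
        mg = (1 - 0.05) / (1 + 0.05)
        assert et.D0[0, 0] == pytest.approx(mg, abs=0.004)
        # circular symmetry: isotropic
        assert et.D0[0, 0] == pytest.approx(et.D0[1, 1], rel=1e-3)
        assert et.FA < 2e-3

    def test_free_normalizer_is_cell_over_porosity(self):
        bg = circular_hole_geometry(0.05)
        mesh = mesh_sampling_domain(bg, 1 / 128)
        sol = solve_cell_problems(mesh)
        cell = effective_tensor(mesh, sol, normalizer="cell")
        free = effective_tensor(mesh, sol, normalizer="free")
        porosity = mesh.n_elements * mesh.element_area
        assert np.allclose(free.D0 * porosity, cell.D0, rtol=1e-12)

    def test_symmetry_and_voigt_bound(self, cortical_blocked):
        et = homogenize_blocked_geometry(cortical_blocked, 1 / 128, 32.8)
        assert np.allclose(et.D0, et.D0.T, rtol=1e-10)
        lam1, lam2 = et.eigenvalues
        assert lam1 >= lam2 >= -1e-10
        assert lam1 <= 32.8 * (1 + 1e-8)

    def test_trace_decreases_with_density(self):
        traces, phis = [], []
        for mult in (0.3, 1.0, 2.2):
            net = generate_network(NetworkSpec(1430 * mult, seed=8))
            bg = inaccessible_region(slice_cross_sections(net, 0.5), 0.010)
            et = homogenize_blocked_geometry(bg, 1 / 128, 1.0)
            traces.append(et.trace_mean)
            phis.append(bg.phi)
        assert phis[0] < phis[1] < phis[2]
        assert traces[0] > traces[1] > traces[2]

    def test_mesh_convergence_smooth_fixture(self):
        bg = circular_hole_geometry(0.1)
        coarse = homogenize_blocked_geometry(bg, 1 / 96, 1.0)
        fine = homogenize_blocked_geometry(bg, 1 / 192, 1.0)
        assert fine.trace_mean == pytest.approx(coarse.trace_mean, rel=5e-3)

    def test_two_phase_formulation_close_to_perforated(self):
        bg = circular_hole_geometry(0.08)
        perf = homogenize_blocked_geometry(bg, 1 / 128, 1.0)
        soft = homogenize_blocked_geometry(bg, 1 / 128, 1.0, formulation="two_phase")
        assert soft.trace_mean == pytest.approx(perf.trace_mean, rel=0.01)

    def test_enclosed_pocket_carries_no_flux(self):
        ring = Point(0.5, 0.5).buffer(0.45).difference(Point(0.5, 0.5).buffer(0.35))
        bg = BlockedGeometry(0.0, 0.0, [], ring, float(ring.area), 1.0)
        mesh = mesh_sampling_domain(bg, 1 / 64)
        assert not mesh.trapped  # the outside of the ring still percolates
        # the enclosed disk is equilibrated: only the outside conducts
        et = homogenize_blocked_geometry(bg, 1 / 64, 1.0, normalizer="cell")
        assert et.trace_mean < 0.35

    def test_spanning_cross_traps_domain(self):
        from shapely.geometry import box as shapely_box
        from shapely.ops import unary_union

        cross = unary_union([
            shapely_box(0.45, -0.01, 0.55, 1.01),
            shapely_box(-0.01, 0.45, 1.01, 0.55),
        ])
        bg = BlockedGeometry(0.0, 0.0, [], cross, float(cross.area), 1.0)
        mesh = mesh_sampling_domain(bg, 1 / 64)
        assert mesh.trapped and mesh.percolates == (False, False)


class TestFractionalAnisotropy:
    @pytest.mark.parametrize(
        "tensor, expected",
        [
            (np.eye(2), 0.0),
            (np.diag([1.0, 0.0]), 1.0),
            (np.diag([2.0, 1.0]), 1.0 / np.sqrt(5.0)),
        ],
    )
    def test_closed_form_values(self, tensor, expected):
        assert fractional_anisotropy(tensor) == pytest.approx(expected, abs=1e-12)

    def test_zero_tensor_flagged(self):
        assert np.isnan(fractional_anisotropy(np.zeros((2, 2))))

    def test_asymmetric_input_raises(self):
        with pytest.raises(ValueError):
            fractional_anisotropy(np.array([[1.0, 0.5], [0.0, 1.0]]))


class TestHillMandel:
    def test_empty_domain_zero(self):
        mesh = mesh_sampling_domain(empty_geometry(), 1 / 32, D_micro=2.0)
        sol = solve_cell_problems(mesh)
        assert hill_mandel_residual(mesh, sol, [1.0, 0.0]) < 1e-12

    @pytest.mark.parametrize("h_inv", [64, 128])
    def test_realistic_domain_machine_zero(self, cortical_blocked, h_inv):
        mesh = mesh_sampling_domain(cortical_blocked, 1.0 / h_inv)
        sol = solve_cell_problems(mesh)
        for g in ([1.0, 0.0], [0.3, -0.7]):
            assert hill_mandel_residual(mesh, sol, g) < 1e-6
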