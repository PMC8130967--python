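"""Whole-cell homogenized transport."""

import numpy as np
import pytest
from scipy.special import j0, j1, jn_zeros
from shapely.geometry import Point

from cytodiffuse.density import synth_cell_map
from cytodiffuse.effective_law import PowerLawParams
from cytodiffuse.homogenization import mesh_sampling_domain, solve_cell_problems
from cytodiffuse.accessibility import BlockedGeometry
from shapely.geometry import Polygon
from cytodiffuse.transport import (
    ConcentrationSeries,
    DensityPhiLookup,
    TransportProblem,
    build_phi_field,
    local_correction,
    mesh_cell_polygon,
    solve_transport,
    time_to_threshold,
)


def disk_mesh(radius=8.0, h=0.4, D=32.8):
    mesh = mesh_cell_polygon(Point(radius, radius).buffer(radius, quad_segs=64), h)
    mesh.D_elem = np.full(mesh.n_elements, D)
    return mesh


def disk_uptake_series(r_over_a, t, D, a, n_terms=60):
    """u(r, t) for u=1 on the rim of a disk of radius a, u0 = 0."""
    al = jn_zeros(0, n_terms)
    terms = (
        2.0 / (al * j1(al)) * j0(al * r_over_a)
        * np.exp(-D * (al / a) ** 2 * t)
    )
    return 1.0 - terms.sum()


class TestMacroMesh:
    def test_square_polygon_mesh(self):
        from shapely.geometry import box as shapely_box

        mesh = mesh_cell_polygon(shapely_box(0, 0, 10, 10), 1.0)
        assert mesh.n_elements == 200
        # boundary nodes: the outer ring of the 11×11 grid
        assert len(mesh.dirichlet_nodes) == 40

    def test_locate_barycentric(self):
        mesh = disk_mesh()
        e, lam = mesh.locate(np.array([8.0, 8.0]))
        assert lam.min() >= -1e-9 and lam.sum() == pytest.approx(1.0)


class TestSolveTransport:
    def test_steady_state_identity(self):
        mesh = disk_mesh(radius=4.0, h=0.5)
        p = TransportProblem(mesh, g_D=1.0, u_0=1.0, dt=0.05, t_end=0.5)
        s = solve_transport(p)
        assert np.allclose(s.nodal_values, 1.0, atol=1e-12)

    def test_disk_uptake_matches_bessel_series(self):
        a, D = 8.0, 32.8
        mesh = disk_mesh(radius=a, h=0.25, D=D)
        # effective disk radius of the staircase mesh
        a_eff = np.sqrt(mesh.element_areas().sum() / np.pi)
        s = solve_transport(
            TransportProblem(mesh, g_D=1.0, u_0=0.0, dt=0.005, t_end=1.0),
            store_every=1,
        )
        centre = s.at_point(np.array([a, a]))
        for t_probe in (0.25, 0.5, 0.9):
            exact = disk_uptake_series(0.0, t_probe, D, a_eff)
            num = float(np.interp(t_probe, s.times, centre))
            assert num == pytest.approx(exact, abs=0.01)

    def test_maximum_principle(self):
        mesh = disk_mesh(radius=4.0, h=0.4)
        s = solve_transport(TransportProblem(mesh, g_D=1.0, u_0=0.0,
                                             dt=0.02, t_end=0.6))
        assert s.nodal_values.min() >= -1e-12
        assert s.nodal_values.max() <= 1.0 + 1e-12

    def test_mass_conservation_closed_cell(self):
        mesh = disk_mesh(radius=4.0, h=0.4)
        rng = np.random.default_rng(0)
        u0 = rng.uniform(0, 1, mesh.n_nodes)
        p = TransportProblem(mesh, u_0=u0, dt=0.01, t_end=0.2, neumann=True)
        s = solve_transport(p)
        from cytodiffuse.transport import _assemble_macro

        _, m, _ = _assemble_macro(mesh)
        masses = s.nodal_values @ m
        assert np.allclose(masses, masses[0], rtol=1e-10)

    def test_dt_refinement(self):
        # step small relative to the crossing time, as in whole-cell runs
        mesh = disk_mesh(radius=4.0, h=0.4, D=8.0)
        t_coarse = time_to_threshold(
            solve_transport(TransportProblem(mesh, dt=0.01, t_end=4.0)),
            np.array([4.0, 4.0]), 0.9,
        )
        t_fine = time_to_threshold(
            solve_transport(TransportProblem(mesh, dt=0.005, t_end=4.0)),
            np.array([4.0, 4.0]), 0.9,
        )
        assert t_fine == pytest.approx(t_coarse, rel=0.01)

    def test_invalid_dt_raises(self):
        mesh = disk_mesh(radius=4.0, h=0.5)
        with pytest.raises(ValueError):
            TransportProblem(mesh, dt=0.0)


class TestTimeToThreshold:
    def test_initial_value_already_there(self):
        mesh = disk_mesh(radius=4.0, h=0.5)
        s = solve_transport(TransportProblem(mesh, g_D=1.0, u_0=1.0,
                                             dt=0.05, t_end=0.2))
        assert time_to_threshold(s, np.array([4.0, 4.0]), 0.5) == 0.0

    def test_unreached_level_is_inf(self):
        mesh = disk_mesh(radius=8.0, h=0.5)
        s = solve_transport(TransportProblem(mesh, dt=0.01, t_end=0.05))
        assert time_to_threshold(s, np.array([8.0, 8.0]), 0.9) == np.inf

    def test_larger_phi_slows_arrival(self):
        # uniformly smaller diffusivity ⇒ later threshold crossing
        law = PowerLawParams(0.6209, 1.183)
        times = []
        for D in (32.8, 16.4):
            mesh = disk_mesh(radius=6.0, h=0.5, D=D)
            s = solve_transport(TransportProblem(mesh, dt=0.02, t_end=10.0))
            times.append(time_to_threshold(s, np.array([6.0, 6.0]), 0.9))
        assert times[1] > times[0]


class TestPhiField:
    def test_zero_density_gives_zero_phi(self):
        g = synth_cell_map(seed=1)
        zero = type(g)(g.weights * 1e-30, g.means, g.covariances,
                       g.cell_polygon, g.reference())
        mesh = mesh_cell_polygon(g.cell_polygon, 3.0)
        phi = build_phi_field(zero, 0.01, mesh, fast=False)
        assert np.allclose(phi, 0.0)

    def test_lookup_matches_direct_sampling(self):
        lookup = DensityPhiLookup(1430.0, 0.010, seed=0, n_levels=8, n_seeds=2)
        from cytodiffuse.transport import _phi_single_network

        for dens in (400.0, 900.0, 1380.0):
            direct = np.mean([
                _phi_single_network(dens, 0.010, s) for s in (11, 12, 13)
            ])
            assert float(lookup(dens)) == pytest.approx(direct, abs=0.012)

    def test_lookup_monotone(self):
        lookup = DensityPhiLookup(2000.0, 0.010, seed=1, n_levels=6, n_seeds=1)
        d = np.linspace(0, 2000, 50)
        assert np.all(np.diff(lookup(d)) >= -1e-12)


class TestLocalCorrection:
    def test_zero_corrector_returns_linear_field(self):
        bg = BlockedGeometry(0.0, 0.0, [], Polygon(), 0.0, 1.0)
        mesh = mesh_sampling_domain(bg, 1 / 16, D_micro=1.0)
        sol = solve_cell_problems(mesh)
        out = local_correction(2.0, [1.0, 0.0], sol)
        lin = 2.0 + (mesh.nodes[:, 0] - 0.5)
        assert np.allclose(out, lin, atol=1e-10)

    def test_cell_mean_matches_macro_value(self):
        from shapely.geometry import Point as P

        hole = P(0.5, 0.5).buffer(0.2)
        bg = BlockedGeometry(0.0, 0.0, [], hole, float(hole.area), 1.0)
        mesh = mesh_sampling_domain(bg, 1 / 32)
        sol = solve_cell_problems(mesh)
        out = local_correction(1.5, [0.7, -0.3], sol)
        # zero-mean correctors: the corrected field's mean stays at the
        # linear profile's mean over the free nodes (≈ the macro value)
        lin = 1.5 + (mesh.nodes - 0.5) @ np.array([0.7, -0.3])
        assert out.mean() == pytest.approx(lin.mean(), abs=5e-3)
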