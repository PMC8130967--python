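"""Cross-sections and vesicle-inaccessible regions."""

import numpy as np
import pytest

from cytodiffuse.accessibility import (
    inaccessible_region,
    phi_of_radius,
    raster_blocked_mask,
    rasterize_obstacles,
    slice_cross_sections,
    stack_inaccessible_volume,
)
from cytodiffuse.network import NetworkSpec, generate_network
from tests.conftest import make_net


def raster_obstacle_mask_3d(net, z, px):
    """Oracle: pixel centres within one radius of any filament axis in 3D."""
    n = int(round(net.box_edge / px))
    xs = (np.arange(n) + 0.5) * px
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), np.full(n * n, z)], axis=1)
    a, b = net.endpoints()
    r = net.filaments[0].radius
    mask = np.zeros(n * n, dtype=bool)
    for p0, p1 in zip(a, b):
        d = p1 - p0
        L2 = d @ d
        t = np.clip(((pts - p0) @ d) / L2, 0.0, 1.0)
        closest = p0 + t[:, None] * d
        mask |= np.linalg.norm(pts - closest, axis=1) <= r
    return mask.reshape(n, n)


class TestSliceGeometry:
    def test_perpendicular_axis_gives_circle(self):
        net = make_net([((0.5, 0.5, 0.0), (0.5, 0.5, 1.0), 0.02)])
        obs = slice_cross_sections(net, 0.5)
        assert len(obs) == 1 and obs[0].kind == "circle"
        assert obs[0].area == pytest.approx(np.pi * 0.02**2, rel=1e-3)

    def test_oblique_axis_gives_ellipse(self):
        # 45° to the slice: semi-axes (r, r/cos45°), area πr²√2
        net = make_net([((0.3, 0.5, 0.3), (0.7, 0.5, 0.7), 0.02)])
        obs = slice_cross_sections(net, 0.5)
        assert len(obs) == 1 and obs[0].kind == "ellipse"
        assert obs[0].area == pytest.approx(np.pi * 0.02**2 * np.sqrt(2), rel=1e-3)

    def test_grazing_sections_excluded_by_default(self):
        net = make_net([((0.1, 0.5, 0.5), (0.9, 0.5, 0.5), 0.005)])
        assert slice_cross_sections(net, 0.5) == []
        obs = slice_cross_sections(net, 0.5, include_grazing=True)
        assert len(obs) == 1 and obs[0].kind == "polygon"
        # in-plane strip: length 0.8, width 2r
        assert obs[0].area == pytest.approx(0.8 * 0.01, rel=0.05)

    def test_plane_outside_cylinder_span(self):
        net = make_net([((0.5, 0.5, 0.1), (0.5, 0.5, 0.4), 0.02)])
        assert slice_cross_sections(net, 0.8) == []

    def test_total_area_matches_3d_raster_oracle(self, sparse_net):
        obs = slice_cross_sections(sparse_net, 0.5, include_grazing=True)
        geom_area = sum(o.area for o in obs)
        mask = raster_obstacle_mask_3d(sparse_net, 0.5, 1e-3)
        raster_area = mask.mean() * sparse_net.box_edge**2
        assert geom_area == pytest.approx(raster_area, rel=0.03, abs=2e-4)

    def test_invalid_height_raises(self, sparse_net):
        with pytest.raises(ValueError):
            slice_cross_sections(sparse_net, 1.5)


class TestInaccessibleRegion:
    def test_empty_obstacles(self):
        bg = inaccessible_region([], 0.01)
        assert bg.phi == 0.0

    def test_zero_radius_returns_union(self, sparse_net):
        obs = slice_cross_sections(sparse_net, 0.5)
        bg = inaccessible_region(obs, 0.0)
        union_area = bg.obstacle_union().area
        assert bg.phi == pytest.approx(union_area, rel=1e-9)

    def test_negative_radius_raises(self):
        with pytest.raises(ValueError):
            inaccessible_region([], -0.01)

    def test_two_close_circles_vs_raster_opening(self):
        # gap 0.008 < 2R = 0.010: the bridged pair against the raster oracle
        net = make_net([
            ((0.03, 0.03, 0.0), (0.03, 0.03, 0.06), 0.005),
            ((0.048, 0.03, 0.0), (0.048, 0.03, 0.06), 0.005),
        ], box_edge=0.06)
        obs = slice_cross_sections(net, 0.03)
        bg = inaccessible_region(obs, 0.005, box_edge=0.06)
        px = 5e-5
        omask = rasterize_obstacles(bg.obstacle_union(), 0.06, px)
        rmask = raster_blocked_mask(omask, 0.005, px)
        phi_raster = rmask.mean()
        assert bg.phi > inaccessible_region(obs, 0.0, box_edge=0.06).phi
        assert bg.phi == pytest.approx(phi_raster, rel=0.02)

    @pytest.mark.parametrize("seed", range(6))
    def test_geometric_vs_raster_oracle_random(self, seed):
        net = generate_network(NetworkSpec(400, seed=seed, box_edge=1.0))
        obs = slice_cross_sections(net, 0.5)
        bg = inaccessible_region(obs, 0.010)
        px = 1e-3
        omask = rasterize_obstacles(bg.obstacle_union(), 1.0, px)
        rmask = raster_blocked_mask(omask, 0.010, px)
        assert abs(bg.phi - rmask.mean()) <= 0.02

    def test_blocked_region_contains_obstacles(self, sparse_net):
        obs = slice_cross_sections(sparse_net, 0.5)
        bg = inaccessible_region(obs, 0.015)
        assert bg.blocked_region.area >= bg.obstacle_union().area - 1e-12

    def test_wkt_serialization(self, sparse_net):
        obs = slice_cross_sections(sparse_net, 0.5)
        bg = inaccessible_region(obs, 0.01)
        assert bg.to_wkt().startswith(("POLYGON", "MULTIPOLYGON", "GEOMETRYCOLLECTION"))


class TestPhiCurve:
    def test_monotone_and_saturating(self, cortical_net):
        radii = np.array([0.0, 0.005, 0.01, 0.02, 0.04, 0.08, 0.15])
        curve = phi_of_radius(cortical_net, 0.5, radii)
        assert np.all(np.diff(curve.phi_values) >= -1e-12)
        # φ(R→∞) → 1 up to the finite-window margin (no obstacles are
        # sampled outside the slice square, so its rim fills last)
        assert curve.phi_values[-1] > 0.9
        obs = slice_cross_sections(cortical_net, 0.5)
        assert curve.phi_values[0] == pytest.approx(
            inaccessible_region(obs, 0.0).phi, rel=1e-9
        )

    def test_unsorted_radii_raise(self, cortical_net):
        with pytest.raises(ValueError):
            phi_of_radius(cortical_net, 0.5, [0.02, 0.01])

    def test_phi_increases_with_density(self):
        phis = []
        for dens in (400, 1430, 2800):
            vals = []
            for seed in (0, 1, 2):
                net = generate_network(NetworkSpec(dens, seed=seed))
                obs = slice_cross_sections(net, 0.5)
                vals.append(inaccessible_region(obs, 0.01).phi)
            phis.append(np.mean(vals))
        assert phis[0] < phis[1] < phis[2]

    def test_crossing_radius_interpolation(self, cortical_net):
        radii = np.linspace(0.0, 0.06, 13)
        curve = phi_of_radius(cortical_net, 0.5, radii)
        target = 0.5 * (curve.phi_values[5] + curve.phi_values[6])
        r = curve.first_radius_reaching(target)
        assert radii[5] < r < radii[6]
        assert np.isnan(curve.first_radius_reaching(2.0))


class TestStackVolume:
    def test_empty_network(self):
        net = make_net([])
        assert stack_inaccessible_volume(net, 0.01, n_slices=5) == 0.0

    def test_z_invariant_field_equals_single_slice(self):
        # one perpendicular cylinder: every slice is the same circle
        net = make_net([((0.5, 0.5, 0.0), (0.5, 0.5, 1.0), 0.05)])
        single = inaccessible_region(slice_cross_sections(net, 0.5), 0.01).phi
        stacked = stack_inaccessible_volume(net, 0.01, n_slices=11)
        assert stacked == pytest.approx(single, rel=1e-6)

    def test_slice_refinement_converges(self, sparse_net):
        v1 = stack_inaccessible_volume(sparse_net, 0.01, n_slices=20)
        v2 = stack_inaccessible_volume(sparse_net, 0.01, n_slices=40)
        assert v2 == pytest.approx(v1, rel=0.05, abs=5e-4)

    def test_too_few_slices_raise(self, sparse_net):
        with pytest.raises(ValueError):
            stack_inaccessible_volume(sparse_net, 0.01, n_slices=1)
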