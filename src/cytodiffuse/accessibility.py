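"""Vesicle-inaccessible regions of 2D network cross-sections.

A horizontal plane through the filament network intersects each solid
cylinder in a conic section: a circle for perpendicular axes, an ellipse for
oblique axes (clipped by the flat cylinder caps), and an elongated
rectangle for axes lying nearly in the plane.  A vesicle of radius R cannot
occupy the obstacles themselves nor squeeze through gaps narrower than its
diameter 2R.

Three constructions of the blocked region are provided:

* ``method="closing"`` (default) — the morphological closing of the
  obstacle union (dilate by R, erode by R), whose complement is exactly
  the morphological opening of the free space by the vesicle disk: the
  obstacles plus every gap narrower than the vesicle diameter.  As R grows
  the dilated obstacles merge and cover the slice, so φ(R) rises
  sigmoidally to 1.

* ``method="opening"`` — the same opening complement refined by
  reachability: only components of the eroded centre space connected to
  the slice boundary are considered accessible, so free pockets fully
  enclosed by blocked structure also count as inaccessible.

* ``method="graph"`` — the explicit proximity-graph heuristic: obstacle
  pairs with boundary gap below 2R are linked, the link set is pruned to
  node degree ≤ 2 (narrowest gaps first, the degree-two reduction of
  densely connected clusters), and each retained link is filled with the
  wedge bounded by the two obstacle boundaries and the two extreme tangent
  placements of the vesicle disk (the joint closing of the pair).  Cheap
  and local, but it does not capture enclosed pockets, so φ(R) saturates
  well below 1.

A pixel-raster implementation of the morphological opening
(``raster_blocked_mask``) is shipped as an independent cross-check and as a
fallback for degenerate geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Point, Polygon, box as shapely_box
from shapely.ops import nearest_points, unary_union

from cytodiffuse.network import NetworkRealization

# chord tolerance of arc discretization, μm (1 nm)
CHORD_TOL = 1e-3
_NEAR_PARALLEL_DEG = 5.0


@dataclass
class Obstacle2D:
    """One cylinder cross-section, as a polygon in slice coordinates (μm)."""

    kind: str  # "circle" | "ellipse" | "polygon"
    polygon: Polygon
    source_filament: int
    center: np.ndarray | None = None
    semi_axes: tuple[float, float] | None = None
    orientation: float | None = None  # radians, major-axis angle

    @property
    def area(self) -> float:
        return self.polygon.area


@dataclass
class BlockedGeometry:
    """Blocked (vesicle-inaccessible) region of one slice."""

    slice_z: float
    vesicle_radius: float
    obstacles: list[Obstacle2D]
    blocked_region: shapely.Geometry  # polygonal union within the slice square
    phi: float
    box_edge: float = 1.0

    def obstacle_union(self) -> shapely.Geometry:
        return unary_union([o.polygon for o in self.obstacles])

    def to_wkt(self) -> str:
        return shapely.to_wkt(self.blocked_region)


@dataclass
class PhiCurve:
    radii: np.ndarray
    phi_values: np.ndarray
    slice_z: float
    network_seed: int | None = None

    def first_radius_reaching(self, phi_c: float) -> float:
        """Smallest vesicle radius with φ(R) ≥ phi_c, by linear interpolation.

        Returns ``nan`` if the curve never reaches ``phi_c``.
        """
        phi = np.asarray(self.phi_values, dtype=float)
        r = np.asarray(self.radii, dtype=float)
        idx = np.nonzero(phi >= phi_c)[0]
        if idx.size == 0:
            return float("nan")
        i = idx[0]
        if i == 0:
            return float(r[0])
        f = (phi_c - phi[i - 1]) / (phi[i] - phi[i - 1])
        return float(r[i - 1] + f * (r[i] - r[i - 1]))


def _n_arc_vertices(radius: float, chord_tol: float = CHORD_TOL) -> int:
    if radius <= chord_tol:
        return 16
    dtheta = 2.0 * np.arccos(max(-1.0, 1.0 - chord_tol / radius))
    return int(np.clip(np.ceil(2 * np.pi / dtheta), 16, 256))


def _ellipse_polygon(center, major_dir, a, b) -> Polygon:
    """Polygon of an ellipse with semi-axes a (along major_dir) and b.

    Vertices are placed slightly outside the exact boundary so the polygon
    area equals the ellipse area exactly (the inscribed n-gon deficit is
    compensated; exact for circles and, by affine invariance, ellipses).
    """
    n = max(24, _n_arc_vertices(max(a, b)))
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    s = np.sqrt(2 * np.pi / n / np.sin(2 * np.pi / n))  # area compensation
    e1 = np.asarray(major_dir, dtype=float)
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.array([-e1[1], e1[0]])
    pts = (
        np.asarray(center)[None, :]
        + s * a * np.cos(t)[:, None] * e1[None, :]
        + s * b * np.sin(t)[:, None] * e2[None, :]
    )
    return Polygon(pts)


def _cylinder_slice_polygon(p0, p1, radius, z) -> tuple[Polygon, str] | None:
    """Cross-section of the solid finite cylinder with the plane z=const.

    The section of the *infinite* cylinder is a circle/ellipse; the flat
    caps restrict it to the slab 0 ≤ s ≤ L of axial coordinate s.  Both are
    intersected in-plane.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    L = np.linalg.norm(d)
    if L == 0:
        return None
    u = d / L
    uz = u[2]
    sin_in_plane = abs(uz)  # cos of angle between axis and plane normal

    if sin_in_plane < np.sin(np.radians(_NEAR_PARALLEL_DEG)):
        # axis (nearly) in the slice plane: elongated strip around the part
        # of the projected axis lying within one radius of the plane
        zspan = p1[2] - p0[2]
        if abs(zspan) < 1e-15:
            t_lo, t_hi = 0.0, 1.0
        else:
            ta = (z - radius - p0[2]) / zspan
            tb = (z + radius - p0[2]) / zspan
            t_lo = max(0.0, min(ta, tb))
            t_hi = min(1.0, max(ta, tb))
            if t_hi <= t_lo:
                return None
        dz_mid = z - (p0[2] + 0.5 * (t_lo + t_hi) * zspan)
        if abs(dz_mid) >= radius:
            return None
        half_w = np.sqrt(max(radius**2 - dz_mid**2, 0.0))
        if half_w <= 0:
            return None
        a2 = p0[:2] + t_lo * (p1[:2] - p0[:2])
        b2 = p0[:2] + t_hi * (p1[:2] - p0[:2])
        t = b2 - a2
        nt = np.linalg.norm(t)
        if nt < 1e-12:
            return None
        t /= nt
        n2 = np.array([-t[1], t[0]])
        quad = [
            a2 + half_w * n2, b2 + half_w * n2,
            b2 - half_w * n2, a2 - half_w * n2,
        ]
        return Polygon(quad), "polygon"

    # intersection point of the axis line with the plane
    t_axis = (z - p0[2]) / uz
    center3 = p0 + t_axis * u
    center = center3[:2]
    u_xy = u[:2]
    nxy = np.linalg.norm(u_xy)
    if nxy < 1e-12:
        # perpendicular axis: circle (caps: plane must lie within the span)
        if not (min(p0[2], p1[2]) - 1e-15 <= z <= max(p0[2], p1[2]) + 1e-15):
            return None
        poly = _ellipse_polygon(center, (1.0, 0.0), radius, radius)
        return poly, "circle"

    major_dir = u_xy / nxy
    a = radius / sin_in_plane  # semi-major along the projected axis
    b = radius
    ellipse = _ellipse_polygon(center, major_dir, a, b)

    # cap slab: axial coordinate s(p) = (p - p0)·u for p in the plane
    # s = (p_xy - p0_xy)·u_xy + (z - p0_z)·uz, linear in p_xy
    # clip only when the caps actually cut the ellipse
    s_center = t_axis  # axial coordinate of the ellipse centre
    if s_center - a * nxy < -1e-12 or s_center + a * nxy > L + 1e-12:
        # strip of 0 <= s <= L in the plane
        g = u_xy  # gradient of s wrt p_xy
        c0 = (z - p0[2]) * uz - np.dot(p0[:2], g)
        # s(p) = g·p + c0; build a generous strip polygon
        span = 2 * (a + L + 1.0)
        tdir = np.array([-g[1], g[0]])
        tdir /= np.linalg.norm(tdir)
        gn = g / np.linalg.norm(g)
        # points on lines s=0 and s=L closest to the ellipse centre
        s_c = np.dot(g, center) + c0
        p_on0 = center - (s_c - 0.0) / np.linalg.norm(g) * gn
        p_onL = center - (s_c - L) / np.linalg.norm(g) * gn
        strip = Polygon([
            p_on0 + span * tdir, p_onL + span * tdir,
            p_onL - span * tdir, p_on0 - span * tdir,
        ])
        ellipse = ellipse.intersection(strip)
        if ellipse.is_empty:
            return None
        return ellipse, "polygon"
    return ellipse, "ellipse"


def slice_cross_sections(
    net: NetworkRealization,
    z: float,
    include_grazing: bool = False,
) -> list[Obstacle2D]:
    """Obstacles of the cross-section at height ``z``, clipped to the slice square.

    By default, filaments grazing the plane at less than 5° of tilt are
    omitted.  Their sections — rectangle-like strips up to the filament
    length — are artifacts of reducing the 3D geometry to a zero-thickness
    plane: such a filament spans only a few nanometres of height, so in the
    stack model (slice spacing box/100) a vesicle passes above or below it,
    and a strip hundreds of nanometres long would otherwise act as a solid
    wall that the three-dimensional network does not possess.  Set
    ``include_grazing=True`` for the literal planar sections (circles,
    ellipses and rectangles).
    """
    if not 0 <= z <= net.box_edge:
        raise ValueError("slice height must lie within the box")
    square = shapely_box(0.0, 0.0, net.box_edge, net.box_edge)
    sin_thr = np.sin(np.radians(_NEAR_PARALLEL_DEG))
    out: list[Obstacle2D] = []
    for i, f in enumerate(net.filaments):
        zlo = min(f.p0[2], f.p1[2]) - f.radius
        zhi = max(f.p0[2], f.p1[2]) + f.radius
        if not (zlo <= z <= zhi):
            continue
        if not include_grazing:
            u = f.p1 - f.p0
            if abs(u[2]) < sin_thr * np.linalg.norm(u):
                continue
        res = _cylinder_slice_polygon(f.p0, f.p1, f.radius, z)
        if res is None:
            continue
        poly, kind = res
        poly = poly.intersection(square)
        if poly.is_empty or poly.area <= 0:
            continue
        out.append(Obstacle2D(kind=kind, polygon=poly, source_filament=i))
    return out


def _as_polygon_list(geom) -> list[Polygon]:
    if geom.is_empty:
        return []
    if isinstance(geom, Polygon):
        return [geom]
    return [g for g in geom.geoms if isinstance(g, Polygon) and g.area > 0]


def _pruned_gap_edges(compounds: list[Polygon], R: float) -> list[tuple[int, int, float]]:
    """Proximity edges (gap ≤ 2R) greedily pruned to node degree ≤ 2.

    Edges are taken narrowest-gap first; an edge is kept only while both
    obstacles still have fewer than two links, which reduces every densely
    connected cluster to chains and simple cycles — the degree-two
    reduction of the path structure between too-narrow obstacles.
    """
    tree = shapely.STRtree(compounds)
    cand = tree.query(
        np.array(compounds, dtype=object), predicate="dwithin", distance=2.0 * R
    )
    pairs = {(int(i), int(j)) for i, j in cand.T if i < j}
    edges = []
    for i, j in pairs:
        gap = compounds[i].distance(compounds[j])
        if gap <= 2.0 * R:  # closed condition: gap == 2R is blocked
            edges.append((i, j, gap))
    edges.sort(key=lambda e: e[2])
    degree = np.zeros(len(compounds), dtype=int)
    kept = []
    for i, j, gap in edges:
        if degree[i] < 2 and degree[j] < 2:
            kept.append((i, j, gap))
            degree[i] += 1
            degree[j] += 1
    return kept


def _pair_wedge(a: Polygon, b: Polygon, R: float, gap: float, qs: int):
    """Fill of the narrow gap between two obstacles.

    The wedge bounded by the two obstacle boundaries and the two extreme
    tangent vesicle placements equals the joint morphological closing of
    the pair; it is computed in a local window around the closest approach
    for efficiency.
    """
    pa, pb = nearest_points(a, b)
    m = Point(0.5 * (pa.x + pb.x), 0.5 * (pa.y + pb.y))
    rwin = 0.5 * gap + 3.0 * R
    window = m.buffer(rwin, quad_segs=8)
    local = unary_union([a.intersection(window), b.intersection(window)])
    if local.is_empty:
        return None
    closed = local.buffer(R, quad_segs=qs).buffer(-R, quad_segs=qs)
    wedge = closed.difference(local).intersection(
        m.buffer(0.5 * gap + 2.0 * R, quad_segs=8)
    )
    return None if wedge.is_empty else wedge


def inaccessible_region(
    obstacles: list[Obstacle2D],
    R: float,
    box_edge: float = 1.0,
    slice_z: float = 0.0,
    method: str = "closing",
) -> BlockedGeometry:
    """Region a vesicle of radius R can never occupy, and its area fraction φ.

    See the module docstring for the three constructions.  A boundary gap
    exactly equal to 2R is blocked (closed condition).  R = 0 returns the
    obstacle union itself.
    """
    if R < 0:
        raise ValueError("vesicle radius must be >= 0")
    square = shapely_box(0.0, 0.0, box_edge, box_edge)
    union = unary_union([o.polygon for o in obstacles]) if obstacles else Polygon()
    if union.is_empty:
        return BlockedGeometry(slice_z, R, obstacles, Polygon(), 0.0, box_edge)
    if R == 0:
        blocked = union.intersection(square)
        return BlockedGeometry(
            slice_z, R, obstacles, blocked,
            float(blocked.area / box_edge**2), box_edge,
        )
    qs = max(8, _n_arc_vertices(R) // 4)
    if method == "opening":
        # centre configuration space, components reachable from the boundary
        centre_space = square.difference(union.buffer(R, quad_segs=qs))
        reachable = [
            p for p in _as_polygon_list(centre_space)
            if p.intersects(square.exterior)
        ]
        if reachable:
            body = unary_union(reachable).buffer(R, quad_segs=qs)
            blocked = square.difference(body)
        else:
            blocked = square
        blocked = unary_union([blocked, union.intersection(square)])
    elif method == "closing":
        closed = union.buffer(R, quad_segs=qs).buffer(-R, quad_segs=qs)
        # closing can only grow the set; tiny buffer slivers are unioned away
        blocked = unary_union([closed, union]).intersection(square)
    elif method == "graph":
        compounds = _as_polygon_list(union)
        fills = []
        for i, j, gap in _pruned_gap_edges(compounds, R):
            w = _pair_wedge(compounds[i], compounds[j], R, gap, qs)
            if w is not None:
                fills.append(w)
        web = unary_union([union, *fills]).intersection(square)
        # free regions sealed off by the wedge web are inaccessible:
        # keep only free components connected to the slice boundary
        free_parts = [
            p for p in _as_polygon_list(square.difference(web))
            if p.intersects(square.exterior)
        ]
        blocked = square.difference(unary_union(free_parts)) if free_parts \
            else square
    else:
        raise ValueError(f"unknown method {method!r}")
    return BlockedGeometry(
        slice_z, R, obstacles, blocked,
        float(blocked.area / box_edge**2), box_edge,
    )


def phi_of_radius(
    net: NetworkRealization,
    z: float,
    radii,
    method: str = "closing",
) -> PhiCurve:
    """φ(R) on a single slice for an ascending list of vesicle radii."""
    radii = np.asarray(radii, dtype=float)
    if np.any(np.diff(radii) < 0):
        raise ValueError("radii must be sorted ascending")
    obstacles = slice_cross_sections(net, z)
    phis = np.array([
        inaccessible_region(obstacles, float(r), net.box_edge, z, method).phi
        for r in radii
    ])
    return PhiCurve(radii, phis, z, net.seed)


def stack_inaccessible_volume(
    net: NetworkRealization, R: float, n_slices: int = 100
) -> float:
    """Inaccessible volume fraction from a stack of slices.

    Per-slice φ on evenly spaced planes, aggregated trapezoidally over z
    (for uniform spacing this equals averaging neighbouring slices and
    multiplying by the slice distance).
    """
    if n_slices < 2:
        raise ValueError("need at least 2 slices")
    zs = np.linspace(0.0, net.box_edge, n_slices)
    phis = [
        inaccessible_region(slice_cross_sections(net, z), R, net.box_edge, z).phi
        for z in zs
    ]
    return float(np.trapezoid(phis, zs) / net.box_edge)


# ---------------------------------------------------------------------------
# raster oracle / fallback

def rasterize_obstacles(
    geometry: shapely.Geometry, box_edge: float, px: float
) -> np.ndarray:
    """Boolean mask (True = obstacle) at pixel size ``px`` μm/px."""
    n = int(round(box_edge / px))
    xs = (np.arange(n) + 0.5) * px
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    pts_x = X.ravel()
    pts_y = Y.ravel()
    shapely.prepare(geometry)
    mask = shapely.contains_xy(geometry, pts_x, pts_y)
    return mask.reshape(n, n)


def raster_blocked_mask(
    obstacle_mask: np.ndarray, R: float, px: float,
    boundary_connected: bool = False,
) -> np.ndarray:
    """Blocked mask from the raster morphological opening of free space.

    free ∘ disk(R) computed with binary erosion/dilation; the blocked set is
    its complement — the independent raster oracle of the default geometric
    construction.  With ``boundary_connected`` only eroded components
    reachable from the image border are dilated back (the raster analogue
    of ``method="opening"``).
    """
    from scipy import ndimage

    if R == 0:
        return obstacle_mask.copy()
    r_px = R / px
    # disk erosion/dilation via exact Euclidean distance transforms
    dist_to_obstacle = ndimage.distance_transform_edt(~obstacle_mask)
    eroded = dist_to_obstacle > r_px
    if boundary_connected:
        lab, _ = ndimage.label(eroded)
        border = np.unique(np.concatenate([
            lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]
        ]))
        border = border[border > 0]
        eroded = np.isin(lab, border)
    dist_to_eroded = ndimage.distance_transform_edt(~eroded)
    opened = dist_to_eroded <= r_px
    return ~opened
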