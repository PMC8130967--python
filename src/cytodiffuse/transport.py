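"""Homogenized vesicle transport on the whole-cell domain.

The cell is a 2D polygon meshed with structured right triangles (maximum
edge ~1 μm by default).  Each element carries an effective diffusivity D0,
either from the power-law surrogate evaluated on its inaccessible area
fraction φ, or from direct homogenization.  The concentration field solves

    ∂u/∂t − ∇·(D0(x) ∇u) = f,  u = g_D on ∂Ω_D,  n·D0∇u = g_N on ∂Ω_N,

by P1 Galerkin in space and backward Euler in time (lumped mass matrix, so
the discrete maximum principle holds for any time step).  For the standard
uptake experiment the whole membrane carries g_D = 1, the interior starts
empty, and the readout is the time for the concentration at a probe point
to reach a threshold (0.9 at (30, 30) μm in the reference configuration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.interpolate import PchipInterpolator
from scipy.sparse import coo_matrix, diags
from scipy.sparse.linalg import splu
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from cytodiffuse.accessibility import inaccessible_region, slice_cross_sections
from cytodiffuse.density import GMMDensity, density_to_spec
from cytodiffuse.effective_law import PowerLawParams, predict_D0
from cytodiffuse.homogenization import CellSolution
from cytodiffuse.network import generate_network


@dataclass
class MacroMesh:
    """P1 triangulation of the cell polygon with element diffusivities."""

    nodes: np.ndarray            # (n_nodes, 2) μm
    triangles: np.ndarray        # (n_elem, 3)
    dirichlet_nodes: np.ndarray  # node indices on ∂Ω_D
    D_elem: np.ndarray | None = None  # scalar μm²/s per element

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.triangles].mean(axis=1)

    def element_areas(self) -> np.ndarray:
        v = self.nodes[self.triangles]
        e1 = v[:, 1] - v[:, 0]
        e2 = v[:, 2] - v[:, 0]
        return 0.5 * np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])

    def locate(self, x) -> tuple[int, np.ndarray]:
        """Containing triangle and barycentric coordinates of a point."""
        x = np.asarray(x, dtype=float)
        cen = self.element_centroids()
        tree = cKDTree(cen)
        _, cand = tree.query(x, k=min(24, self.n_elements))
        cand = np.atleast_1d(cand)
        best = None
        for e in cand:
            lam = self._barycentric(int(e), x)
            if lam.min() >= -1e-9:
                return int(e), lam
            m = lam.min()
            if best is None or m > best[1]:
                best = (int(e), m, lam)
        # fall back to the least-violating candidate (point on the boundary)
        return best[0], best[2]

    def _barycentric(self, e: int, x: np.ndarray) -> np.ndarray:
        v = self.nodes[self.triangles[e]]
        T = np.array([v[1] - v[0], v[2] - v[0]]).T
        lam12 = np.linalg.solve(T, x - v[0])
        return np.array([1.0 - lam12.sum(), lam12[0], lam12[1]])


def mesh_cell_polygon(polygon: Polygon, target_h: float = 0.75) -> MacroMesh:
    """Structured triangulation of the polygon interior.

    Grid cells of pitch ``target_h`` split into two triangles; triangles
    whose centroid lies outside the polygon are dropped.  Boundary edges of
    the kept mesh form ∂Ω (all Dirichlet by default).
    """
    x0, y0, x1, y1 = polygon.bounds
    nx = int(np.ceil((x1 - x0) / target_h))
    ny = int(np.ceil((y1 - y0) / target_h))
    hx = (x1 - x0) / nx
    hy = (y1 - y0) / ny
    ii, jj = np.meshgrid(np.arange(nx + 1), np.arange(ny + 1), indexing="ij")
    nodes = np.stack([x0 + ii.ravel() * hx, y0 + jj.ravel() * hy], axis=1)
    idx = lambda i, j: i * (ny + 1) + j
    ci, cj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    ci, cj = ci.ravel(), cj.ravel()
    A = idx(ci, cj)
    B = idx(ci + 1, cj)
    C = idx(ci + 1, cj + 1)
    Dn = idx(ci, cj + 1)
    tris = np.concatenate(
        [np.stack([A, B, C], axis=1), np.stack([A, C, Dn], axis=1)], axis=0
    )
    cen = nodes[tris].mean(axis=1)
    shapely.prepare(polygon)
    keep = shapely.contains_xy(polygon, cen[:, 0], cen[:, 1])
    tris = tris[keep]

    used = np.unique(tris)
    remap = -np.ones(len(nodes), dtype=int)
    remap[used] = np.arange(len(used))
    nodes = nodes[used]
    tris = remap[tris]

    # boundary edges: used by exactly one triangle
    from collections import Counter

    cnt: Counter = Counter()
    for tri in tris:
        for a, b in ((0, 1), (1, 2), (2, 0)):
            e = (min(tri[a], tri[b]), max(tri[a], tri[b]))
            cnt[e] += 1
    bnodes = sorted({n for e, c in cnt.items() if c == 1 for n in e})
    return MacroMesh(nodes, tris, np.array(bnodes, dtype=int))


@dataclass
class TransportProblem:
    mesh: MacroMesh
    g_D: float = 1.0
    u_0: float | np.ndarray = 0.0
    f: float | np.ndarray = 0.0
    dt: float = 0.01
    t_end: float = 30.0
    neumann: bool = False  # True: no Dirichlet rows (closed cell)

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if np.any(np.asarray(self.g_D) < 0) or np.any(np.asarray(self.g_D) > 1):
            raise ValueError("g_D must lie in [0, 1]")


@dataclass
class ConcentrationSeries:
    times: np.ndarray           # (n_t,)
    nodal_values: np.ndarray    # (n_t, n_nodes)
    mesh: MacroMesh

    def at_point(self, x) -> np.ndarray:
        e, lam = self.mesh.locate(x)
        tri = self.mesh.triangles[e]
        return self.nodal_values[:, tri] @ lam


def _assemble_macro(mesh: MacroMesh):
    v = mesh.nodes[mesh.triangles]
    e1 = v[:, 1] - v[:, 0]
    e2 = v[:, 2] - v[:, 0]
    det = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    area = 0.5 * np.abs(det)
    g1 = np.stack([e2[:, 1], -e2[:, 0]], axis=1) / det[:, None]
    g2 = np.stack([-e1[:, 1], e1[:, 0]], axis=1) / det[:, None]
    g0 = -g1 - g2
    grads = np.stack([g0, g1, g2], axis=1)
    D = mesh.D_elem
    if D is None:
        raise ValueError("mesh carries no element diffusivities")
    K_loc = np.einsum("e,eid,ejd->eij", D * area, grads, grads)
    dofs = mesh.triangles
    rows = np.repeat(dofs, 3, axis=1).ravel()
    cols = np.tile(dofs, (1, 3)).ravel()
    K = coo_matrix((K_loc.ravel(), (rows, cols)),
                   shape=(mesh.n_nodes, mesh.n_nodes)).tocsr()
    # lumped mass
    m = np.zeros(mesh.n_nodes)
    np.add.at(m, dofs.ravel(), np.repeat(area / 3.0, 3))
    return K, m, area


def solve_transport(p: TransportProblem, store_every: int = 1) -> ConcentrationSeries:
    """Backward-Euler time stepping of the homogenized diffusion problem."""
    mesh = p.mesh
    K, m, area = _assemble_macro(mesh)
    n = mesh.n_nodes
    u = np.full(n, 0.0) + np.asarray(p.u_0, dtype=float)
    if u.shape != (n,):
        u = np.broadcast_to(u, (n,)).copy()
    fvec = np.full(n, 0.0) + np.asarray(p.f, dtype=float)
    if fvec.shape != (n,):
        fvec = np.broadcast_to(fvec, (n,)).copy()

    M = diags(m)
    A = (M / p.dt + K).tolil()
    dir_nodes = mesh.dirichlet_nodes if not p.neumann else np.array([], dtype=int)
    for nd in dir_nodes:
        A.rows[nd] = [nd]
        A.data[nd] = [1.0]
    lu = splu(A.tocsc())

    if dir_nodes.size:
        u[dir_nodes] = p.g_D

    n_steps = int(np.ceil(p.t_end / p.dt))
    times = [0.0]
    snaps = [u.copy()]
    for step in range(1, n_steps + 1):
        rhs = m * u / p.dt + m * fvec
        if dir_nodes.size:
            rhs[dir_nodes] = p.g_D
        u = lu.solve(rhs)
        if step % store_every == 0 or step == n_steps:
            times.append(step * p.dt)
            snaps.append(u.copy())
    return ConcentrationSeries(np.array(times), np.array(snaps), mesh)


def time_to_threshold(s: ConcentrationSeries, x_A, level: float) -> float:
    """First time the concentration at x_A reaches ``level``.

    Linear interpolation between the bracketing stored steps; the point
    value is P1-interpolated inside its containing triangle.  Returns
    ``inf`` if the level is never reached.
    """
    vals = s.at_point(x_A)
    if vals[0] >= level:
        return 0.0
    above = np.nonzero(vals >= level)[0]
    if above.size == 0:
        return float("inf")
    i = above[0]
    t0, t1 = s.times[i - 1], s.times[i]
    v0, v1 = vals[i - 1], vals[i]
    return float(t0 + (level - v0) / (v1 - v0) * (t1 - t0))


# ---------------------------------------------------------------------------
# φ field construction

def _phi_single_network(density: float, R: float, seed: int,
                        base_spec=None) -> float:
    from cytodiffuse.network import NetworkSpec
    from dataclasses import replace as _replace

    if density <= 0:
        return 0.0
    spec = base_spec or NetworkSpec(filaments_per_um3=density)
    spec = _replace(spec, filaments_per_um3=density, seed=int(seed))
    net = generate_network(spec)
    z = 0.5 * spec.box_edge
    obs = slice_cross_sections(net, z)
    return inaccessible_region(obs, R, spec.box_edge, z).phi


class DensityPhiLookup:
    """Monotone interpolant of the density → φ response.

    Tabulated once per run from a few network realizations per density
    level; replaces per-element network generation in whole-cell runs.
    """

    def __init__(self, max_density: float, R: float, seed: int,
                 n_levels: int = 12, n_seeds: int = 2):
        dens = np.linspace(0.0, max(max_density, 1.0), n_levels)
        rng = np.random.default_rng(seed)
        phis = np.zeros(n_levels)
        for i, d in enumerate(dens):
            vals = [
                _phi_single_network(d, R, rng.integers(2**31))
                for _ in range(n_seeds)
            ]
            phis[i] = np.mean(vals)
        phis = np.maximum.accumulate(phis)  # enforce monotone response
        phis = np.clip(phis, 0.0, 1.0)
        self.densities = dens
        self.phis = phis
        self._interp = PchipInterpolator(dens, phis, extrapolate=False)
        self.max_density = dens[-1]

    def __call__(self, density) -> np.ndarray:
        d = np.clip(np.asarray(density, dtype=float), 0.0, self.max_density)
        return np.clip(self._interp(d), 0.0, 1.0)


def build_phi_field(
    g: GMMDensity,
    R: float,
    mesh: MacroMesh,
    seed: int = 0,
    fast: bool = True,
    lookup: DensityPhiLookup | None = None,
) -> np.ndarray:
    """Per-element inaccessible area fraction over the macro mesh.

    Direct mode generates one filament network per element (density from
    the mixture at the element centroid, element-indexed seeds) and slices
    it mid-cube.  Fast mode evaluates a precomputed density → φ lookup.
    """
    from cytodiffuse.density import MAX_FILAMENTS_PER_UM3

    cen = mesh.element_centroids()
    ref = g.reference()
    dens = MAX_FILAMENTS_PER_UM3 * np.asarray(g(cen)) / ref
    if fast:
        if lookup is None:
            lookup = DensityPhiLookup(float(dens.max()), R, seed)
        return np.asarray(lookup(dens))
    rng = np.random.default_rng(seed)
    elem_seeds = rng.integers(2**31, size=len(cen))
    return np.array([
        _phi_single_network(d, R, s) for d, s in zip(dens, elem_seeds)
    ])


def apply_power_law_D(mesh: MacroMesh, phi: np.ndarray, law: PowerLawParams,
                      D_invitro: float, floor_ratio: float = 1e-9) -> None:
    """Set per-element D0 from φ via the power law (with trapping floor)."""
    mesh.D_elem = np.asarray(
        predict_D0(np.clip(phi, 0.0, 1.0), law, D_invitro,
                   floor=floor_ratio * D_invitro)
    )


def local_correction(
    u0_value: float,
    u0_gradient,
    cell_sol: CellSolution,
    element_center=None,
) -> np.ndarray:
    """First-order corrector: uᵉ = u⁰ − Σ_j χ_j ∂u⁰/∂x_j on the micro nodes.

    ``u0_value``/``u0_gradient`` are the macroscopic solution and its
    gradient at the element's quadrature point; the returned array gives the
    reconstructed fine-scale field on the sampling-domain nodes (the linear
    macro profile around the centre minus the corrector term, periodically
    extended).
    """
    mesh = cell_sol.mesh
    grad = np.asarray(u0_gradient, dtype=float)
    chi_nodes = cell_sol.chi[:, mesh.dof_of_node]  # (2, n_nodes)
    x = mesh.nodes
    if element_center is None:
        element_center = np.full(2, mesh.domain_size / 2.0)
    lin = u0_value + (x - np.asarray(element_center)) @ grad
    return lin - chi_nodes.T @ grad
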