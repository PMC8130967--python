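"""Independent checks of the homogenization machinery.

Two surfaces:

* ``mc_effective_D`` — vesicles performing Gaussian random walks amid the
  blocked geometry (periodically tiled), with a Metropolis reject-and-stay
  rule at obstacles.  The effective tensor follows from the slope of the
  mean-squared displacement, D̃_ij = ⟨Δx_i Δx_j⟩/(2t), fitted through the
  origin over the diffusive regime.  This estimates the same effective
  tensor as the periodic cell problems, by entirely different means.

* ``solve_1d_oscillatory`` — steady diffusion on [0, 1] with a rapidly
  oscillating coefficient d(x/ε), for which the exact solution
  u(x) = A ∫ dx/d + B and the homogenized coefficient (the harmonic mean of
  d) are available in closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.sparse import diags
from scipy.sparse.linalg import spsolve

from cytodiffuse.accessibility import BlockedGeometry, rasterize_obstacles


@dataclass
class MCConfig:
    """Random-walk estimator configuration.

    The per-axis step is σ = √(2·D_free·step_dt); it should stay well below
    the obstacle feature size (a warning fires above 0.2× the typical
    obstacle radius scale of 5 nm).  Displacement statistics are
    time-averaged over sliding windows, which multiplies the effective
    sample count per walker.
    """

    geometry: BlockedGeometry
    n_walkers: int = 2000
    step_dt: float = 4e-9
    total_time: float = 1.2e-3
    D_free: float = 32.8
    seed: int = 0
    raster_px: float = 5e-4      # μm/px for the geometry mask
    mask: np.ndarray | None = None  # precomputed blocked mask (overrides)
    collision: str = "reject"    # Metropolis reject-and-stay rule
    n_samples: int = 240         # position sampling instants
    msd_burn_in: float = 0.1     # shortest lag, as a fraction of total_time

    def step_sigma(self) -> float:
        return float(np.sqrt(2.0 * self.D_free * self.step_dt))


@dataclass
class MCResult:
    D_tensor: np.ndarray        # 2×2 μm²/s
    std_err: np.ndarray         # 2×2 bootstrap standard errors
    msd_times: np.ndarray
    msd: np.ndarray             # (n_t, 2, 2) displacement moments

    @property
    def trace_mean(self) -> float:
        return float(np.trace(self.D_tensor) / 2.0)


def _walk_numpy(blocked, npx, px, edge, sigma, n_steps, sample_steps, pos,
                rng):
    """Vectorized reject-and-stay walk; positions at the sample steps."""
    def is_blocked(p):
        ij = np.floor((p % edge) / px).astype(int)
        np.clip(ij, 0, npx - 1, out=ij)
        return blocked[ij[:, 0], ij[:, 1]]

    sample_set = set(sample_steps.tolist())
    snaps = []
    for step in range(1, n_steps + 1):
        prop = pos + rng.normal(scale=sigma, size=pos.shape)
        bad = is_blocked(prop)
        prop[bad] = pos[bad]
        pos = prop
        if step in sample_set:
            snaps.append(pos.copy())
    return np.array(snaps)


def _walk_kernel_compiled():
    import numba

    @numba.njit(cache=True)
    def kernel(blocked, npx, px, edge, sigma, n_steps, sample_steps, pos,
               seed):  # pragma: no cover - compiled
        np.random.seed(seed)
        nw = pos.shape[0]
        n_s = sample_steps.shape[0]
        out = np.empty((n_s, nw, 2), np.float64)
        si = 0
        for step in range(1, n_steps + 1):
            for w in range(nw):
                nx = pos[w, 0] + sigma * np.random.standard_normal()
                ny = pos[w, 1] + sigma * np.random.standard_normal()
                mx = nx % edge
                my = ny % edge
                ix = int(mx / px)
                iy = int(my / px)
                if ix >= npx:
                    ix = npx - 1
                if iy >= npx:
                    iy = npx - 1
                if not blocked[ix, iy]:
                    pos[w, 0] = nx
                    pos[w, 1] = ny
            if si < n_s and step == sample_steps[si]:
                out[si] = pos
                si += 1
        return out

    return kernel


_KERNEL = None


def mc_effective_D(cfg: MCConfig) -> MCResult:
    """Estimate the effective diffusion tensor by obstructed random walks.

    Walkers start uniformly in the free space of the (periodically tiled)
    blocked geometry; each step proposes a Gaussian displacement, and steps
    landing inside the blocked region are rejected (walker stays put) — the
    Metropolis rule whose stationary law is uniform on the free space.
    Coordinates are unwrapped; the tensor follows from time-averaged
    displacement moments ⟨Δx_i Δx_j⟩(τ) = 2 D_ij τ fitted through the
    origin over a window of lags, with bootstrap standard errors over
    walkers.
    """
    geom = cfg.geometry
    edge = geom.box_edge
    sigma = cfg.step_sigma()
    if sigma > 0.2 * 0.005:
        warnings.warn(
            f"step size {sigma*1e3:.2f} nm exceeds 20% of the 5 nm filament "
            "radius; the walk may under-resolve narrow gaps", stacklevel=2
        )

    if cfg.mask is not None:
        blocked = cfg.mask
        px = edge / blocked.shape[0]
    else:
        px = cfg.raster_px
        blocked = rasterize_obstacles(geom.blocked_region, edge, px) \
            if not geom.blocked_region.is_empty else \
            np.zeros((int(round(edge / px)),) * 2, dtype=bool)
    npx = blocked.shape[0]
    if blocked.all():
        raise ValueError("no free space in the geometry")

    rng = np.random.default_rng(cfg.seed)

    def is_blocked(p):
        ij = np.floor((p % edge) / px).astype(int)
        np.clip(ij, 0, npx - 1, out=ij)
        return blocked[ij[:, 0], ij[:, 1]]

    # uniform start positions in free space
    pos = np.empty((0, 2))
    while len(pos) < cfg.n_walkers:
        cand = rng.uniform(0, edge, size=(2 * cfg.n_walkers, 2))
        cand = cand[~is_blocked(cand)]
        pos = np.vstack([pos, cand])
    pos = pos[: cfg.n_walkers].copy()

    n_steps = int(round(cfg.total_time / cfg.step_dt))
    sample_steps = np.unique(np.linspace(1, n_steps, cfg.n_samples).astype(int))

    if cfg.collision != "reject":
        raise NotImplementedError(
            "only the reject-and-stay collision rule is implemented; it is "
            "the rule with the correct uniform equilibrium on free space"
        )
    global _KERNEL
    if _KERNEL is None:
        try:
            _KERNEL = _walk_kernel_compiled()
        except ImportError:  # numba unavailable: slow path
            _KERNEL = False
    if _KERNEL:
        snaps = _KERNEL(
            blocked, npx, px, edge, sigma, n_steps,
            sample_steps, pos.copy(), int(rng.integers(2**31)),
        )
    else:
        snaps = _walk_numpy(blocked, npx, px, edge, sigma,
                            n_steps, sample_steps, pos.copy(), rng)

    times = sample_steps * cfg.step_dt
    # lags spanning [burn_in, 2·burn_in]·total_time, in sample units
    dt_samp = times[-1] / len(times)
    lag_lo = max(1, int(round(cfg.msd_burn_in * cfg.total_time / dt_samp)))
    lag_hi = min(len(times) - 2, 2 * lag_lo)
    lags = np.unique(np.linspace(lag_lo, lag_hi, 6).astype(int))
    taus = lags * dt_samp

    # per-walker time-averaged displacement moments at each lag
    per_walker = np.empty((len(lags), cfg.n_walkers, 2, 2))
    for li, L in enumerate(lags):
        d = snaps[L:] - snaps[:-L]  # (n_windows, nw, 2)
        per_walker[li] = np.einsum("twi,twj->wij", d, d) / d.shape[0]

    def slope(pw):
        m = pw.mean(axis=1)  # (n_lags, 2, 2)
        return np.einsum("t,tij->ij", taus, m) / (2.0 * np.sum(taus**2))

    D = slope(per_walker)
    n_boot = 64
    boots = np.empty((n_boot, 2, 2))
    for b in range(n_boot):
        idx = rng.integers(0, cfg.n_walkers, cfg.n_walkers)
        boots[b] = slope(per_walker[:, idx])
    se = boots.std(axis=0)

    msd_curve = np.einsum("twi,twj->tij", snaps - snaps[0], snaps - snaps[0]) \
        / cfg.n_walkers
    return MCResult(D_tensor=D, std_err=se, msd_times=times, msd=msd_curve)


@dataclass
class OscillatoryProblem1D:
    """-(d(x/ε) u')' = 0 on (0, 1), u(0) = u_left, u(1) = u_right."""

    epsilon: float
    coefficient: Callable[[np.ndarray], np.ndarray]  # d(y), y = x/ε mod 1
    u_left: float = 0.0
    u_right: float = 1.0
    n_elements: int = 1000

    def d_of_x(self, x: np.ndarray) -> np.ndarray:
        d = np.asarray(self.coefficient(np.mod(x / self.epsilon, 1.0)),
                       dtype=float)
        if np.any(d <= 0):
            raise ValueError("coefficient must be strictly positive")
        return d


@dataclass
class Oscillatory1DResult:
    x: np.ndarray
    u_fem: np.ndarray
    u_exact: np.ndarray
    l2_error: float
    D_hom_analytic: float   # harmonic mean of d over one period
    D_hom_fem: float        # effective coefficient from the FEM flux
    resolved: bool


def solve_1d_oscillatory(p: OscillatoryProblem1D) -> Oscillatory1DResult:
    """P1 FEM solve and closed-form comparison.

    The exact solution is u(x) = u_l + (u_r − u_l)·F(x)/F(1) with
    F(x) = ∫₀ˣ ds/d(s/ε); the homogenized coefficient is the harmonic mean
    of d.  A mesh with h > ε/10 is flagged unresolved.
    """
    n = p.n_elements
    h = 1.0 / n
    resolved = h <= p.epsilon / 10.0
    if not resolved:
        warnings.warn("mesh does not resolve the oscillation (h > ε/10)",
                      stacklevel=2)
    x = np.linspace(0.0, 1.0, n + 1)
    xm = 0.5 * (x[:-1] + x[1:])
    d = p.d_of_x(xm)

    main = np.zeros(n + 1)
    main[:-1] += d / h
    main[1:] += d / h
    off = -d / h
    A = diags([off, main, off], offsets=[-1, 0, 1], format="csc")
    rhs = np.zeros(n + 1)
    # Dirichlet rows
    A = A.tolil()
    A.rows[0], A.data[0] = [0], [1.0]
    A.rows[n], A.data[n] = [n], [1.0]
    rhs[0], rhs[n] = p.u_left, p.u_right
    # eliminate BC coupling for symmetry of the interior problem
    u = spsolve(A.tocsc(), rhs)

    # exact solution by fine quadrature of 1/d; L² error evaluated on the
    # fine grid against the piecewise-linear FEM interpolant
    nf = max(20 * n, 20000)
    xf = np.linspace(0.0, 1.0, nf + 1)
    df = p.d_of_x(0.5 * (xf[:-1] + xf[1:]))
    F = np.concatenate([[0.0], np.cumsum((1.0 / df) * (1.0 / nf))])
    u_exact_f = p.u_left + (p.u_right - p.u_left) * F / F[-1]
    u_exact = np.interp(x, xf, u_exact_f)
    u_fem_f = np.interp(xf, x, u)
    l2 = float(np.sqrt(np.trapezoid((u_fem_f - u_exact_f) ** 2, xf)))

    # homogenized coefficient: analytic harmonic mean vs FEM flux
    yf = np.linspace(0.0, 1.0, 20001)
    dy = p.coefficient(0.5 * (yf[:-1] + yf[1:]))
    d_harm = float(1.0 / np.mean(1.0 / np.asarray(dy)))
    flux = d * np.diff(u) / h  # constant in exact arithmetic
    D_hom_fem = float(np.mean(flux) / (p.u_right - p.u_left)) \
        if p.u_right != p.u_left else float("nan")

    return Oscillatory1DResult(x, u, u_exact, l2, d_harm, D_hom_fem, resolved)
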