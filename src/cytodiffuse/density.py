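"""Macroscopic actin density fields as Gaussian mixtures.

The coarse actin distribution over a cell is represented as a mixture of K
two-dimensional Gaussians,

    p(x) = Σ_k b_k N(x | μ_k, Σ_k),     Σ_k b_k = 1,

fitted to a nonnegative intensity raster by expectation-maximization with
the raster interpreted as a weighted sample, followed by a nonnegative
least-squares refinement of the weights.  The mixture is convenient to
perturb: scaling every weight b_k rescales the total filament amount
(weights are deliberately *not* renormalized), while scaling the
covariances spreads or concentrates the same amount of actin.

Filament densities are anchored so that the maximum of the *unperturbed*
reference field maps to 1430 filaments/μm³ (≈ 40 mg/ml F-actin); perturbed
fields may therefore exceed the anchor.

``synth_cell_map`` generates reproducible synthetic cell maps — a smoothed
convex polygon ~45 μm across with cortically biased high-density patches —
so that no external imaging data is required.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import nnls
from shapely.geometry import Point, Polygon

from cytodiffuse.network import NetworkSpec

MAX_FILAMENTS_PER_UM3 = 1430.0


@dataclass
class DensityRaster:
    """Nonnegative density samples on a regular grid."""

    origin: np.ndarray           # (2,) μm, centre of pixel (0, 0)
    spacing: float               # μm/px
    values: np.ndarray           # (nx, ny), values[i, j] at origin + (i, j)·spacing
    normalized: bool = False

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if np.any(self.values < 0):
            raise ValueError("raster values must be nonnegative")

    def pixel_centers(self) -> np.ndarray:
        nx, ny = self.values.shape
        xs = self.origin[0] + np.arange(nx) * self.spacing
        ys = self.origin[1] + np.arange(ny) * self.spacing
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        return np.stack([X.ravel(), Y.ravel()], axis=1)

    def normalized_copy(self) -> "DensityRaster":
        tot = self.values.sum() * self.spacing**2
        if tot <= 0:
            raise ValueError("cannot normalize an all-zero raster")
        return DensityRaster(self.origin, self.spacing, self.values / tot, True)


@dataclass
class GMMDensity:
    """Gaussian-mixture density field over a cell polygon."""

    weights: np.ndarray                 # (K,)
    means: np.ndarray                   # (K, 2) μm
    covariances: np.ndarray             # (K, 2, 2) μm²
    cell_polygon: Polygon
    max_reference: float | None = None  # max p over Ω of the unperturbed field

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        for S in self.covariances:
            if np.linalg.eigvalsh(S)[0] <= 0:
                raise ValueError("covariances must be SPD")

    @property
    def K(self) -> int:
        return len(self.weights)

    def __call__(self, x) -> np.ndarray | float:
        """Evaluate p(x) for x of shape (2,) or (n, 2)."""
        pts = np.atleast_2d(np.asarray(x, dtype=float))
        out = np.zeros(len(pts))
        for b, m, S in zip(self.weights, self.means, self.covariances):
            out += b * _gauss2(pts, m, S)
        return float(out[0]) if np.asarray(x).ndim == 1 else out

    def max_over_domain(self, n_grid: int = 200) -> float:
        """Max of p on a grid over the cell polygon's bounding box."""
        x0, y0, x1, y1 = self.cell_polygon.bounds
        xs = np.linspace(x0, x1, n_grid)
        ys = np.linspace(y0, y1, n_grid)
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        vals = self(np.stack([X.ravel(), Y.ravel()], axis=1))
        return float(vals.max())

    def reference(self) -> float:
        if self.max_reference is None:
            self.max_reference = self.max_over_domain()
        return self.max_reference

    def cumulative_over_domain(self, n_grid: int = 200) -> float:
        """∫_Ω p dx on a grid restricted to the cell polygon."""
        import shapely

        x0, y0, x1, y1 = self.cell_polygon.bounds
        xs = np.linspace(x0, x1, n_grid)
        ys = np.linspace(y0, y1, n_grid)
        dx = (xs[1] - xs[0]) * (ys[1] - ys[0])
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel()], axis=1)
        shapely.prepare(self.cell_polygon)
        inside = shapely.contains_xy(self.cell_polygon, pts[:, 0], pts[:, 1])
        return float(self(pts)[inside].sum() * dx)

    def to_json(self) -> str:
        import json

        return json.dumps({
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "cell_polygon": list(self.cell_polygon.exterior.coords),
            "max_reference": self.max_reference,
        })

    @classmethod
    def from_json(cls, text: str) -> "GMMDensity":
        import json

        d = json.loads(text)
        return cls(
            np.asarray(d["weights"]), np.asarray(d["means"]),
            np.asarray(d["covariances"]), Polygon(d["cell_polygon"]),
            d.get("max_reference"),
        )


def _gauss2(pts: np.ndarray, m: np.ndarray, S: np.ndarray) -> np.ndarray:
    d = pts - m
    Sinv = np.linalg.inv(S)
    q = np.einsum("ni,ij,nj->n", d, Sinv, d)
    norm = 2.0 * np.pi * np.sqrt(np.linalg.det(S))
    return np.exp(-0.5 * q) / norm


def _kmeanspp(pts: np.ndarray, w: np.ndarray, K: int,
              rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding on weighted points."""
    centers = [pts[rng.choice(len(pts), p=w / w.sum())]]
    for _ in range(1, K):
        d2 = np.min(
            [np.sum((pts - c) ** 2, axis=1) for c in centers], axis=0
        )
        prob = w * d2
        tot = prob.sum()
        if tot <= 0:
            centers.append(pts[rng.integers(len(pts))])
        else:
            centers.append(pts[rng.choice(len(pts), p=prob / tot)])
    return np.array(centers)


def fit_gmm(
    raster: DensityRaster,
    K: int,
    tol: float = 1e-7,
    max_iter: int = 500,
    n_restarts: int = 3,
    seed: int = 0,
    cell_polygon: Polygon | None = None,
    refine_weights: bool = True,
) -> tuple[GMMDensity, float]:
    """Weighted EM fit of a K-component mixture to a raster.

    The raster is normalized to unit mass and treated as a weighted sample
    of pixel centres.  EM (with k-means++ style initialization on
    intensity-weighted pixels, best of ``n_restarts`` by log-likelihood)
    runs until the relative change of the weighted log-likelihood drops
    below ``tol``; a nonnegative least-squares pass then refines the
    weights against the raster.  Returns the mixture and the coefficient of
    determination R² between p(x) and the raster on the pixel grid.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    norm = raster if raster.normalized else raster.normalized_copy()
    pts = norm.pixel_centers()
    w = norm.values.ravel() * norm.spacing**2  # pixel masses, sum to 1
    keep = w > 0
    pts_k, w_k = pts[keep], w[keep]
    if K > keep.sum():
        raise ValueError("K exceeds the number of informative pixels")

    span = max(np.ptp(pts_k[:, 0]), np.ptp(pts_k[:, 1]), norm.spacing)
    reg = (0.25 * norm.spacing) ** 2  # covariance floor: sub-pixel scale

    best = None
    rng_master = np.random.default_rng(seed)
    for _ in range(n_restarts):
        rng = np.random.default_rng(rng_master.integers(2**31))
        mu = _kmeanspp(pts_k, w_k, K, rng)
        cov = np.tile(np.eye(2) * (span / max(K, 2)) ** 2, (K, 1, 1))
        b = np.full(K, 1.0 / K)
        ll_prev = -np.inf
        trace = []
        for _it in range(max_iter):
            # E step
            comp = np.stack(
                [b[k] * _gauss2(pts_k, mu[k], cov[k]) for k in range(K)], axis=1
            )
            tot = comp.sum(axis=1)
            tot = np.where(tot <= 0, 1e-300, tot)
            ll = float((w_k * np.log(tot)).sum())
            trace.append(ll)
            resp = comp / tot[:, None]
            # M step with pixel masses
            rw = resp * w_k[:, None]
            Nk = rw.sum(axis=0)
            Nk = np.where(Nk <= 0, 1e-300, Nk)
            b = Nk / Nk.sum()
            mu = (rw.T @ pts_k) / Nk[:, None]
            for k in range(K):
                d = pts_k - mu[k]
                cov[k] = (rw[:, k, None] * d).T @ d / Nk[k] + reg * np.eye(2)
            if ll - ll_prev < tol * abs(ll) and _it > 2:
                break
            ll_prev = ll
        if best is None or ll > best[0]:
            best = (ll, b.copy(), mu.copy(), cov.copy(), list(trace))

    _, b, mu, cov, ll_trace = best

    if refine_weights:
        # nonnegative least squares of the raster on the component pdfs
        A = np.stack([_gauss2(pts, mu[k], cov[k]) for k in range(K)], axis=1)
        target = norm.values.ravel()
        coef, _ = nnls(A, target)
        if coef.sum() > 0:
            b = coef / coef.sum()

    poly = cell_polygon
    if poly is None:
        x0 = pts[:, 0].min() - norm.spacing / 2
        x1 = pts[:, 0].max() + norm.spacing / 2
        y0 = pts[:, 1].min() - norm.spacing / 2
        y1 = pts[:, 1].max() + norm.spacing / 2
        poly = Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])
    g = GMMDensity(b, mu, cov, poly)
    g.em_loglik_trace = ll_trace  # weighted log-likelihood per EM iteration
    pred = g(pts)
    target = norm.values.ravel()
    ss_res = float(np.sum((target - pred) ** 2))
    ss_tot = float(np.sum((target - target.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    g.reference()
    return g, r2


def perturb_gmm(g: GMMDensity, b_scale: float, sigma_scale: float) -> GMMDensity:
    """Scale all weights by ``b_scale`` and all covariances by ``sigma_scale``.

    Weights are *not* renormalized: b_scale rescales the total actin amount,
    while sigma_scale redistributes it (larger covariances damp the peaks).
    The density anchor of the unperturbed reference is preserved so that
    perturbed fields can exceed the reference maximum.
    """
    if b_scale <= 0 or sigma_scale <= 0:
        raise ValueError("perturbation factors must be positive")
    out = GMMDensity(
        g.weights * b_scale,
        g.means.copy(),
        g.covariances * sigma_scale,
        g.cell_polygon,
        g.reference(),
    )
    return out


def density_to_spec(
    g: GMMDensity,
    x,
    base: NetworkSpec | None = None,
) -> NetworkSpec:
    """Network spec at macroscopic position x.

    filaments/μm³ = 1430 · p(x)/max(p_ref), anchored to the *unperturbed*
    reference maximum stored on the mixture.
    """
    x = np.asarray(x, dtype=float)
    if not g.cell_polygon.covers(Point(x)):
        raise ValueError("position lies outside the cell polygon")
    ref = g.reference()
    dens = MAX_FILAMENTS_PER_UM3 * float(g(x)) / ref
    if base is None:
        base = NetworkSpec(filaments_per_um3=dens)
    else:
        base = replace(base, filaments_per_um3=dens)
    return base


def _smoothed_ellipse(
    rng: np.random.Generator,
    semi_axes=(22.5, 16.0),
    n_vertices: int = 96,
    wobble: float = 0.06,
) -> Polygon:
    """Convex-ish smoothed ellipse polygon centred at the origin offset."""
    t = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    # low-order Fourier perturbation of the radius, kept small for convexity
    a1, a2 = rng.uniform(-wobble, wobble, 2)
    p1, p2 = rng.uniform(0, 2 * np.pi, 2)
    rmod = 1.0 + a1 * np.cos(2 * t + p1) + a2 * np.cos(3 * t + p2)
    x = semi_axes[0] * rmod * np.cos(t) + semi_axes[0]
    y = semi_axes[1] * rmod * np.sin(t) + semi_axes[1]
    return Polygon(np.stack([x, y], axis=1)).buffer(0)


def synth_cell_map(
    n_components: int = 12,
    cell_shape: tuple[float, float] = (22.5, 16.0),
    seed: int = 0,
    cortical_bias: float = 0.65,
    sigma_range: tuple[float, float] = (1.5, 4.0),
) -> GMMDensity:
    """Reproducible synthetic whole-cell actin density map.

    Emulates the qualitative structure of cortical actin imaging: a convex
    smoothed-ellipse cell outline (~45 μm across by default) with Gaussian
    density patches biased towards the cell boundary (radial positions drawn
    with density ∝ r^(1/(1−bias)) inside the outline) and random SPD
    covariances of a few μm.  Purely synthetic plumbing — a stand-in for
    unpublished imaging-derived fields.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    rng = np.random.default_rng(seed)
    poly = _smoothed_ellipse(rng, cell_shape)
    cx, cy = poly.centroid.x, poly.centroid.y

    means = []
    while len(means) < n_components:
        ang = rng.uniform(0, 2 * np.pi)
        # radial coordinate biased towards the boundary
        u = rng.uniform() ** (1.0 / (1.0 + 4.0 * cortical_bias))
        r = u * 0.92
        p = np.array([cx + r * cell_shape[0] * np.cos(ang),
                      cy + r * cell_shape[1] * np.sin(ang)])
        if poly.covers(Point(p)):
            means.append(p)
    means = np.array(means)

    covs = []
    for _ in range(n_components):
        s1, s2 = rng.uniform(*sigma_range, 2)
        th = rng.uniform(0, np.pi)
        Q = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        covs.append(Q @ np.diag([s1**2, s2**2]) @ Q.T)
    covs = np.array(covs)

    w = rng.dirichlet(np.full(n_components, 2.0))
    g = GMMDensity(w, means, covs, poly)
    g.reference()
    return g
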