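"""Power-law surrogate for the effective diffusivity, and Stokes–Einstein.

Across random obstacle microstructures the homogenized diffusivity is
captured remarkably well by a two-parameter law in the inaccessible area
fraction φ alone:

    tr(D0) / (d · D_free) = (1 − φ/φc)^μ / (1 − φ),   φ < φc,

with the critical (percolation) fraction φc at which finite-size tracers
become trapped, and an empirical exponent μ.  Both parameters are obtained
by constrained nonlinear least squares (0 ≤ φc ≤ 1, μ ≥ 0).

The free-solution diffusivity of a spherical vesicle of radius R follows
Stokes–Einstein, D = k_B·T/(6πηR).  For R = 10 nm in water-like cytosol at
37 °C (η = 0.692 mPa·s, T = 310.15 K) this gives ≈ 32.8 μm²/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

BOLTZMANN_J_PER_K = 1.380649e-23


@dataclass(frozen=True)
class PhysicalConstants:
    """SI inputs of the Stokes–Einstein relation."""

    k_B: float = BOLTZMANN_J_PER_K  # J/K
    T: float = 310.15               # K
    eta: float = 6.92e-4            # Pa·s
    vesicle_radius: float = 1e-8    # m

    def __post_init__(self):
        if min(self.k_B, self.eta, self.vesicle_radius) <= 0 or self.T < 0:
            raise ValueError("physical constants must be positive (T >= 0)")


@dataclass(frozen=True)
class PowerLawParams:
    phi_c: float
    mu: float
    r_squared: float = float("nan")
    n_points: int = 0

    def __post_init__(self):
        if not 0 <= self.phi_c <= 1:
            raise ValueError("phi_c must lie in [0, 1]")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")


def stokes_einstein(c: PhysicalConstants = PhysicalConstants()) -> float:
    """Free-solution diffusivity D = k_B·T/(6πηR) in μm²/s."""
    d_m2_per_s = c.k_B * c.T / (6.0 * np.pi * c.eta * c.vesicle_radius)
    return d_m2_per_s * 1e12  # m²/s → μm²/s


def power_law_rel(phi, phi_c: float, mu: float):
    """Relative diffusivity (1 − φ/φc)^μ / (1 − φ), zero beyond φc."""
    phi = np.asarray(phi, dtype=float)
    with np.errstate(invalid="ignore"):
        base = np.clip(1.0 - phi / phi_c, 0.0, None) if phi_c > 0 else np.zeros_like(phi)
        val = base**mu / (1.0 - phi)
    return np.where(phi >= phi_c, 0.0, val)


def fit_power_law(points, init=None, n_multistart: int = 5) -> PowerLawParams:
    """Constrained least-squares fit of the power law to (φ, D_rel) points.

    Box constraints 0 ≤ φc ≤ 1 and μ ≥ 0; multistart over a few initial
    (φc, μ) pairs guards against boundary traps (points beyond a candidate
    φc are predicted as zero — trapped).  R² is reported against the fitted
    curve.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need at least 3 (phi, D_rel) points")
    phi, drel = pts[:, 0], pts[:, 1]
    if np.any((phi < 0) | (phi >= 1)):
        raise ValueError("phi values must lie in [0, 1)")
    if np.ptp(phi) == 0:
        raise ValueError("degenerate input: all phi equal")

    phi_max = float(phi.max())
    lo = np.array([1e-9, 0.0])
    hi = np.array([1.0, np.inf])

    def resid(p):
        return power_law_rel(phi, p[0], p[1]) - drel

    starts = [np.array([min(phi_max + 0.1, 0.999), 1.0])]
    if init is not None:
        starts.insert(0, np.clip(np.asarray(init, dtype=float), lo, [1.0, 50.0]))
    rng_starts = np.linspace(0.05, 0.95, n_multistart)
    for f in rng_starts:
        pc = phi_max + f * (1.0 - phi_max)
        starts.append(np.array([min(pc, 0.9999), 0.5 + 2.0 * f]))

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo, np.array([1.0, 1e3]))
        try:
            res = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-14,
                                ftol=1e-14, gtol=1e-14)
        except ValueError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("power-law fit failed from every start")

    phi_c, mu = float(best.x[0]), float(best.x[1])
    pred = power_law_rel(phi, phi_c, mu)
    ss_res = float(np.sum((drel - pred) ** 2))
    ss_tot = float(np.sum((drel - drel.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return PowerLawParams(min(phi_c, 1.0), mu, r2, len(pts))


def predict_D0(phi, p: PowerLawParams, D_invitro: float,
               floor: float = 0.0) -> np.ndarray | float:
    """Effective diffusivity D_invitro·(1 − φ/φc)^μ/(1 − φ) in μm²/s.

    Beyond the percolation threshold the vesicles are trapped; the value is
    0 (or ``floor``, e.g. 1e-9·D_invitro to keep macroscopic stiffness
    matrices nonsingular).
    """
    phi_arr = np.asarray(phi, dtype=float)
    if np.any((phi_arr < 0) | (phi_arr > 1)):
        raise ValueError("phi must lie in [0, 1]")
    val = D_invitro * power_law_rel(phi_arr, p.phi_c, p.mu)
    val = np.maximum(val, floor)
    return float(val) if np.isscalar(phi) or phi_arr.ndim == 0 else val
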