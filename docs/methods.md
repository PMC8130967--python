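# Methods

`cytodiffuse` models the purely diffusive part of vesicle-mediated
transport in a eukaryotic cell whose cytoplasm is obstructed by the
cortical actin filament network. The pipeline has four stages: a stochastic
geometric model of the filament network, a morphological model of the area
a finite-size vesicle cannot occupy, numerical homogenization of obstructed
diffusion on sampling domains, and a whole-cell transport solve driven by a
two-parameter surrogate law. Units are μm, seconds and μm²/s everywhere;
SI units enter only through the Stokes–Einstein relation (SI in, μm²/s
out).

## Filament network model

F-actin is abstracted as solid cylinders of radius 5 nm inside a cubic
sampling volume of edge 1 μm. Unbranched filaments have their centres
placed uniformly in the cube and axes drawn uniformly on the sphere;
branched filaments (an Arp2/3-style fraction, default 0.25 of the total —
the branched fraction of in vivo networks is not well constrained and is a
documented free parameter) attach at a uniformly chosen point on a
previously placed parent with an inter-axis angle uniform in 65–75°.
Filament length is fixed at the mean (1.1 μm); a pluggable length sampler
is available. The filament count is exactly `round(density × volume)`
rather than a Poisson draw, so absolute counts are reproducible. Segments
are clipped to the cube; the nominal (pre-clip) lengths define the bulk
statistics, so at the cortical reference density of 1430 filaments/μm³ the
nominal cylinder volume fraction is N·πr²L/V ≈ 0.124 and the F-actin mass
density ≈ 40 mg/ml (370 monomers/μm × 42 kDa).

The headline spacing statistic, `neighbor_dist`, is the nearest-neighbour
distance between filament midpoints (≈ 47–48 nm at 1430/μm³). The minimum
axis-to-axis clearance is reported separately (`axis_gap_*`); at cortical
density it is of order 1 nm — dozens of filaments pass within tens of
nanometres of any given one, and branch children touch their parents — so
it is *not* a meaningful measure of inter-filament spacing.

All randomness derives from one root seed per realization via NumPy's
seed-sequence spawning; fixed seeds give byte-identical realizations.

## Vesicle-inaccessible area of a cross-section

A horizontal plane through the network intersects each cylinder in a conic
section: a circle for perpendicular axes, a cap-clipped ellipse for oblique
axes. Ellipse polygons are discretized with an area-compensated vertex
ring (the polygon area equals the exact conic area; boundary error is well
below 1 nm at the radii involved).

Filaments grazing the plane at less than 5° of tilt are excluded by
default. Their literal planar sections are wall-like strips up to the
filament length; such a filament spans only ~10 nm of height, so in the
100-slice stack model a vesicle passes above or below it within one slice
spacing. Keeping the strips makes single slices strongly anisotropic
(fractional anisotropy 0.05–0.25) and noisy between seeds, which the
near-isotropy of reference effective-diffusion tables rules out.
`include_grazing=True` restores the literal sections.

A vesicle of radius R cannot occupy the obstacles nor any gap narrower
than its diameter. The default blocked region is the morphological closing
of the obstacle union by a disk of radius R (dilate then erode, computed
with polygon buffers at sub-nanometre arc tolerance), which by duality is
exactly the complement of the morphological opening of the free space —
the region the vesicle body can never cover. A boundary gap equal to 2R
counts as blocked (closed condition). Two alternatives are provided: a
reachability-refined opening in which free pockets sealed off from the
slice boundary also count as inaccessible, and the proximity-graph
heuristic (links between obstacles with gaps < 2R pruned to node degree
≤ 2, narrowest first, each retained link filled with the tangent-vesicle
wedge, i.e. the joint closing of the pair, plus sealed-pocket filling).
The graph heuristic reproduces a later trapping point but its φ(R) curve
saturates far below 1 at cortical density, so the exact morphological
definition is the default. A pixel-raster opening implemented with exact
Euclidean distance transforms serves as an independent oracle; geometric
and raster φ agree to well within 0.02 on random fixtures.

φ(R) is non-decreasing in R, equals the obstacle area fraction at R = 0,
and rises sigmoidally towards 1 (up to a finite-window rim effect: no
obstacles are sampled outside the slice square, so its margin fills last).
The inaccessible volume of a stack is the trapezoidal aggregate of
per-slice φ over evenly spaced planes (equivalent to averaging
neighbouring slices times the slice distance for uniform spacing).

## Homogenization

Each sampling domain Kδ = [0, δ]² minus the blocked region is discretized
with a structured right-triangle P1 mesh (each grid cell split in two;
elements whose centroid falls in the blocked region are removed, leaving a
zero-flux staircase hole boundary; a low-contrast two-phase variant is
available for degenerate geometry). Periodicity is enforced exactly by
identifying opposite-boundary nodes — trivial and exact on the structured
grid, which is why no unstructured mesh generator is used. The two
corrector problems

    −∇·(D ∇χ_j) = −∇·(D e_j),  χ_j periodic, zero mean,

are solved by sparse direct factorization with one pinned degree of
freedom per connected free component (the zero mean is restored by
subtraction afterwards; only gradients enter the tensor). The homogenized
tensor is the averaged corrected flux

    D0_ij = (1/|Kδ|) ∫ D (δ_ij − ∂χ_j/∂x_i) dx.

On a perforated domain the normalizer |Kδ| is ambiguous. Dividing by the
full cell area δ² gives the Fickian flux coefficient; dividing by the free
(pore) area gives the tracer diffusivity that a mean-squared-displacement
measurement sees (the two differ by 1 − φ). The free-area convention is
the default: it is the quantity the Monte Carlo validation estimates and
the convention consistent with the reference effective-diffusion values
this model chain is built to reproduce. Both vanish at the percolation
threshold. A cell-level labelling diagnostic flags domains whose free
phase spans neither coordinate direction (`trapped`).

The solver is verified against closed forms: an empty cell returns the
microscopic tensor exactly; a laminate returns the harmonic/arithmetic
means to 1e-9; a dilute circular hole matches the Maxwell–Garnett value to
three digits; and the discrete Hill–Mandel identity — the macroscopic
flux–gradient product equals the volume average of the reconstructed
microscopic one — holds to machine precision under periodic constraints
(a consequence of Galerkin orthogonality; `hill_mandel_residual` checks
it). Staircase resolution of the thin gap fills converges first order in
h; production sweeps use h = 1/256 μm (≈ 131k elements per domain), where
the trace changes by ≲1.5% on halving h for cortical-density fixtures.

## Power-law surrogate and Stokes–Einstein

Across the sweep of sampling domains, tr(D0)/(2·D_invitro) is fitted
against φ with

    (1 − φ/φc)^μ / (1 − φ),  0 ≤ φc ≤ 1, μ ≥ 0,

by constrained nonlinear least squares with multistart (points beyond a
candidate φc are predicted as zero — trapped). The sweep picks ~20
filament densities by probing and inverting the monotone density → φ
response so that φ spans 0.03–0.50 at the reference vesicle radius
R = 10 nm. Noise-free synthetic data are recovered to 1e-6; on real
sweeps the fit is verified against a dense 2D grid search.

With the shipped default geometry the calibration lands near
φc ≈ 0.46–0.52, μ ≈ 1.5–1.8, R² ≈ 0.99 — a markedly faster decay than the
published reference values for this system (φc = 0.6209, μ = 1.183). We
believe the published mid-range values are not attainable by any
impermeable-obstacle microstructure at the stated area fractions: their
dilute slope is ≈0.9 in the tracer convention, below the rigorous
Hashin–Strikman-type lower bound of 1 (circles), and ≈1.9 in the flux
convention, below the bound of 2. The package reports what its own
pipeline computes.

The free-solution diffusivity uses D = k_B T/(6πηR) with the CODATA
Boltzmann constant (1.380649e-23 J/K), T = 310.15 K, η = 0.692 mPa·s,
giving 32.8 μm²/s for R = 10 nm. In macroscopic solves, φ ≥ φc maps to a
configurable floor (default 1e-9·D_invitro) to keep stiffness matrices
nonsingular.

## Macroscopic density field and whole-cell transport

The coarse actin density over the cell is a 2D Gaussian mixture
p(x) = Σ b_k N(x|μ_k, Σ_k). It is fitted to a nonnegative raster by
weighted EM (pixels as a weighted sample; k-means++-style seeding on
intensity-sampled pixels, three restarts, relative log-likelihood
tolerance 1e-7, covariance floor at a quarter pixel) followed by a
nonnegative least-squares refinement of the weights; R² against the raster
is reported. Perturbations scale all weights (total actin amount — the
weights are deliberately not renormalized) and/or all covariances (spatial
spread; shrinking covariances raises the peaks and vice versa). Filament
density is anchored linearly with the *unperturbed* reference maximum
mapping to 1430 filaments/μm³, so perturbed fields can exceed the anchor.

The synthetic cell-map generator emulates a cortical-actin imaging field:
a smoothed-ellipse cell outline ~45 μm across, mixture components biased
towards the boundary, random SPD covariances of 1.5–4 μm, Dirichlet
weights. It reproduces the qualitative structure (localized peripheral
density patches over a smooth background) but not the fine speckle,
hundreds-of-component complexity, or segmentation artifacts of real
confocal data — tests passing on it show the pipeline's mechanics, not
image fidelity.

The cell polygon is meshed with the same structured triangulation (max
edge ≈ 1 μm), the per-element φ field is built from the mixture (one
seeded network per element at its centroid, or a tabulated monotone
density → φ lookup for whole-cell runs; the lookup matches direct
single-element sampling to ≈0.01 in φ over the in vitro density range),
and the homogenized diffusion problem is integrated by backward Euler with
a lumped mass matrix (discrete maximum principle at any step; total mass
conserved exactly in closed cells). Dirichlet data are imposed strongly;
the standard uptake experiment sets u = 1 on the whole membrane, u0 = 0,
f = 0, dt = 0.01 s. Traveling times interpolate linearly in time and P1 in
space. The first-order corrector u⁰ − Σ χ_j ∂_j u⁰ reconstructs the
fine-scale field within a sampling domain.

## Validation

Monte Carlo: point tracers random-walk in the blocked geometry
(periodically tiled) with Gaussian steps of σ = √(2 D dt) ≈ 0.5 nm and a
Metropolis reject-and-stay rule at obstacles — the rule whose stationary
law is uniform on the free space, which equilibrium MSD estimation
requires (resample-until-accept would violate detailed balance at walls;
it is therefore not offered). The tensor comes from time-averaged
displacement moments ⟨Δx_i Δx_j⟩(τ) = 2 D_ij τ fitted through the origin
over a window of lags, with bootstrap standard errors over walkers; the
time averaging multiplies the effective sample count severalfold. A
numba-compiled kernel performs the stepping (a vectorized NumPy fallback
is included). In free space the estimator is unbiased within its standard
error, and in a sealed cage the apparent slope decays as 1/T (MSD
plateau).

For the cross-method check, the FEM and the walker share one pixel mask of
the blocked region (mask at 1/128 μm, FEM at h = 1/512 so each pixel is
resolved by 32 elements). Sharing the discrete geometry isolates method
error from geometry-resolution error — the closing construction produces
zero-width cusps that any finite resolution breaks differently, which
otherwise dominates the comparison at cortical density. Over the in vitro
density range (0.2–1.0× cortical) the two methods agree within 3%
(typically ≤1.5%, MC standard error ≈1%).

The 1D verification solves −(d(x/ε) u′)′ = 0 with P1 elements against the
closed form u = A∫dx/d + B; the homogenized coefficient equals the
harmonic mean of d, and the L² error converges at second order for smooth
coefficients (for element-aligned piecewise-constant coefficients the P1
solution is nodally exact, so the convergence study uses a smooth
oscillatory coefficient).

## Known limitations

- The 2D slice surrogate cannot represent out-of-plane detours; the
  grazing-section exclusion is a regularization of exactly that artifact.
- Hole boundaries are staircase approximations; effective tensors carry an
  O(h) geometric bias (~1–2% at production resolution), absorbed into the
  calibration scatter.
- The power-law surrogate is isotropic by construction; strongly
  anisotropic networks (e.g. with directional growth) are out of scope.
- The macroscale model is 2D and purely diffusive: no motor-protein
  advection, no microtubules or intermediate filaments, no organelles, and
  the cytoskeleton is frozen over the simulated time window.
- Enclosed free pockets conduct nothing in the FEM regardless of the
  accessibility method; only the φ bookkeeping differs between methods.
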