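# cytodiffuse

Multiscale finite-element modelling of diffusive vesicle transport through
the actin cytoskeleton of a eukaryotic cell.

Intracellular transport vesicles (20–100 nm across) that are not riding
motor proteins move by Brownian diffusion through a cytoplasm crowded with
cortical actin filaments. Because a vesicle has finite size, it is excluded
not only from the filaments themselves but from every gap narrower than its
own diameter; the fraction of a cross-section it can never occupy — the
inaccessible area fraction φ — controls how strongly the network slows it
down. `cytodiffuse` is for computational biophysicists who want to ask
*how a change in cytoskeletal density changes transport times*: it builds
stochastic filament networks from experimentally motivated parameters,
computes φ for a given vesicle radius, homogenizes the obstructed diffusion
problem, and propagates the result to whole-cell concentration dynamics.

## Model chain

1. **Network geometry** — F-actin as solid cylinders (radius 5 nm, length
   1.1 μm) in a 1 μm³ sampling cube; isotropic axes, Arp2/3-style branching
   at 65–75°. At the cortical reference density of 1430 filaments/μm³ this
   gives a volume fraction ≈ 0.124 and ≈ 40 mg/ml F-actin.
2. **Accessibility** — for a slice through the network, the blocked region
   is the morphological closing of the obstacle union by a disk of the
   vesicle radius R, i.e. the complement of the opening of the free space:
   obstacles plus all gaps narrower than 2R.
3. **Homogenization** — on each sampling domain Kδ the periodic correctors
   χ_j solve −∇·(D∇χ_j) = −∇·(D e_j) on the perforated cell (P1 FEM,
   periodic constraints by DOF identification), and

       D⁰_ij = (1/|Kδ|) ∫ D (δ_ij − ∂χ_j/∂x_i) dx

   with the free-area normalizer (tracer convention). Fractional
   anisotropy FA = (λ₁−λ₂)/√(λ₁²+λ₂²) quantifies isotropy, and the
   Hill–Mandel macro-homogeneity condition holds to machine precision.
4. **Surrogate law** — across many sampling domains the relative
   diffusivity collapses onto the two-parameter form

       tr D⁰ / (2 D_free) = (1 − φ/φc)^μ / (1 − φ)

   with a critical (percolation) fraction φc at which vesicles are
   trapped. Once calibrated, whole-cell runs need only φ(x).
5. **Whole-cell transport** — ∂u/∂t = ∇·(D⁰(x)∇u) on a cell polygon
   (Gaussian-mixture actin density → per-element φ → D⁰), P1 Galerkin in
   space, backward Euler in time; readouts are concentration fields and
   traveling times to a probe point.

A Monte Carlo random-walk estimator and a closed-form 1D oscillatory
problem validate the homogenization machinery independently.

## Worked example

```python
import numpy as np
from cytodiffuse import (NetworkSpec, generate_network, network_statistics,
    slice_cross_sections, inaccessible_region, homogenize_blocked_geometry,
    stokes_einstein)

spec = NetworkSpec(filaments_per_um3=1430, seed=7)
net = generate_network(spec)
stats = network_statistics(net)
print(f"volume fraction: {stats.volume_fraction:.4f}")
print(f"F-actin mass density: {stats.mass_density:.1f} mg/ml")
print(f"neighbor spacing: {stats.neighbor_dist_mean*1e3:.1f} nm")

obstacles = slice_cross_sections(net, z=0.5)
blocked = inaccessible_region(obstacles, R=0.010)   # 10 nm vesicle
print(f"inaccessible fraction: {blocked.phi:.4f}")

D_free = stokes_einstein()                           # 32.8 um^2/s
tensor = homogenize_blocked_geometry(blocked, target_h=1/256, D_micro=D_free)
print(f"effective D tensor (um^2/s):\n{np.round(tensor.D0, 2)}")
print(f"fractional anisotropy: {tensor.FA:.4f}")
```

prints

```
volume fraction: 0.1235
F-actin mass density: 40.6 mg/ml
neighbor spacing: 48.2 nm
inaccessible fraction: 0.0866
effective D tensor (um^2/s):
[[26.88  0.36]
 [ 0.36 27.43]]
fractional anisotropy: 0.0237
```

Reading: the cortical network occupies ~12% of the volume; a 10 nm vesicle
additionally loses the narrow gaps, so ~8.7% of the slice is off limits,
and its free diffusivity of 32.8 μm²/s drops to ≈ 27 μm²/s, nearly
isotropically (FA ≈ 0.02).

Command-line entry points wrap the same calls: `cytodiffuse netgen`,
`fitlaw`, `densitysynth`, `densityperturb`, `celltransport`, and
`cytodiffuse experiment <name>` for the seeded end-to-end pipelines
(power-law sweep, φ(R) curves, perturbation table, Monte Carlo validation,
1D verification).

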