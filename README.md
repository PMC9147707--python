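# ionatmos

Analysis of the counterion atmosphere around a pair of parallel DNA duplexes
from molecular-dynamics trajectories — and a synthetic Brownian-dynamics
generator that reproduces the geometry of that system with known ground
truth, so every estimator in the package has a recovery test that needs no
external data.

Like-charged double helices attract under the right ionic conditions, and
the attraction lives in the details of the ion atmosphere: where the Na⁺
ions sit, how strongly they fluctuate, and how fast they move in the minor
groove, the major groove and the interface between the two duplexes.  The
package implements the post-processing side of that analysis for
trajectories of two parallel duplexes (modelled as cylinders of radius
R_DNA = 10 Å, axes along z, at interhelical distance d):

- **Zone bookkeeping** — inside/interface/non-interface partition of a
  1.0 Å grid (interface ownership split at the midpoint of the two helical
  centers' x coordinates), parametric minor/major groove shells, RMSD/RMSF.
- **Densities** — voxel number densities; the Gaussian coarse-grained
  density field ρ̄(r,t) = Σᵢ (2πξ²)^(−3/2) exp(−|r−rᵢ(t)|²/2ξ²) with
  ξ = 3.0 Å; radial shell profiles at 0.5 Å spacing restricted to
  hemicylinders.
- **Fluctuation entropy** — treating density fluctuations δρ as
  multivariate Gaussian, S = const + (k_B/2) ln|Σ| with
  Σᵢⱼ = ⟨δρᵢδρⱼ⟩; on matched point sets the constant cancels in
  ΔS = S(flexible) − S(rigid), reported with a nine-block jackknife SE.
- **Local dynamics** — the grid-localized diffusion estimator
  6D_uvw = ⟨(r(t₂)−r(t₀))² − (r(t₁)−r(t₀))²⟩/(t₂−t₁) with capture radius
  1.0 Å, t₁ = 1 ps, t₂ = 2 ps; a nine-block occupancy-consistency filter
  (≥ 70% of blocks); weighted six-neighbor site merging to > 2.8 Å
  separation; localized residence times.
- **Energetics** — per-ion electrostatic energies by standard Ewald
  summation (Coulomb constant 332.0637 kcal·Å/(mol·e²)) deposited per
  voxel, and Lennard-Jones decomposition (12 Å cutoff, Lorentz–Berthelot
  with NBFIX-style pair overrides).
- **PMF assembly** — mean-force accumulation in 0.1 Å bins over
  d ∈ [21, 31] Å, stitching of consecutive windows, trapezoid integration
  anchored to zero at 31 Å, Anderson–Darling normality and
  sampling-uniformity diagnostics, block-variance uncertainty propagation.
- **Effect statistics** — Wilcoxon rank-sum tests and Cliff's delta with
  95% confidence intervals and the conventional 0.11/0.28/0.43 magnitude
  thresholds, per zone.

The synthetic generator (`ionatmos.synthetic`) produces overdamped-Langevin
ion trajectories around charged cylinders with position-dependent mobility
(slow groove shell ≈ 0.06 Å²/ps, bulk ≈ 0.21 Å²/ps), rigid or thermally
jittered surface charges, written as PDB + DCD so synthetic and real data
flow through the same loader.

## Worked example

```python
import numpy as np
from ionatmos import (free_scene, simulate_ion_cloud, local_diffusion_map,
                      GridSpec, gaussian_field_series, entropy_difference,
                      cliffs_delta, delta_to_exceedance_probability)

# recover a known diffusion coefficient from a force-free ion cloud
tr = simulate_ion_cloud(free_scene(box=(15., 15., 15.), D=0.20, n_ions=200,
                                   n_frames=20000, frame_interval=1.0, seed=1))
grid = GridSpec(origin=(4., 4., 4.), spacing=2.0, shape=(4, 4, 4),
                box_lengths=(15., 15., 15.))
dmap = local_diffusion_map(tr, "na", grid)
print(f"median local D: {np.nanmedian(dmap.D):.3f} A^2/ps "
      f"({int(dmap.n_events.min())}+ events/point)")

# entropy difference of two density-fluctuation ensembles (truth: 10 kB)
flex = gaussian_field_series(np.eye(10) * np.e**2, 50000, seed=2)
rigid = gaussian_field_series(np.eye(10), 50000, seed=3)
res = entropy_difference(flex, rigid, region="demo")
print(f"delta S = {res.delta_S:.2f} +/- {res.standard_error:.2f} kB")

# effect size of a flexible-vs-rigid site comparison
r = cliffs_delta([0.08, 0.11, 0.10, 0.14], [0.05, 0.07, 0.09, 0.06])
print(f"Cliff's delta = {r.delta:.3f} [{r.ci_low:.2f}, {r.ci_high:.2f}] "
      f"({r.magnitude}), P(exceed) = {delta_to_exceedance_probability(r.delta):.2f}")
```

Output:

```
median local D: 0.200 A^2/ps (4629+ events/point)
delta S = 10.00 +/- 0.01 kB
Cliff's delta = 0.875 [0.41, 0.98] (large), P(exceed) = 0.94
```

The median recovered diffusion coefficient matches the generator's ground
truth (0.20 Å²/ps); ΔS reproduces the analytic (n/2)·ln(variance ratio);
the effect size says a randomly chosen flexible site beats a rigid one 94%
of the time, with a CI that excludes zero.

## Command line

`ionatmos all --config run.toml --out results/` runs the whole pipeline
(synthetic rigid + flexible scene pair through density, entropy, diffusion,
energetics, PMF and stats, with a provenance manifest); the verbs
`simulate`, `density`, `entropy`, `diffusion`, `energetics`, `pmf` and
`stats` run single stages.  Configs are TOML or JSON; every value has a
sensible default, so `ionatmos all --out demo/` works as-is.

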