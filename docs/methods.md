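# Methods

This note documents the models, estimators and numerical choices behind
`ionatmos`, and what the synthetic generator does and does not emulate.

## System model and units

Two parallel double helices are idealized as cylinders of radius
R_DNA = 10 Å with axes along z, located by helical centers c₁, c₂ and
separated by the interhelical distance d (center to center, 21–31 Å in the
analyses this package targets).  Units are Å, ps, kcal/mol, elementary
charge e, and k_B for entropies; the Coulomb constant is
332.0637 kcal·Å/(mol·e²), k_BT = 0.616 kcal/mol at 310 K.

## Spatial zones

Grid points are voxel centers with half-open ownership
[c − s/2, c + s/2); the default spacing is 1.0 Å.  A point is *inside* a
duplex when its in-plane distance to that center is < R_DNA.  The
*interface* is the band of exterior points with x strictly between the two
centers' x and |y − y_axis| ≤ R_DNA; the y-extent is this package's
construction (the zone is usually drawn only as the slab between the
cylinders), and ownership splits at the midpoint x, ties to duplex 1, to
keep the rule deterministic.  All remaining exterior points belong to the
*non-interface* zone of the duplex on their side of the midpoint, which
makes the five labels an exact partition of any grid.

Minor/major groove labels live on a configurable radial shell
(default 10–14 Å from the nearer axis).  Each shell point is classified by
its azimuth relative to the two backbone strands' phase angles at its own
height (rise 3.4 Å, twist 36°/step, strand phases 0° and 120° by default):
the narrower inter-strand sector is the minor groove.  No standard
definition exists for groove membership of grid voxels, so the sector rule
is parametric and is validated against an independent atom-based oracle
(the pair of backbone crossings bracketing a point vertically at its
azimuth: a ≈ 11.3 Å gap marks the minor groove, ≈ 22.7 Å the major, for a
34 Å pitch).

RMSD is computed without a superposition fit: the intended systems are
restrained in global position and orientation, so raw deviations are the
meaningful quantity.

## Density fields

Voxel number density is the time-averaged count per voxel volume.  The
coarse-grained field sums a normalized 3-D Gaussian of width ξ = 3.0 Å
over all ions at minimum-image distance, truncated at 4ξ without
renormalization (truncation error < 10⁻⁴ of the peak value).  Minimum
image is used rather than a full lattice sum because the duplexes are
periodic through the boundary and ξ ≪ box.  Radial profiles average voxel
*values* over 0.5 Å cylindrical shells; voxels never visited are excluded
rather than averaged as zeros, and empty shells are reported missing — a
zero would bias profiles low exactly where sampling is worst.

## Fluctuation entropy

Density fluctuations in small volumes are treated as multivariate
Gaussian, so S = const + (k_B/2) ln|Σ| with Σ the covariance of δρ at the
chosen points.  The constant depends only on grid spacing and point count
and cancels in ΔS between two systems evaluated on identical point sets;
mismatched point sets are rejected rather than subsampled.  Choices the
underlying theory leaves open, made here once:

- covariance by the unbiased 1/(T−1) estimator;
- a ridge εI added only when the smallest eigenvalue falls below
  ε_floor = 10⁻³ × median diagonal (recorded in the result); constant
  series are flagged but not fatal;
- log-determinant via `slogdet`, never the raw determinant;
- the SE of ΔS by a delete-one jackknife over nine contiguous time blocks,
  matching the nine-block convention used for the dynamics filters.

ΔS is invariant under any common permutation or invertible linear map of
the points (the Jacobian cancels), which is tested, and adding independent
noise of variance v raises S by Σ ½ ln(1 + v/λᵢ), tested against the
eigenvalue oracle.

## Grid-localized diffusion

The finite-difference estimator

    6 D_uvw = ⟨(r(t₂) − r(t₀))² − (r(t₁) − r(t₀))²⟩ / (t₂ − t₁)

is accumulated over every capture event (ion within 1.0 Å of the grid
point at t₀; overlapping origins allowed), with t₁ = 1 ps, t₂ = 2 ps.
Displacements use periodically unwrapped coordinates; capture uses wrapped
ones.  The absolute value is applied to the *averaged* difference: applied
per event it would bias D upward at low counts (the per-event reading is
available behind `abs_mode="per_event"`).  On force-free Brownian motion
the signed-mean estimator is exactly unbiased for any t₁ < t₂.  Points
with fewer than 10 events are not reported.

Noise control follows the block protocol: equal-frame ninths of the
trajectory, a point retained when it has events in
≥ ceil(0.7 × 9) = 7 blocks ("presence in ≥ 70% of blocks" is one of two
possible readings of the filter; the other — value agreement — is noted,
not implemented).  Retained points are merged by weighted averaging of up
to six nearest neighbors until all sites are > 2.8 Å apart, processing the
closest offending pair first with ties broken by lowest index, which makes
the result order-independent and reproducible; total event weight is
conserved and merged sites stay in the convex hull of their contributors.

Residence times are maximal visits of one ion within 1.0 Å of a site,
bridging interruptions of up to 2 frames (0.2 ps at the 0.1 ps save
interval) to suppress single-frame boundary flicker.

## Energetics

Per-particle electrostatics use classic Ewald summation in an orthorhombic
periodic box.  Alpha comes from the error-balance heuristic
erfc(α·r_c) ≈ target with r_c = min(L)/2, the reciprocal cutoff from the
matching Gaussian tail, and an explicit convergence check rejects an
undersized k-space.  A particle's energy against a partner group is the
pair sum C qᵢqⱼψ(rᵢⱼ) plus, when the subject's own group is among the
partners, its interaction with its own periodic images C qᵢ²ψ₀
(`self_images="auto"`); with that bookkeeping, energies against a
partition of the partner set add up exactly to the energy against the
union, and the total cell energy of a rocksalt lattice reproduces the
Madelung constant to < 10⁻⁵ relative.  For a well-separated neutral pair
the self-image term cancels the leading finite-box correction, so the pair
energy approaches bare Coulomb as the box grows.

Lennard-Jones energies use the ε/r_min form with Lorentz–Berthelot
combination unless a symmetric pair override is declared, and a plain
(unshifted) 12 Å cutoff; the decompositions of interest are differences at
matched settings, which are insensitive to the tail treatment.  Voxel
energy maps deposit each subject ion's Ewald energy (partners: the two
duplexes and the other cations by default; anions and water are excluded
by default and configurable) at its voxel; unvisited voxels are missing,
not zero.  No intramolecular exclusions are applied to synthetic scenes,
which have no bonded topology.

## PMF assembly

Force samples are accumulated in half-open 0.1 Å bins over [21, 31] Å;
out-of-range samples are tallied and dropped.  Consecutive,
non-overlapping windows are concatenated at force level (no offsets
needed); PMF-level windows are offset-matched at shared boundaries.  The
PMF is the trapezoid integral of the mean force from the largest-d bin
(anchored to 0 there), exact for piecewise-linear force — higher-order
schemes add nothing at 0.1 Å resolution.  Per-bin force SEs come from the
variance of nine block means of each bin's sample stream, a practical
stand-in for the established mean-force error estimator that is cited in
this literature without a restated formula, and are propagated through the
trapezoid weights as independent bins, giving an uncertainty that grows
monotonically away from the anchor.  Convergence diagnostics report
Anderson–Darling normality per bin at the 5% level (the normality
*criterion* is standard; the choice of test is ours) and a min/median
bin-count uniformity ratio.

## Effect statistics

Cliff's delta is computed by exhaustive sign counting over all pairs (ties
contribute 0), so it is exactly invariant under monotone transforms and
agrees with the rank-based identity δ = 2U/(n₁n₂) − 1.  The 95% CI uses
Cliff's consistent variance estimate with the asymmetric transform and
clipping to [−1, 1]; at |δ| = 1 the transform degenerates and is evaluated
at a delta shrunk as if one pair disagreed.  A percentile bootstrap is
available as an alternative.  P-values come from the two-sided
Wilcoxon/Mann-Whitney test (exact for small tie-free samples, tie-corrected
normal approximation otherwise).  Magnitude labels use the conventional
thresholds |δ| ≥ 0.11/0.28/0.43.  No multiple-testing correction is applied
across the three zones by default.  The identity P(exceed) = (δ+1)/2 holds
in the absence of ties.

## Synthetic generator

Ions follow overdamped Langevin dynamics (Euler–Maruyama) in a periodic
box: drift D(r)F/k_BT plus, for spatially smooth mobility maps, the Itô
correction ∇D, plus Gaussian noise of variance 2D·dt per axis.  Forces are
a soft harmonic wall expelling ions from the cylinder interiors
(k = 10 kcal/mol/Ų) and force-shifted truncated Coulomb wells at the
surface charges (cutoff 12 Å, soft core 1 Å).  The well strength is
screened by an implicit-water dielectric (78.5 by default), giving
≈ 3 kcal/mol wells — without screening, bare unit charges would produce
physically meaningless ~170 kcal/mol traps in a solvent-free model.
Sub-stepping caps the RMS displacement per step at 0.25 Å so the 1.0 Å
capture-radius logic stays meaningful; the sub-step also respects a
drift-rate probe of the initial configuration, rare deep-core excursions
are clamped to the cap, and a configuration that would need more than 512
sub-steps per frame raises a step-size error naming the offending
parameters.  Force-free uniform-mobility scenes are propagated with exact
Gaussian increments — the analytic solution of the same SDE — which is
what makes ≥ 10⁴ capture events per grid point affordable in the recovery
tests.  Mobility maps are piecewise-constant profiles blended over a 2 Å
smoothing length (uniform, slow slab, slow groove shell with defaults
0.06/0.21 Å²/ps).

"Flexible" scenes jitter the surface-charge anchors with an
Ornstein–Uhlenbeck process (stationary RMS 1.0 Å — the scale of the
all-atom RMSDs the restrained duplexes show — relaxation time 5 ps);
rigid scenes keep anchors fixed.  The scene defaults are the study
conditions: a 99 × 99 × 103 Å box, cylinders at d = 22.4 Å, 0.15 M-like
NaCl (91 ion pairs) plus neutralizing counterions for the 124 backbone
charges, frames every 0.1 ps.  `init_positions="wells"` seeds one cation
just outside the wall above each surface charge; combined with deep wells
it pins the well occupancy, which is how the entropy recovery fixture
makes the rigid and flexible systems differ *only* through anchor jitter —
with free occupancy, well-exchange times of hundreds of ps would dominate
the covariance and the comparison would need orders of magnitude more
sampling.

What the generator does **not** emulate: explicit water and its hydrogen-
bond networks, all-atom DNA geometry (grooves exist only through the
angular sector construction and the helical charge placement), ion–ion
correlations (ions interact with the fixed charges but not each other),
inertial or hydrodynamic effects, and enhanced-sampling bias forces.
Passing recovery tests therefore demonstrate that the estimators recover
known transport, fluctuation and energetic ground truth from
trajectory-shaped data — not that the biophysical conclusions about real
DNA would be reproduced from these toy scenes.

## Problem sizes and determinism

The bundled demo runs two 20 000-frame (2 ns at 0.1 ps) scenes of 52 ions
in a 44.8 × 40 × 27.2 Å box — large enough that the nine-block filter
retains sites in all three zones while the whole pipeline, run twice for
the bit-identity check, stays comfortable on one CPU.  Diffusion recovery
fixtures use 1 ps frames, which keeps successive capture events nearly
independent (at 0.1 ps spacing, overlapping origins share most of their
displacement window and the effective sample count collapses).  All
randomness flows from `numpy.random.default_rng` seeds derived from the
run seed; pipeline outputs are hashed into a manifest, and reruns at a
fixed seed are bit-identical, including the PDB/DCD trajectory files and
the gzipped zone masks (written with a pinned mtime).

## Known limitations

- The groove delimitation is a geometric construction; sequence-dependent
  groove widths are out of scope.
- The Ewald implementation is plain (no mesh/FFT); it is meant for
  desk-scale systems, not 10⁵-atom frames.
- The consistent-variance CI for Cliff's delta is asymptotic; at very
  small site counts the bootstrap option is preferable.
- The block-variance PMF uncertainty treats bins as independent; weak
  cross-bin correlation from window sampling is neglected.
- `entropy_difference` compares runs of equal length; unequal-length
  comparisons are deliberately not supported because the determinant bias
  would not cancel.
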