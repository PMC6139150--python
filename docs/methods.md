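# Methods

This note records the model, the numerical choices, and the limits of what
the synthetic validation demonstrates.

## Coarse-grained model and coordinates

Each residue contributes the backbone heavy atoms N, CA, C, O as pseudo-atoms
plus one mass-weighted side-chain centroid (glycine: none); pseudo-atom
weights are the summed heavy-atom masses, so heavier groups contribute more
density (configurable to unit weights through the projection call). The
dynamics runs in Cartesian coordinates, M = 3A degrees of freedom for A
pseudo-atoms. Covalent geometry is preserved by distance constraints
generated at coarse-graining time: N–CA, CA–C, C–O, CA–centroid, the 1–3 pair
N–C within each residue, and C–N(next), CA–N(next) across each peptide bond.
The 1–3 pairs pin the bond angles that pure bond constraints would leave
free. A torsion-coordinate backend could be substituted behind the same
constraint formalism (the Jacobian interface is the general Wilson matrix,
which in Cartesian coordinates reduces to position differences); Cartesian
coordinates were chosen because every algorithm here is coordinate-agnostic
and the linear algebra stays a single sparse solve.

## Density matching

The model-induced map is the sum of normalised isotropic Gaussians
(width σ, truncated at 4σ per axis) sampled at voxel centres, so the map
integral equals the total pseudo-atom weight up to truncation error (≲0.1%
for atoms ≥4σ inside the grid). "Thresholding" always means subtract-and-clip,
max(g−T, 0): the volume counts voxels strictly above T, the integral sums
(g−T) over them, and the 95% quantile is taken over the *subtracted* values
(ascending order statistic at 1-based index ⌈0.95·V⌉, no interpolation).
Taking Q over the subtracted values is what makes the three matching
relations exactly satisfiable when the experimental map is itself a
thresholded Gaussian projection — the quantile of an already-thresholded
experimental map can only be measured on subtracted values, so the model side
must match that convention.

The solver alternates (i) rebuilding g at the current σ and setting T to the
order statistic that matches the experimental volume with (ii) one
Newton–Raphson step on σ for D(σ,T) = I₂/Q₂ − I₁/Q₁. Numerical choices:

- The central-difference derivative (h = max(0.01σ, 0.02 Å)) re-solves the
  volume-matching threshold at σ±h. Differentiating at fixed T gives a slope
  roughly twice that of the composed residual D(σ, T(σ)) and degrades Newton
  to linear convergence with rate ~1/2; tracking T restores the observed 4–6
  iteration convergence.
- Steps are damped to |Δσ| ≤ 0.5σ.
- Q₂ is an order statistic, so D has small jump discontinuities; off the
  self-consistent fixture its zero can fall inside a jump. The iteration
  therefore maintains a sign bracket on D and switches from Newton to
  bisection when the residual stalls; convergence is declared when
  |D| < 10⁻⁶·(I₁/Q₁), or when the bracket is narrower than tol_σ = 10⁻³ Å
  (the residual has then reached its discreteness floor).
- Failure modes (no convergence in 50 iterations, σ below a quarter voxel or
  above the grid extent, flat residual) raise with diagnostics.
- During refinement the solver is warm-started from the previous step's σ and
  typically converges in 1–3 iterations.

The synthetic map generator thresholds at a percentile of the strictly
positive voxel values using the 'lower' order statistic, so the threshold is
an attained map value and the generator is an exact fixed point of the
solver.

## Dynamics

One step solves the sparse saddle system for velocities and multipliers.
Parameters and choices:

- Damper strength c₀/√r along the connecting line (classic dashpot,
  projection block c·uuᵀ); c₀ = 1 by default. Because the force field is
  renormalised every step (max per-atom force = 1) and the time step is set
  by a displacement cap, c₀ only fixes units; what matters is the ratio to
  the background viscosity.
- Background viscosity V = ε·I with ε = 0.01·c₀. This regularises the damping
  matrix (B alone is PSD with rigid-motion null space) and sets how strongly
  isolated atoms resist the force field relative to collectively damped ones.
- Bonded (constrained) pairs are excluded from the damper network.
- Pairs closer than 0.1 Å get their damper strength capped (clash guard).
- dt is chosen each step so the maximum per-atom displacement is
  δ_max = 0.3 Å, and additionally capped at 20× the first accepted step's dt:
  near convergence the force field becomes balanced, velocities shrink, and
  an uncapped rescale would amplify discretisation noise into full-size
  steps.
- After the position update, constrained distances are restored by a
  Gauss–Newton projection (solve J Jᵀλ = −C, update q += Jᵀλ, iterate to
  10⁻¹⁰ relative). Tangent-space motion alone accrues second-order drift per
  step; Gauss–Seidel (SHAKE-style) sweeps stall near 10⁻⁴ relative error on
  the stiff bond/angle triangles, while the Gauss–Newton projection converges
  quadratically and keeps 1000-step drift at machine precision.
- Redundant constraint sets (e.g. rigidified elements overlapping covalent
  constraints) make the saddle matrix singular; the solve then falls back to
  the Schur complement of the always-definite damping block with a
  least-squares solve for the multipliers. The primary solve is accepted only
  if the constraint-rate postcondition |J q̇| < 10⁻⁹‖q̇‖ holds, which also
  catches near-singular factorisations.

Secondary-structure constraint modes: "endpoints" ties the terminal and
penultimate CA pairs of adjacent β-strands at both ends (4 constraints per
adjacent strand pair — enough to hold the strand register while the sheet
stays flexible); "rigidify" triangulates each helix/strand with a minimal
3-predecessor scheme (3n−6 constraints per element, every interior atom ≥4
non-coplanar partners).

## Cutoff schedule

ρ = v(t)/v(t−1) with v the RMS pseudo-atom speed from the saddle solve;
d_cut ← d_cut·ρ^{2/5}, clamped to [max(7 Å, 2σ), d_init]. Defaults:
d_init = 14 Å. The exponent follows from the aggregate damper strength
scaling C ∝ d_cut^{5/2} (strength 1/√r integrated over an r² dr shell
population). Growth is capped at d_init because an unbounded increase on a
transient velocity spike would rebuild very large networks; the floor
preserves minimum connectivity. The first step uses ρ = 1; a vanishing
previous velocity leaves the cutoff unchanged.

## Stopping criterion

The overlap metric is support coverage: the percentage of the experimental
map's positive voxels that the thresholded model map also covers. (Any
monotone saturating fit-quality series would work; coverage is cheap and
bounded.) The regression y(t) = b − c·e^{−kt} is fitted by variable
projection: for each trial k the linear pair (b, c) is solved in closed form
on the basis {1, e^{−kt}}, and the profiled RSS is minimised over
log k ∈ [−8, 2] on a 50-point grid refined by bounded 1D search. Fits are
rejected for short (<10 points) or constant series, when the optimum sits at
a bracket edge (unsaturated, k→0, or step-like series), or when c ≤ 0.
Warning and stopping times are rounded to the nearest step; the run stops
when t₂ ≤ t, and t₁ is then frozen and saved frames with t > t₁ flagged.
With the default α₁ = 0.9, α₂ = 0.99 the stopping time is exactly twice the
warning time.

## Synthetic fixtures: what they do and do not show

The generator builds idealized poly-alanine geometry: α-helices from
cylindrical parameters (1.5 Å rise, 100° twist, CA radius 2.27 Å, N/C
interpolated at ±0.38 residue with 1.9 Å radius, carbonyl O and CB placed
radially), and extended strands with 3.3 Å CA spacing and alternating
pseudo-CB sides. The hinge fixture joins two rigid helical domains by a
3-residue extended linker; the second domain's axis is tilted 30° out of the
hinge axis so a hinge rotation of θ displaces its far end substantially (for
θ = 30° and 40-residue domains the backbone RMSD is ≈6.2 Å, reported exactly
by the generator from its own rotation). The simulated map projects the
coarse-grained target at σ = R/(2√3), optionally adds Gaussian voxel noise,
and subtract-clips at a percentile threshold.

Passing the synthetic tests shows that the matching equations, constrained
dynamics, cutoff schedule and stopping rule behave as designed, and that the
pipeline recovers a piecewise-rigid hinge motion at 7 Å with an order of
magnitude RMSD reduction. It does not demonstrate performance on real maps:
simulated maps lack CTF and solvent noise, inhomogeneous resolution,
unmodelled densities (which must be removed before refinement), and the
residue-level heterogeneity of real side-chain density. Side-chain
conformations are not modelled at all — an external rotamer-optimisation
command can be hooked per saved trajectory, but is never required.

## Problem sizes

The shipped validation uses 20–100 residue fixtures, grids of 2 Å voxels, and
refinement runs of up to 500 steps (the default `max_steps`; frames saved
every 5 steps). These sizes exercise every code path; the implementation is
sparse throughout (KD-tree neighbour search, CSR damping matrix, sparse
saddle factorisation), so cost grows near-linearly in atoms for fixed
cutoff.

## Known limitations

- The overlap percentage depends on the support-coverage definition; absolute
  overlap values are not comparable across different metric definitions.
- Cartesian pseudo-atoms with distance constraints approximate, but do not
  reproduce, torsion-space kinematics; free-variable counts differ from
  torsion-coordinate implementations.
- Only orthogonal-cell maps are supported; mmCIF models, half-map validation
  and symmetry averaging are out of scope.
- The kernel width is global; maps with strongly local resolution variation
  would need per-region kernels.
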