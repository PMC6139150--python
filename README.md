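# ddflex

Flexible refinement of atomic models against medium-resolution (5–15 Å)
cryo-EM density maps by **overdamped coarse-grained dynamics**.

At these resolutions a rigidly docked atomic model often disagrees with the
map because the molecule changed conformation between the crystal and the
ice-embedded specimen. `ddflex` deforms the model into the density while
preserving its covalent geometry and local structure, and tells the user when
to stop before the fit starts chasing noise.

## Method

**Model-induced map matching.** The model is convolved with an isotropic 3D
Gaussian kernel of width σ to produce a synthetic map *g*, which is compared
with the experimental map after thresholding (subtract *T* and clip at zero).
Three summary statistics are matched between the two maps — the volume
*V* (above-threshold voxel count), the integral *I* of the thresholded
density, and its 95% quantile *Q*:

    V₂ = V₁,   a·I₂ = I₁,   a·Q₂ = Q₁

with *a* an intensity scale. Volume matching fixes *T* as the (N−V₁)-th
ascending order statistic of *g*; the scale-free residual
D(σ,T) = I₂/Q₂ − I₁/Q₁ is driven to zero by a safeguarded Newton iteration on
σ (started from σ = R/(2√3) for a map of nominal resolution R); finally
a = I₁/I₂. This is re-solved at every dynamics step, warm-started.

**Damped dynamics.** Each residue is reduced to pseudo-atoms (backbone
N, CA, C, O plus one side-chain centroid). Motion is first-order in time: at
each step the velocities q̇ and Lagrange multipliers h solve the saddle system

    (B + V) q̇ − Jᵀ h = Q,      J q̇ = 0,

where *B* is a network of pairwise dashpots (strength c₀/√r for a damper of
length r, acting along the connecting line) between all non-bonded pairs
closer than a cutoff d_cut, *V* = ε·I a background viscosity, *Q* the force
field γ·∇Δ evaluated at the pseudo-atoms (Δ = thresholded EM map minus the
scaled thresholded model map), and *J* the Jacobian of the distance
constraints — covalent bond/angle geometry, optional user pairs, and optional
secondary-structure constraints (β-strand endpoint ties or full
rigidification).

**Adaptive cutoff.** The aggregate damper strength scales as d_cut^{5/2}, so
keeping the RMS velocity v steady calls for the update
d_cut ← d_cut·(v_t/v_{t−1})^{2/5}, floored at max(7 Å, 2σ).

**Overfitting guard.** The overlap between map supports is re-fitted every
step with the saturating exponential y(t) = b − c·e^{−kt} (variable
projection over k). The warning time t₁ = ln(1/(1−α₁))/k and stopping time
t₂ = ln(1/(1−α₂))/k mark where the fitted curve has covered fractions
α₁ = 0.9 and α₂ = 0.99 of its rise; the run stops once the current step
reaches t₂ and frames past t₁ are flagged as possible overfitting.

## Worked example

Everything runs offline on generated fixtures. Create a two-domain hinge
fixture (domains rigid, 30° hinge rotation) with a simulated 7 Å map of the
target conformation, then refine the start conformation into it:

```sh
$ ddflex make-fixture hinge --n-res 20 --theta 30 --resolution 7 --out demo
hinge fixture: backbone RMSD start->target 3.10 A

$ ddflex refine --model demo_start.pdb --map demo_map.mrc --resolution 7 \
        --max-steps 200 --out run
{
  "steps": 63,
  "overlap_final": 99.74651457541191,
  "t1": 32,
  "t2": 63,
  "b": 100.13493092758185,
  "c": 15.365783813792046,
  "k": 0.07267760548208142,
  "n_points": 63,
  "stopped_at": 63,
  ...
}
```

The run stopped itself at step 63 (the fitted stopping time t₂), with the
warning time t₁ = 32 marking where overfitting would likely begin; the
support overlap rose from 87.0% to 99.7% along the way. `run_trajectory.pdb`
holds the saved conformations (frames after t₁ are flagged in
`run_stopping.json`), and `run_log.csv` records per-step overlap, RMS
velocity, cutoff, σ, T, a and the running t₁/t₂ estimates:

```sh
$ ddflex analyze --log run_log.csv
{
  "n_steps": 63,
  "t1": 32,
  "t2": 63,
  "overlap_initial": 87.02999577524292,
  "overlap_final": 99.74651457541192
}
```

The same pipeline is available as a library (`ddflex.run_refinement`), which
additionally reports backbone RMSD to a known target for synthetic
validation; on the default 40+40-residue hinge fixture the refinement
recovers the 6.2 Å hinge motion to about 0.1 Å backbone RMSD.

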