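# Methods

## Model and assumptions

The package simulates one polymer-grafted adsorbent — a spherical
nanoparticle core or a flat wall — in a closed cell of small spherical
fluid particles, in an implicit solvent.  Solvent quality is encoded in
the effective pair interactions: with all ε_ij = ε and particle–segment
attraction ε_Ps ∈ {1.5ε, 3ε}, the chains are solvophilic (good-solvent
conditions).  There is exactly one adsorbent per cell; aggregation of
multiple hairy particles, charges, bending stiffness and explicit
solvent are out of scope.

All beads have unit mass.  Reduced units throughout: σ (segment
diameter), ε (segment–segment well depth), m, τ = σ√(m/ε).  The
time-unit definition is the standard dimensionally consistent one.

Two modelling choices deserve explicit statement:

* **Energy shift at the cutoff.**  The shifted-force construction used
  here subtracts the cutoff force (making the force continuous) *and*
  the constant needed to make the energy vanish continuously at r_cut.
  The constant does not alter forces, so the dynamics are identical to a
  force-shifted potential without it; it makes NVE bookkeeping and the
  continuity checks exact.
* **Bonded pairs.**  Directly bonded (1–2) neighbours interact only
  through the harmonic spring, not additionally through the pair LJ.
  The stiff spring (k_ss = 1000 ε/σ²) dominates in any case; excluding
  the LJ term makes the bonded dimer an exact harmonic oscillator with
  ω = 2√(k_ss/m), which the integrator tests exploit.  A consequence is
  that the repulsive contact shoulder acts only between non-bonded
  beads.

Repulsive pairs are truncated exactly at contact (r_cut = σ_ij), not at
the 2^{1/6}σ_ij potential minimum.  Because the force shift subtracts
F_LJ(σ_ij) = 24ε/σ_ij, this leaves a *softened* repulsive shoulder: the
effective packing diameter of segments is noticeably below σ.  This is
visible in the outer layering of dense coronas (see "Known
limitations").

## Parameters

| parameter | default | meaning |
|---|---|---|
| dt | 0.002 τ | ≥ 50 steps per stiff-bond period (2π/ω ≈ 0.1 τ) |
| thermostat damping | 0.1 τ | Nosé–Hoover coupling time; Q = N_dof T τ_d² |
| T\* | 1.0 | reduced temperature of all replication runs |
| k_ss | 1000 ε/σ² | tether spring constant |
| ε_Ps | 1.5 ε | particle–segment attraction (3.0 ε for the strong case) |
| bin width | 0.05 σ | profile resolution; resolves the 1σ layer spacing |
| anchor min separation | 0.9 σ | keeps the build free of sub-0.9σ_ij contacts |
| build overlap limit | 0.9 σ_ij | rejection threshold for random placement |
| ρ_b window | outer 20 % of [R_c, L/2] (sphere) / middle fifth of the cell (slab) | plateau region; a significant slope raises a warning |

Thermostatted degrees of freedom count mobile beads only; frozen beads
(core, anchors, rigid hedgehog ligands) have forces reported but never
applied.  Three COM degrees of freedom are subtracted only for fully
mobile periodic systems, where momentum is conserved.

## Numerical choices

* **Integrator**: velocity Verlet; single Nosé–Hoover thermostat with
  the symmetric (Trotter-split) half-step update.  NVE mode (thermostat
  off) conserves energy to better than 10⁻⁴ relative over 10⁴ steps in
  bulk.
* **Neighbour search**: linked-cell lists for fully periodic boxes with
  at least four cells per axis; otherwise a numba O(N²) kernel.  Both
  are verified against an independent vectorized numpy O(N²) reference
  on every mechanical fixture.
* **Hard walls** (slab geometry) are specular: a mobile bead crossing
  z = σ_i/2 (or L_z − σ_i/2) is mirrored and its normal velocity
  reversed.  This conserves energy to the bulk tolerance for pair-only
  interactions; a stiffly bonded bead that bounces mid-step picks up an
  O(dt) energy error per event (~0.4 % over 10⁴ steps for a brush slab),
  which the thermostat absorbs in production runs.
* **Initial chain placement**: flexible chains are grown as
  outward-biased self-avoiding walks with fixed bond length σ (never
  entering the core, never below the grafted wall).  Dense flat brushes
  (e.g. ρ_gr = 0.398 with M = 20 on a √(f/ρ_gr) cell) can exhaust the
  random-growth retry budget; the builder then restarts with every
  chain a vertical rod, which is overlap-free at any admissible anchor
  spacing.  Either initial condition is erased by equilibration; only
  the overlap invariant (no pair below 0.9 σ_ij) is load-bearing.
* **Histogram grids** are center-aligned (bin centers at
  r_min + kΔ, edge bins clipped to the domain), so beads frozen exactly
  at the anchor radius σ_cs or at z = 0.5σ fall at a bin center rather
  than on an edge; reported peak positions are bin centers.
* **Quadrature** for Γ and H uses shell-exact sums (the binned counts
  supply ∫r²ρ dr directly; the r³- and r⁴-moments use the exact
  per-bin integrals), eliminating midpoint discretization bias:
  ∫4πr²ρ_s dr over the binned range reproduces the segment count
  exactly, and closed-form fixtures (top-hat shells, uniform layers)
  are matched to 10⁻¹⁰.
* **Adsorption routes.**  The integral route sums (ρ − ρ_b) over the
  virtual adsorption region; the mass-balance route is Γ = V′(ρ₀ − ρ_b).
  For a closed simulation cell the two measure the same Gibbs excess
  when V′ is the *accessible* virtual volume (the [R_c, L/2] shell for
  the sphere, the full cell for the slab) and ρ₀ the mean density over
  that same volume; the workflow uses this form for its internal
  cross-check, which must agree within 2 SEM across replicates.
* **Equilibration check**: the total-energy series of the equilibration
  phase is split into two halves of its second half; a difference
  beyond 5 combined standard errors flags the trajectory as
  non-equilibrated (warning plus a flag in the output, never silent).
* **Degenerate inputs**: r = 0 pair separations raise a singularity
  error; displacement > 0.5σ in one step raises an instability error
  suggesting a smaller dt; empty species selections, zero profiles and
  empty bulk windows raise ValueError.

## Synthetic-data fixtures

The fixtures module makes every estimator testable without dynamics:
positions are drawn from prescribed analytic radial/planar densities
(constant, top-hat shell, Gaussian layer bumps, exponential decay onto a
plateau) by inverse-CDF sampling on the shell-weighted measure, so the
tails are exact and every draw is reproducible from its seed.  Each
analytic form carries its closed-form Γ and (where defined) H, verified
against adaptive quadrature.  Mechanical fixtures (bonded dimer,
contact pairs, a 50-bead random periodic cell, a rigid hedgehog with
exactly known bead radii) carry independently computed energy/force/H
oracles.

These fixtures validate estimators, not dynamics: they emulate the
*geometry* of sampled configurations (shell-weighted radial measure,
layering peaks, plateaus) but none of the correlations, slow modes or
adsorption kinetics of real trajectories.  Passing them shows the
observables are computed correctly, not that a given MD schedule is
converged — the latter is probed separately by the stationarity flag
and the replicate scatter.

## Scaled-down study conditions

Publication-scale schedules (10⁸ equilibration steps, boxes up to 107σ,
~10⁵ fluid beads) are far beyond a desk run.  The package's test and
replication conditions are scaled down as follows, as its own standard
problem sizes:

* layering/thermostat state point: σ_c = 4σ, f = 20, M = 10,
  ε_Ps = 1.5ε, ρ₀ = 0.01, L = 30σ, 10⁵ + 10⁵ steps, 3 seeds;
* trend scans: ρ₀ = 0.05, L = 30σ (M = 10) or L = 50σ (M = 20, the
  smallest box admitting fully stretched M = 20 ligands),
  3·10⁴ + 3·10⁴ steps, 3 seeds per condition;
* flat-brush comparisons at matched ρ_gr = 0.398 σ⁻², L_z = 40σ.

At these sizes the qualitative orderings (Γ* rising with f, with M, and
from flat to spherical substrates at matched grafting density; H*
rising with f) are resolved well beyond replicate scatter, while each
state point runs in tens of seconds on one CPU.

## Known limitations

* The corona layering of the force-shifted model is softer than that of
  a hard-core (energy-shifted-only) truncation: the effective segment
  packing distance is ≈ 0.85σ, so while the frozen-anchor peak (2.5σ)
  and the bond-constrained second-segment peak (≈ 3.5σ) are exact, the
  third-layer maximum of the scaled-down dense brush sits at ≈ 4.2σ
  rather than at the idealized contact value 4.5σ.  This is a property
  of the prescribed potential, stable under 3× longer schedules and
  present even without fluid.
* Mass-balance adsorption with the inscribed-sphere volume πL³/6 and
  the cell density ρ₀ = N/V is only an approximation for closed cells
  (the excess is drawn from the whole cube); the accessible-volume form
  above is exact and is what the cross-checks use.
* Specular walls are not differentiable interactions; slab NVE energies
  carry bounce noise for bonded beads (see above).
* Single adsorbent per box; no chain mobility on the core surface; no
  polydispersity.
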