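# Methods

## The model

`patchygibbs` simulates a two-component mixture of hard spheres decorated
with attractive surface patches, a minimal model for a droplet-forming
("driver") protein P mixed with a macromolecular regulator R (RNA, a crowding
agent, or a second protein).  Both species have hard-core diameter σ, the
unit of length.  P carries m_P = 4 patches at the vertices of a tetrahedron;
R carries m_R = 2 patches at its poles.  All patches on a particle together
cover a fraction χ of its surface, so each patch is a spherical disk whose
spanning polar half-angle θ_S obeys

    cos θ_S = 1 − 2 χ / m_S .

With the default χ = 0.7 this gives cos θ_P = 0.65 and cos θ_R = 0.30: the
R patches are individually wider, but their polar placement limits how many
partners an R can engage compared with the tetrahedral spread on P.

Two particles i, j interact through a directional square well

    U_ij = U_sw(r_ij) · U_pp(r̂_ij, Ω_i, Ω_j)

where U_sw is ∞ for r ≤ σ (hard core), −ε_ij for σ < r ≤ σ + λ, and 0
beyond, with well width λ = 0.5 σ.  U_pp is 1 exactly when the pair is
*bonded*: some patch α on i and some patch β on j satisfy
r̂_ij · n_iα > cos θ_iα and −r̂_ij · n_jβ > cos θ_jβ (strict inequalities).
Well depths are ε_PP = 1 (the unit of energy), ε_RR = 0 (regulators are
mutually purely repulsive), and ε_PR ∈ [0, 1.5] is the control parameter.
Temperature is reduced by ε_PP/k_B.

Conventions worth noting:

- A pair contributes at most one bond and one −ε_ij even if several patch
  pairs align simultaneously; the well depth multiplies a single indicator.
  (At χ = 0.7 double alignment is geometrically impossible for these patch
  layouts, but the rule is enforced regardless.)
- Overlap is a distinguished sentinel value, compared by identity, never
  summed — this keeps incremental energy bookkeeping free of ∞ − ∞ traps.
- Boundary conventions are literal: overlap iff r ≤ σ, well iff
  σ < r ≤ σ + λ, bond iff the dot products strictly exceed the cosines.
  The boundary sets have measure zero.
- In bond *reports*, only pair classes with ε_ij > 0 count: a geometric
  R–R contact (or P–R contact at ε_PR = 0) stabilises nothing, so a
  regulator can only have protein partners.
- Parameter sets whose patches overlap on a single particle are rejected at
  construction (χ is a covered-area fraction only for disjoint disks).  The
  isotropic χ → 1 limit — useful as a square-well consistency check on the
  two-patch species — deliberately violates this for the four-patch species
  and is reachable through an explicit `check_patch_overlap=False` opt-out.

## Gibbs-ensemble Monte Carlo

Coexistence is computed with the two-box Gibbs ensemble: fixed totals
(N_P, N_R, V_total, T), with three move types per cycle in a randomly
shuffled interleaving (default 500 + 500 + 5 attempts):

1. **Displacement** — a uniformly chosen particle receives a joint random
   translation (uniform in a cube of half-width `max_translation`) and
   rotation (uniform axis, angle uniform in [0, max_rotation]); Metropolis
   acceptance min[1, exp(−ΔU/T)].  Patchy particles require orientation
   sampling, so translation and rotation are proposed together; pure
   translations would leave orientations frozen.
2. **Exchange** — a species is drawn uniformly among species present in the
   system, a source box uniformly (the attempt fails if the source holds no
   such particle), and a uniform particle of that species is reinserted at a
   uniform position/orientation in the other box.  Acceptance
   min[1, (N_s,src V_dest) / ((N_s,dest + 1) V_src) · exp(−ΔU/T)].
3. **Volume exchange** — proposed symmetrically in ln(V_I/V_II) with
   V_total conserved exactly and coordinates rescaled affinely; acceptance
   min[1, (V_I′/V_I)^(N_I+1) (V_II′/V_II)^(N_II+1) exp(−ΔU/T)], the +1
   exponents being the Jacobian of the ln-volume proposal.  The
   log-ratio proposal keeps acceptance healthy across the decade-scale
   volume asymmetry that develops near coexistence.

Initialization uses random sequential insertion (retry budget 10⁴ per
particle; at the standard overall density ρ0 = 0.3 the packing fraction is
≈ 0.157 and naive insertion succeeds; failure raises immediately rather than
looping).  By default the boxes start *asymmetric*, near typical
coexistence: a droplet box at liquid-like total density (≈ 0.55) holding
the proteins plus a regulator share that scales with the regulator's
bonding ability ε_PR/ε_PP (inert regulators start fully dispersed, strongly
bound ones get a uniform share), and a dilute box with threshold-level
protein (≈ 0.05) and the remaining regulators.  Below T_c the dominant
equilibration cost is the slow net insertion of proteins into the bonded
droplet, so that transfer is pre-done; regulators, which carry no mutual
attraction, re-partition comparatively quickly.  The stationary
distribution does not depend on the start; an even split at equal volumes
is available via ``warm_start=False`` and is the natural choice for clearly
supercritical state points.

During equilibration only, `max_translation` and `max_rotation` adapt every
100 cycles toward a 30–50% displacement acceptance window; they are frozen
for collection, since adapting during sampling would violate stationarity.

Neighbour search uses cell lists with cell edge ≥ σ + λ = 1.5 σ (the full
interaction range), rebuilt on volume changes and particle transfers; boxes
too small for a 3×3×3 decomposition fall back to brute-force loops.  Box
energies are tracked incrementally; because every energy is an exact sum of
well depths, the cache is required to equal an O(N²) recomputation *exactly*,
and the engine can re-derive and compare it every `check_every` cycles
(used in the test suite).

All randomness flows from a single seeded generator inside the compiled
kernel; a fixed seed reproduces the trajectory bit for bit.

## Observables

One sample per `sample_stride` cycles records, per box: particle counts by
species, volume, energy, and geometric bonded-pair counts by class
(PP/PR/RR).  Phase labels are assigned per sample — the box with the higher
total number density is the droplet phase II — and all averages are taken
after labeling.  Samples whose density gap is below twice the pooled spread
of the two branches are flagged; a stream with more than half its samples
flagged is reported as "no coexistence" rather than averaged.

Bond statistics per sample follow from the tallies: bonds per P particle
n_b;P = (2·PP + PR)/N_P, bonds per R particle n_b;R = PR/N_R (classes with
ε = 0 excluded), and the overall

    n_b = (ρ_P n_b;P + ρ_R n_b;R) / (ρ_P + ρ_R),   n_b;P = n_b;P−P + n_b;P−R

hold exactly per sample, as definitions.  Standard errors use block
averaging with 10 contiguous blocks, since successive samples are
autocorrelated.  The bonding ability of a lone regulator in a pure protein
droplet ("dilute-R limit") cannot be simulated directly; n_b;R is measured
at the two smallest ratios X = 0.05, 0.10 and extrapolated linearly to
X = 0.

The critical point of a binodal {(T, ρ_P^I, ρ_P^II)} is fitted with the law
of rectilinear diameters: mean density linear in T, width
ρ_P^II − ρ_P^I = B (T_c − T)^0.32 with the Ising-like exponent held fixed.
The nonlinear width fit runs first (multistart over T_c in (T_max,
T_max + 0.15] to avoid the boundary minimum), then the linear diameter fit
given T_c.  Points nearest T_c are pruned one at a time — highest T first —
refitting until successive T_c estimates agree to 0.002 or four points
remain; the full trace is returned.  The 0.002 stopping tolerance and the
four-point floor quantify an otherwise qualitative "prune until stable"
procedure and make it deterministic and testable.  Fits are unweighted by
default.

## Problem sizes and what desk scale shows

The package defaults target a single workstation core: N_total = 256
particles at ρ0 = 0.3, ~10⁴ equilibration and collection cycles (the test
suite uses 8 000 + 8 000, with 20 000 equilibration cycles for
regulator-heavy mixtures, which take longer to re-partition R).  Two
quantities are size-sensitive at 256 particles and run at the reference
size of 512 instead: the X = 1.5 droplet bond count (only ~40% of the
particles are proteins there, and the small droplet depresses n_b) and the
droplet-density ratio between the strong-regulator mixture and the pure
protein (both legs at matched size and length, so residual equilibration
bias largely cancels in the ratio).  Production-scale settings (512–1000
particles, 10⁶ cycle equilibration) are available through the run
configuration; desk scale mainly costs precision in the dilute branch and
near-critical resolution, not the phenomenology.

What desk-scale agreement does show: the three regulator regimes (inert
crowders promote LLPS; moderately attractive regulators are recruited and
suppress it; strongly attractive regulators promote at small X and suppress
at large X), the corresponding tie-line slopes, and droplet bond statistics
within a few percent.  What it does not show: sharp binodal shapes near T_c,
finite-size-converged critical parameters, or any claim about real
biomolecules — the model has rigid spherical particles with fixed valence,
no electrostatics, no chain connectivity, and a structureless solvent.

## Known limitations

- Only two-phase coexistence is handled; three-phase or gel regions would
  confuse the per-sample density labeling.
- At very high regulator load the dilute box becomes a moderately dense
  hard-sphere fluid; exchange acceptance drops and equilibration slows —
  hence the longer equilibration budget for high-X runs.
- The critical-point fit inherits the rectilinear-diameter law's bias when
  applied too close to T_c; the pruning loop mitigates but cannot remove it.
- Single-stream determinism is the contract; there is no parallel execution.
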