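# patchygibbs

Gibbs-ensemble Monte Carlo for a two-component patchy-particle model of
protein–regulator mixtures, built to ask one question: **when does a
regulatory macromolecule (RNA, a crowder, a second protein) promote a
protein's liquid–liquid phase separation (LLPS), and when does it suppress
it?**

Membraneless organelles form when a driver protein condenses into a droplet
phase held together by a network of weak, valence-limited bonds.  The model
strips this to its essentials: hard spheres of diameter σ carrying attractive
surface patches.  The protein-like species P has four tetrahedral patches
with well depth ε_PP = 1 (the energy unit); the regulator R has two polar
patches, no R–R attraction (ε_RR = 0), and a tunable P–R attraction ε_PR.
Patches jointly cover a fraction χ = 0.7 of the surface, each spanning a
polar angle θ_S with cos θ_S = 1 − 2χ/m_S; a pair within the square well
(σ < r ≤ 1.5 σ) interacts with −ε_ij exactly when a patch on each particle
faces the other.

Two simulation boxes at fixed total N, V, T exchange particles and volume
(Gibbs ensemble), so each box relaxes into one bulk phase without an
interface.  From the sample streams the package computes coexistence
densities ρ_P^I/ρ_P^II (binodals), tie lines in the (ρ_P, ρ_R) plane,
critical points via the law of rectilinear diameters with fixed exponent
0.32, and droplet-phase bond statistics n_b, n_b;P = n_b;P−P + n_b;P−R,
n_b;R.

Varying ε_PR reproduces three regimes:

- **ε_PR ≲ 0.25 — volume-exclusion crowder.**  R stays in the dilute phase,
  displaces P into the droplet, and *promotes* LLPS.
- **moderate ε_PR — active suppressor.**  R is recruited into the droplet,
  displaces P, and weakens the bond network: LLPS is *suppressed*.
- **ε_PR > ε_PP — active promoter with turnover.**  R bonds better than P
  and strengthens the network at small R:P ratio X, but at high X the
  displacement of P wins and promotion turns into suppression.

Intended users: soft-matter / biophysics researchers who want a fast,
seeded, fully reproducible reference implementation of patchy-particle
Gibbs-ensemble coexistence with bond-network analysis.

## Worked example

Pure protein at T = 0.7 (reduced units), overall density ρ0 = 0.3,
N = 256 particles:

```python
from patchygibbs import ModelParams, run, bond_report, label_phases

params = ModelParams()          # chi=0.7, lam=0.5, eps_PP=1, eps_RR=0
samples, state = run(
    params, n_total=256, x_ratio=0.0, rho0=0.3, temperature=0.70,
    n_equil_cycles=10_000, n_collect_cycles=15_000, sample_stride=25, seed=11,
)
labeled, point = label_phases(samples, temperature=0.70)
report = bond_report(samples, params)
print(f"rho_P^I  = {point.rho_P_I:.4f} +/- {point.se_rho_P_I:.4f}")
print(f"rho_P^II = {point.rho_P_II:.4f} +/- {point.se_rho_P_II:.4f}")
print(f"n_b      = {report.n_b:.2f} +/- {report.se_n_b:.2f}")
```

```
rho_P^I  = 0.0681 +/- 0.0022
rho_P^II = 0.5334 +/- 0.0058
n_b      = 6.40 +/- 0.06
```

The boxes have split into a dispersed phase at ρ_P ≈ 0.07 and a droplet
phase at ρ_P ≈ 0.53 — wide coexistence, as expected well below the pure-P
critical temperature T_c ≈ 0.75 — and each droplet-phase particle engages
about 6½ bonded partners, the network that holds the condensate together.
Setting `x_ratio` and `ModelParams(eps_PR=...)` explores the regulator
regimes; `fit_critical_point` turns a list of labeled coexistence points
into (T_c, ρ_P^c).

The same workflow is scriptable from the shell:

```bash
patchygibbs simulate --config run.toml --out out/
patchygibbs analyze --samples out/samples.tsv --temperature 0.7 --out analysis/
patchygibbs fit-binodal --binodal binodal.tsv
patchygibbs fixtures export --name trimer_PPR --out trimer.xyz
```

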