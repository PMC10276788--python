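# Methods

This note documents the model implemented by `liece`, the assumptions behind
each component, the numerical choices, and what validation on synthetic data
does and does not demonstrate.

## The binding free-energy model

LIECE is an end-point method: only the bound complex and the free partners
enter, with conformational sampling replaced by energy minimization and
explicit solvent replaced by a dielectric continuum. For each pose three
terms are computed, each as a complex − protein − ligand difference:

* **ΔE_vdW** — Lennard-Jones energy, `ε_ij[(r_min,ij/r)¹² − 2(r_min,ij/r)⁶]`
  summed over pairs with r ≤ 14 Å (plain truncation, no switching or shift).
  Lorentz–Berthelot combination: `ε_ij = √(ε_i ε_j)`,
  `r_min,ij = (r_min,i + r_min,j)/2`.
* **ΔE_coul** — vacuum Coulomb energy `k_e q_i q_j / r` with
  `k_e = 332.0636 kcal·Å·mol⁻¹·e⁻²`, no cutoff and no distance-dependent
  dielectric; all solvent screening lives in the solvation term.
* **ΔG_solv** — electrostatic solvation free energy from a finite-difference
  Poisson solve at zero ionic strength, interior dielectric 1.0, exterior
  78.5.

The experimental response is ΔG_exp = RT·ln(K_i) with
R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹ and T = 298 K; K_i is read on the 1 M
standard state, so pKi 8.27 and 10 map to −11.28 and −13.64 kcal/mol.
The regression

    ΔG_pred = α·ΔE_vdW + β·ΔE_coul + γ·ΔG_solv (+ δ)

is solved in closed form (numpy least squares; nothing iterative, nothing
seeded) in four variants: full or vdW-only regressors, each with or without
the intercept. The key physical caveat the model carries is that the
protein's internal energy is treated as constant across ligands of a series;
for flexible receptors this assumption, not the regression, is usually the
accuracy bottleneck.

### Fit statistics and stability

* R² is computed with the mean-anchored total sum of squares for **all**
  variants, including the through-origin ones. Through-origin R² has no
  single convention; anchoring at the mean keeps the statistic comparable
  across the intercept/no-intercept pairs and is the choice documented here.
* RMSE is the root mean squared prediction error in kcal/mol.
* Leave-one-out analysis refits the model n times, leaving out one ligand
  each time. Reported are the per-coefficient standard deviation across
  refits (population normalization, `ddof=0`, with a flag for sample
  normalization) and ⟨ΔΔG⟩, the arithmetic mean of
  (full-model prediction − loo-model prediction). Two conventions exist for
  which predictions enter the mean; the default evaluates the gap on the
  left-out ligand only (`ddg_mode="left_out"`), the alternative averages the
  gap over every ligand of the set (`ddg_mode="all"`). Both are implemented
  because the statistic is reported ambiguously in the application
  literature; neither is asserted as canonical.
* A leave-one-out run requires at least p + 2 rows (p free coefficients) so
  that every fold retains a residual degree of freedom.

## Pose acceptance filters

Expert inspection of aminergic-receptor poses enforces three constraints
that this package encodes as geometry:

1. **Anchor salt bridge** — at least one ligand nitrogen with partial charge
   ≥ +0.5 e within 4.0 Å of a carboxylate oxygen of the anchor aspartate
   (D3.32; addressed by residue number, default 155 — no generic GPCR
   numbering engine is built).
2. **No stranded polar atoms** — no ligand N/O that is buried (fractional
   exposure < 0.1) yet has neither a hydrogen bond (donor–acceptor ≤ 3.5 Å,
   D–H···A ≥ 120° when explicit hydrogens exist; heavy-atom distance alone
   otherwise, with strongly anionic atoms, q < −0.2 e, treated as
   acceptor-only) nor an ionic contact.
3. **No solvent-exposed hydrophobic moieties** — the exposed fraction of the
   ligand's apolar (carbon) surface, normalized by its free-ligand value,
   must not exceed 0.5.

Exposure uses a Shrake–Rupley-style numerical surface: probe 1.4 Å, radii =
Born radii, and a fixed 92-point golden-spiral sphere sampling, so the
filter is fully deterministic. All thresholds are conventions of common
structural-biology practice, exposed in `FilterRules`; the qualitative
constraints themselves, not these numbers, are the validated content.
Rejections enumerate every violated constraint, not just the first.

## Minimization

The published protocol minimizes each structure before the single-point
evaluations: up to 500 steepest-descent steps, then up to 1000
Polak–Ribière conjugate-gradient steps, stopping when the gradient RMS
falls below 0.001 kcal·mol⁻¹·Å⁻¹. This package follows that schedule with
Armijo backtracking line searches (energy provably non-increasing across
accepted steps). **Fidelity gap:** the original force field's bonded terms
are replaced by harmonic positional restraints (k = 10 kcal·mol⁻¹·Å⁻²,
`E = k·d²` per atom) to the input coordinates. Bonded terms largely cancel
in the complex − protein − ligand difference; the restraints preserve the
protocol's role — local strain relief — without covalent topology. This is
the principal deviation from a full molecular-mechanics treatment and the
reason minimized toy energies should not be compared with published
force-field numbers.

By default the complex is minimized as a whole and the free protein and
ligand are minimized independently, mirroring the three separate
calculations of the original protocol; a flag disables minimization
entirely, in which case the vdW and Coulomb differences reduce exactly to
the protein–ligand inter-group sums.

## Finite-difference Poisson solver

`∇·(ε∇φ) = −4π k_e ρ` is discretized with the 7-point stencil on a regular
node-centered grid:

* **Dielectric boundary** — the union of atomic spheres at the Born radii
  (no solvent-excluded surface; probe effects are folded into the radii).
  Each face (grid edge) carries the harmonic mean of interior and exterior
  dielectric weighted by the analytically computed fraction of the edge
  inside the solute. This smoothed assignment was chosen over a binary
  face-center rule after direct comparison: the binary rule leaves a ~4%
  Born-ion error at 0.4 Å spacing and breaks monotone grid convergence,
  while edge-fraction weighting gives 1.6% → 0.8% → 0.3% across
  0.8/0.6/0.4 Å.
* **Charges** — trilinear spreading to the eight surrounding nodes; total
  charge conserved to 1e−10 e by construction.
* **Boundary condition** — Dirichlet, `φ = k_e Σ q_i/(ε_ext r_i)`.
* **Solver** — diagonally preconditioned conjugate gradients
  (`scipy.sparse`), relative residual 1e−6, at most 10 000 iterations;
  non-convergence raises.
* **Focusing** — coarse solve at 1.0 Å spacing with a 10 Å margin, then a
  fine solve at 0.4 Å over the solute bounding box + 4 Å with boundary
  potentials interpolated from the coarse solution.
* **Self-energy** — removed by subtracting a reference solve with uniform
  interior dielectric on the *identical* fine grid, so
  `G_solv = ½ Σ q_i [φ_solv(x_i) − φ_ref(x_i)]` contains only the reaction
  field. An uncharged solute short-circuits to exactly 0.
* Zero ionic strength throughout (Poisson, not Poisson–Boltzmann); no
  nonpolar/SASA solvation term; no periodic boundaries.

Known discretization limits: grids are anchored to the solute bounding box,
so rigid translations change G_solv only through sub-grid re-registration
(< 0.5% in practice, exactly 0 for translations that preserve the box
alignment); and the on-axis lattice Green's function of the 7-point stencil
deviates ~4% from 1/r at exactly three grid spacings from a point charge
for *any* spacing — agreement to 3% holds from four spacings on-axis and
from three spacings off-axis.

## Synthetic data: what it emulates and what it does not

`gen_energy_table` draws the three energy terms uniformly from ranges that
mimic the application's magnitudes — vdW dominant and negative
(−70…−30 kcal/mol), Coulomb negative (−30…−5), desolvation positive
(5…40) — and builds the response from chosen coefficients
(α = 0.12, β = −0.02, γ = −0.04, δ = −2.0, several-fold α dominance) plus
Gaussian noise of 0.5 kcal/mol standing in for assay and pose error, placing
ΔG_exp in the nanomolar-binder range. `gen_toy_complex` builds a cup-shaped
pocket of Lennard-Jones spheres with an anionic carboxylate-like anchor pair
and a small cationic ligand cluster 3.5 Å from it; `gen_decoy_pose`
deterministically produces a flipped pose (exact involution), a buried
unpartnered donor, and a solvent-exposed apolar tail. All generators are
pure functions of their spec; randomness comes from numpy's PCG64 generator
with integer seeding, named here so that a reimplementation can match
draw-for-draw.

Passing tests on these inputs demonstrates that the regression, filtering
and energy machinery are correct — coefficient recovery to machine
precision on noiseless tables, sampling spread matching OLS theory,
constraint-specific rejections, pair sums equal to brute-force enumeration,
Born/Coulomb analytics to stated tolerances. It does **not** demonstrate
predictive accuracy on real receptor–ligand data: the synthetic response is
linear in the terms by construction, whereas the linearity of real binding
data is exactly the scientific hypothesis under test; the toy geometry has
no conformational strain, no water bridges, and energy scales unrelated to
a real force field (its clustered spheres even leave ΔE_vdW positive).
Reproduction of the published per-series statistics is implemented and runs
whenever the deposited per-pose energy table is supplied at
`data/supplementary_energies.csv`; that file is third-party supplementary
data and is not redistributed here.

## Degenerate inputs and tie-breaks

* Coincident atoms (r = 0) raise rather than returning infinities.
* Zero-variance observations leave R² undefined (`None`) while RMSE is
  still reported.
* Rank-deficient design matrices raise with the collinear columns named;
  no pseudo-inverse fallback.
* A salt-bridge contact is reported once per (cationic center, anchor
  residue) pair at the minimum oxygen distance; hydrogen-bond pairs are
  reported once, ligand-as-donor tried first.
* Toy-complex generation retries with an incremented seed when jitter
  produces interatomic distances below 1.5 Å (at most 100 attempts).

## Problem sizes

Default validation sizes: synthetic tables n = 50 (200 replicates for the
sampling-theory check), toy complexes ~50 atoms, Born/focusing grids up to
~21³ coarse and ~51³ fine nodes. These sizes put every closed-form
comparison well inside its tolerance while keeping the full suite and the
acceptance script in the tens-of-seconds range; all are configurable
upward.
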