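# Methods

This note documents the models, pinned parameters, and design choices behind
`mofix`, and what the shipped tests do and do not demonstrate.

## Chemical model

A catalyst is a homoleptic complex: one Mo center, three identical anionic
ligands (formal charge −1 each), and one or two identical neutral ligands,
plus one site for the NxHy moiety of the catalytic cycle.  Complexes are
RDKit graphs in which donor atoms and the coordinating moiety nitrogen bind
Mo through dative bonds; ligand formal charges stay on the ligands and the
balance is carried by the Mo formal charge, so the assembled complex's total
formal charge equals the cycle state's charge (0 or +1) by construction.
This is bookkeeping, not an oxidation-state assignment.

### The 15-state cycle

The cycle table is pinned as: N2, N2H+, N2H, N2H2+, N2H2, N2H3+, N2H3,
N (after NH3 release), NH+, NH, NH2+, NH2, NH3+, NH3, bare (after the second
NH3 release); N2 binding closes the cycle back to state 1.  This is the
unique sequence consistent with the 6 H+ / 6 e− stoichiometry, alternating
charges 0/+1, and two NH3 releases.  Added protons accumulate on the distal
nitrogen until the N–N bond is cleaved by the first NH3 release; afterwards
they sit on the remaining nitride nitrogen.  The six-coordinate
Mo–NH3–N2 shortcut is deliberately not modeled.  Spin multiplicities are not
physically meaningful at the surrogate level; the table carries bookkeeping
defaults (doublet while the cumulative number of transferred electrons is
even, singlet otherwise), overridable per state.

### Donor patterns

Donor-atom candidates come from a pinned SMARTS file
(`data/donor_smarts.json`): carbenes, phosphines, amines (sp3, aromatic,
imine) and oxygens (ether/hydroxyl, carbonyl) for neutral ligands;
O−, N−, halides and carbanions for anionic ones.  Matches are deduplicated by
graph-symmetry class.  The patterns are intentionally broad class
definitions; the binding-energy ranking, not the pattern, makes the final
choice.

### Stereoisomers

Site assignments are deduplicated under the proper rotation group of the
ideal polyhedron.  The group is derived, not hard-coded: a site permutation
is admitted iff it preserves the Gram matrix of the site unit vectors and
its induced orthogonal map has determinant +1 (24 rotations for the
octahedron, 6 for the trigonal bipyramid).  The canonical label of an isomer
is the lexicographically smallest assignment string over its orbit, which
makes labels stable across runs and platforms.  Counts are cross-checked in
the tests against an independent brute-force oracle built from explicit
rotation matrices.

## Energy backends

All backends implement `optimize` / `single_point` / `species_energy`.

### Surrogate potential

The deterministic surrogate (parameters pinned in
`data/surrogate_params.json`, all in kcal/mol and Å) is

E = Σ element terms + Σ_bonds Morse(r; De, r0, a) + Σ_nonbonded A·e^(−r/ρ)
  + state(moiety, charge) + Σ_donors coupling(element; state)
  + optional motif bonus.

Properties that matter and are asserted in tests: a single minimum of depth
−De per bond, size consistency (separated fragments add), a graph-computable
analytic optimum (every bond at its minimum, repulsion relieved), and a
descent-only optimizer (L-BFGS-B on the analytic gradient) whose output
never exceeds the input single-point energy.  The state terms and per-donor
couplings create a nontrivial, ligand-dependent landscape for E_p and E_r;
the motif bonus is the knob the planted-optimum benchmark uses.  Donor
species energies (LutH+/Lut, CrCp\*2 / CrCp\*2+) are pinned constants of the
surrogate — they cancel out of all within-backend comparisons and set the
overall scale of step energies.

The surrogate is a test stand-in for tight-binding energetics with the same
call signature, not an approximation fitted to any quantum method.  Passing
tests demonstrate that the machinery (protocols, filters, GA, profiles) is
correct and deterministic; they say nothing about real Mo chemistry.

### Fidelity modes

The surrogate exposes two modes.  The default *analytic* mode evaluates the
graph-level optimum directly — no 3D embedding — which makes GA runs and
profiles fast and exactly reproducible; stereoisomer discrimination then
comes only from configured stereo terms.  The *geometric* mode
(`use_3d=True`) runs the full pipeline: template-based conformer generation,
connectivity checks, L-BFGS relaxation.  Both modes agree to within residual
strain on rigid fixtures (asserted).  External backends (xTB, DFT hook)
always operate geometrically; the xTB adapter exchanges XYZ files, passes
charge/multiplicity via flags, logs every invocation, and raises a distinct
environment error when the executable is missing.

### Conformer generation

Whole-molecule ETKDG embedding handles metal-free molecules.  Assembled
complexes use a template-based generator: each ligand copy is ETKDG-embedded
standalone (deterministic per-site seeds), oriented so the donor lone-pair
direction points at Mo, placed on its ideal site at 2.1 Å, and spun about
the site axis by deterministic golden-angle increments; the pool is greedily
pruned at the requested heavy-atom RMSD (Kabsch superposition with identity
atom correspondence).  This sidesteps distance-geometry failures that plague
one-shot embedding of six-coordinate dative complexes while remaining fully
seeded.

### Connectivity check

Bond integrity before and after optimization is verified with extended-Hückel
reduced overlap populations (RDKit's YAeHMOP wrapper, version-locked through
the rdkit dependency): every bond of the reference graph must carry an
overlap population of at least 0.15.  A threshold of 0 accepts any finite
geometry.  The extended-Hückel run treats the system at its neutral electron
count; for the ±1 states of the cycle this is a known, accepted
approximation of the check (it compares bonded vs broken, not absolute
populations).

## Scoring

E_p and E_r are electronic reaction energies including the donor pairs:

- E_p = [E(Mo–N2H+) + E(Lut)] − [E(Mo–N2) + E(LutH+)]
- E_r = [E(Mo–N2H) + E(CrCp\*2+)] − [E(Mo–N2H+) + E(CrCp\*2)]

Mass and charge balance of both reactions is asserted on every call.  Each
complex energy is the lowest surviving conformer of the protocol: embed
`n_confs` (default 4), connectivity-check, optimize, connectivity-check
again, discard conformers more than 20 kcal/mol above the best.  Losing all
conformers of any intermediate is a scoring failure: the catalyst scores 0
with the reason recorded.

Normalization: `clip((100 − x)/200, 0, 1)` — 10 kcal/mol ↦ 0.45, −100 or
lower ↦ 1, +100 or higher ↦ 0.

### Synthetic accessibility

Per ligand, the raw Ertl–Schuffenhauer score (1 = easy … 10 = hopeless;
RDKit contrib implementation) is mapped through a Gaussian score modifier
with target 1.0 and width 2.5, averaged over all ligand copies (3 anionic +
n neutral), and passed through a squeezing modifier: a Gaussian branch
(target 1.0, width 1.0893, chosen so 0.5 maps to exactly 0.9) above 0.5 and
a linear ramp below, making the map continuous and monotone with f(0)=0 and
f(1)=1.  The squeeze deliberately compresses differences among
already-accessible ligand sets so that hard-to-make but catalytically
promising ligands (phosphines, carbenes) are not extinguished early.  A pure
Gaussian cannot both preserve 0 and plateau above 0.5; the hybrid is this
package's pinned resolution of that tension.  Anionic ligands are
neutralized before SA scoring by protonating the charged atom (methoxide is
scored as methanol); a ligand with anything but exactly one anionic atom
fails neutralization and scores 0 with a warning.

## Genetic algorithm

- **Selection**: rank-based roulette (probability proportional to rank of
  total score).  Chosen over fitness-proportional selection because score
  magnitudes are products of clipped terms and would otherwise compress
  selection pressure.
- **Crossover** (rate 1.0): one ligand type is modified per event; a random
  acyclic single bond is cut in each parent's ligand of that type and
  complementary fragments are spliced.  Net formal charge of the class is
  preserved by construction (the two charge-bearing fragments are never
  joined).  Identical parents cut the same bond, making crossover closed
  under identity.  Single-atom ligands fall back to whole-ligand
  inheritance.  Ring-bond crossover is not implemented; rings enter through
  the library and survive intact.
- **Mutation** (rate 0.3): one of {append atom 0.35, delete atom 0.25,
  substitute atom 0.25, flip bond order 0.15} applied to one ligand type,
  retried until chemically valid and donor-bearing; charged atoms are never
  edited.
- **Survivors**: elitist top-N of parents + children, deduplicated by
  canonical catalyst key, so the best score is non-decreasing (asserted).
- **Constraints**: assembled complex has 2–100 heavy atoms, ≤ 20 rotatable
  bonds; ligand copies identical by construction.

Defaults: population 50, 50 generations.  Tests and the planted-optimum
benchmark run population 20 for 20 generations with the analytic surrogate,
a size at which ten independent seeded runs complete in about two minutes on
one CPU; the landscape and thresholds do not depend on the population size.

The crossover/mutation rates and operator weights are this package's pinned
defaults for the cited GA scheme; they are config fields, not constants.

## Validation funnel

Re-scoring uses 500 embeddings with RMSD pruning 1 Å, redoes the
stereoisomer choice with donors fixed, and omits the SA factor.  The
diversity filter visits catalyst pairs in canonical-id order and discards a
seed-deterministic random member of any pair with radius-3 Morgan Tanimoto
similarity above 0.6, so the surviving set is pairwise-compliant and
independent of input order.  The energy cutoff keeps catalysts with both
E_p ≤ 10 and E_r ≤ 10 kcal/mol (exactly the 0.45 normalized threshold).

Full profiles optimize the 15 states sequentially: the relaxed ligand frame
of state k seeds state k+1, the fresh moiety is laid on the N2-site axis and
pre-relaxed against the frozen frame, then everything is relaxed.  A failed
state restarts from the Mo–N2 reference; a second failure discards the
catalyst with the state index.  Step energies include the donor/byproduct
terms (LutH+/Lut, CrCp\*2 pair, free NH3, free N2), so the 15 steps
telescope exactly to the overall reaction energy
N2 + 6 LutH+ + 6 CrCp\*2 → 2 NH3 + 6 Lut + 6 CrCp\*2+ (asserted to
1e−6 kcal/mol).

Ligand substitution analysis replaces each of the 4–5 ligand sites with
NH2− (anionic) or NH3 (neutral) — single points, no re-optimization — first
individually, then cumulatively in descending order of the individual
increase (ties broken by site label), reporting E_p and its change per row.

## Scaling relations and volcano

Every step energy is regressed (ordinary least squares) on the
first-protonation step energy relative to the Mo–N2 resting state (sign
convention: positive = endergonic).  Relations with R² < 0.2 are reported
separately and excluded.  A step with exactly zero variance is recorded as a
flat line with R² = 1 (it is perfectly predictable).  The volcano's limiting
curve is the pointwise maximum of the retained lines over a grid of 201
points spanning the observed descriptor range ± 20%; the apex is the grid
argmin, ties at intersections credit all attaining steps, and an apex on the
grid boundary (or an all-same-sign slope family) is flagged rather than
trusted.

## Synthetic data

`toy_ligand_library` samples from curated pools (≤ 12 heavy atoms) covering
every donor class, so full pre-screen + scoring runs in seconds.
`planted_optimum_benchmark` pins a library in which exactly one neutral
family (phosphines) carries a motif, and surrogate parameters granting that
motif a −40 kcal/mol bonus on both N2H states — lowering E_p by 40 while
leaving E_r untouched — so the global optimum is known by construction and
verified by exhaustive enumeration of the library.  `synthetic_profiles`
draws the descriptor uniformly from [−5, 30] kcal/mol and generates step
energies on planted lines plus Gaussian noise, with state energies as
partial sums so the telescoping invariant holds by construction.  None of
these emulate real conformational entropy, solvation, spin-state crossings
or DFT-level electronic structure; conclusions from passing tests are about
the algorithmic machinery only.

## Numerical choices

- Optimizer: L-BFGS-B, analytic gradients, gradient tolerance 0.1
  kcal/mol/Å on the max atomic force, iteration cap 5000; frozen atoms via
  equal bounds.
- Tie-breaks: donor ties → smallest canonical atom index; stereoisomer ties
  → lexicographically smallest label; substitution-order ties → site label.
- Degenerate inputs: zero-atom structures, unparsable SMILES, charge
  mismatches and site-map gaps raise validation errors; embedding and
  convergence failures are signalled distinctly so callers can apply the
  discard/fallback rules.
- Determinism: every stochastic component (embedding, GA, diversity filter,
  synthetic data) is seeded; repeated runs are asserted bit-identical.

## Known limitations

- The surrogate has no angular terms; its geometric mode keeps rings and
  coordination shells sane through bond terms, weak nonbonded repulsion and
  the template-based initial placement, not through a real force field.
- Heteroleptic anionic mixtures, polydentate ligands and metals other than
  Mo are out of scope (the template is parameterized but only Mo is
  exercised).
- DFT stages of the funnel are parameterized as backend hooks; no DFT engine
  ships with the package.
- The extended-Hückel check runs at neutral electron count regardless of the
  state charge.
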