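# mofix

Genetic-algorithm discovery of homoleptic molybdenum nitrogen-fixation
catalysts.

## The problem

Molecular nitrogen fixation by homogeneous Mo catalysts proceeds through the
Schrock cycle: a Mo-bound N2 is converted to two NH3 by six alternating
proton transfers (from lutidinium, LutH+) and electron transfers (from
decamethylchromocene, CrCp\*2), passing through 15 intermediates.  The first
protonation, Mo–N2 → Mo–N2H+, is notoriously endergonic and limits known
catalysts.  `mofix` searches ligand space for homoleptic complexes — exactly
3 identical anionic ligands plus 1 (trigonal bipyramidal) or 2 (octahedral)
identical neutral ligands around Mo — whose first protonation and first
reduction are as exergonic as possible, while staying synthetically
accessible.

## The method

A graph-based genetic algorithm evolves the (anionic, neutral) ligand pair:

1. **Pre-screening** — SMARTS patterns find candidate donor atoms (carbenes,
   phosphines, amines, oxygens for neutral ligands; halides, alkoxides,
   amides, carbanions for anionic ones); the donor with the lowest binding
   energy to a Mo–N2 core is kept, and the lowest-energy stereoisomer is
   chosen from the full enumeration (3 distinct octahedral, 4 trigonal-
   bipyramidal placements, deduplicated under the proper rotation group).
2. **Scoring** — electronic reaction energies of the first protonation (E_p)
   and reduction (E_r), each from the lowest surviving conformer of a
   4-conformer protocol (20 kcal/mol relative-energy cutoff, extended-Hückel
   connectivity check at overlap threshold 0.15), are min–max normalized with
   min(x) = 100 and max(x) = −100 kcal/mol and combined with a two-stage
   synthetic-accessibility term:

       Score = E_p-norm × E_r-norm × SA_score

   A reaction energy of 10 kcal/mol corresponds to a normalized value of
   0.45.
3. **Evolution** — rank-roulette selection, one-ligand-type cut-and-splice
   crossover, graph-edit mutation, elitist survivors; admitted complexes have
   2–100 heavy atoms and at most 20 rotatable bonds.
4. **Validation funnel** — deep conformer re-scoring (500 embeddings, RMSD
   pruning 1 Å, SA omitted), Morgan-fingerprint (radius 3) Tanimoto 0.6
   diversity pruning, a 10 kcal/mol cutoff on both reaction energies, full
   15-state cycle profiles with sequential geometry propagation, and an
   NH2−/NH3 ligand-substitution attribution of the protonation energy.
5. **Volcano analysis** — each cycle step is fitted linearly against the
   first-protonation descriptor (R² ≥ 0.2 retained); the pointwise maximum of
   the retained lines is the limiting curve, its minimum the volcano apex,
   and the line attaining the maximum the potential-determining step.

Energy evaluation sits behind a pluggable backend: a deterministic surrogate
potential (pinned parameters, analytic optimum — used by all shipped tests),
an adapter for an external GFN2-xTB / GFN-FF executable, an RDKit UFF
pre-optimizer, and a DFT hook.

## Worked example

```bash
mofix fixtures make-library --n-anionic 4 --n-neutral 4 --seed 1 --out lib.smi
mofix evolve --ligands lib.smi --pop 10 --gens 10 --seed 7 --out run1
```

prints

```
best score 0.2819: anionic C[N-]C neutral c1ccncc1 stereo A,A,A,L,L,N2
```

i.e. the best catalyst after 10 generations pairs dimethylamide anions with
pyridine in the octahedral arrangement whose neutral ligands sit cis, with a
GA score of 0.2819 (the product of the two normalized reaction energies and
the SA term; 1.0 would be a perfectly accessible catalyst with both energies
at or below −100 kcal/mol).  A full catalytic-cycle profile for one catalyst:

```bash
mofix cycle --anionic "C[O-]" --neutral "c1ccncc1" --out cyc
# Ep(first protonation) = -10.00 kcal/mol; overall cycle -558.00 kcal/mol
```

The first protonation of this methoxide/pyridine complex is exergonic by
10 kcal/mol at the surrogate level, and the 15 step energies sum to the
overall reaction energy of N2 + 6 LutH+ + 6 CrCp\*2 → 2 NH3 + 6 Lut +
6 CrCp\*2+, as they must.  Scaling relations and the volcano:

```bash
mofix fixtures make-profiles --n 36 --noise-sd 1.0 --seed 2 --out profiles.jsonl
mofix volcano --profiles profiles.jsonl --out volc
# 15 relations retained (R2 >= 0.2); apex at -0.95 kcal/mol, limiting energy 18.00
```

## Layout

- `src/mofix/complex_model.py` — ligands, templates, stereoisomers, cycle
  states, assembly, conformer embedding
- `src/mofix/energy_backend.py` — surrogate / xTB / UFF / DFT-hook backends,
  extended-Hückel connectivity check
- `src/mofix/prescreen.py` — donor-atom and stereoisomer selection
- `src/mofix/scoring.py` — E_p, E_r, normalization, SA shaping, total score
- `src/mofix/ga_engine.py` — crossover, mutation, constraints, the GA loop
- `src/mofix/validation_pipeline.py` — re-scoring, diversity and energy
  filters, full cycle profiles, substitution analysis
- `src/mofix/volcano.py` — scaling relations and volcano construction
- `src/mofix/fixtures.py` — toy libraries, planted-optimum benchmark,
  synthetic profile ensembles
- `docs/methods.md` — model assumptions, parameter choices, limitations
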