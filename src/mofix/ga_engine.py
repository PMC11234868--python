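"""Graph-based genetic algorithm over homoleptic Mo catalyst ligands.

An individual is a catalyst graph (one anionic + one neutral ligand species
on a fixed coordination template).  Evolution follows the classic
cut-and-splice graph GA: parents are chosen by rank-based roulette, crossover
modifies exactly one ligand type (a random acyclic single bond is cut in each
parent's ligand of that type and complementary fragments are re-spliced),
mutation applies one of a small table of graph edits, and survivor selection
is elitist (top ``population_size`` of parents + children by total score), so
the best score never decreases.  Children re-enter pre-screening: donor atom
and stereoisomer are re-selected before scoring.

Admission constraints (on the assembled complex): 2-100 heavy atoms and at
most 20 rotatable bonds; ligand copies of each type are identical by
construction.  Everything is deterministic given (library, config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from .complex_model import (
    CatalystGraph,
    CoordinationTemplate,
    LigandSpec,
    SCHROCK_CYCLE,
    ValidationError,
    find_donor_candidates,
)
from .prescreen import (
    NoDonorError,
    PrescreenConfig,
    StereoSelectionError,
    prescreen_catalyst,
)
from .scoring import ScoreBreakdown, ScoringConfig, total_score

__all__ = [
    "Constraints",
    "GAConfig",
    "Individual",
    "GenerationRecord",
    "CrossoverFailure",
    "init_population",
    "crossover_ligands",
    "crossover",
    "mutate_ligand",
    "mutate",
    "enforce_constraints",
    "run_ga",
]


class CrossoverFailure(RuntimeError):
    """No valid splice was found within the retry budget; parents are retained."""


@dataclass(frozen=True)
class Constraints:
    min_heavy: int = 2
    max_heavy: int = 100
    max_rotatable: int = 20


@dataclass
class GAConfig:
    population_size: int = 50
    n_generations: int = 50
    mutation_rate: float = 0.3
    crossover_rate: float = 1.0
    template: CoordinationTemplate = field(
        default_factory=CoordinationTemplate.octahedral
    )
    seed: int = 0
    constraints: Constraints = field(default_factory=Constraints)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    prescreen: PrescreenConfig = field(default_factory=PrescreenConfig)
    max_attempts_per_child: int = 20

    def __post_init__(self) -> None:
        if not (0.0 <= self.mutation_rate <= 1.0 and 0.0 <= self.crossover_rate <= 1.0):
            raise ValidationError("rates must lie in [0, 1]")
        if self.population_size < 1 or self.n_generations < 0:
            raise ValidationError("sizes must be positive")


@dataclass
class Individual:
    catalyst: CatalystGraph
    score: ScoreBreakdown | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        return self.score.total if self.score is not None else 0.0

    def to_record(self) -> dict:
        return {
            "smiles_anionic": self.catalyst.anionic.smiles,
            "smiles_neutral": self.catalyst.neutral.smiles,
            "donor_anionic": self.catalyst.anionic.donor_atom_index,
            "donor_neutral": self.catalyst.neutral.donor_atom_index,
            "stereo": self.catalyst.stereo_label,
            "score": self.score.to_dict() if self.score else None,
            "provenance": self.provenance,
        }


@dataclass
class GenerationRecord:
    generation: int
    individuals: list[Individual]

    @property
    def best(self) -> Individual:
        return max(self.individuals, key=lambda ind: ind.total)


# --------------------------------------------------------------------------- #
# Constraints
# --------------------------------------------------------------------------- #


def enforce_constraints(catalyst: CatalystGraph, constraints: Constraints) -> bool:
    """Heavy-atom and rotatable-bond limits on the assembled complex graph."""
    mol = catalyst.assemble(SCHROCK_CYCLE[0])
    heavy = mol.GetNumHeavyAtoms()
    if not (constraints.min_heavy <= heavy <= constraints.max_heavy):
        return False
    rot = rdMolDescriptors.CalcNumRotatableBonds(mol)
    return rot <= constraints.max_rotatable


# --------------------------------------------------------------------------- #
# Crossover
# --------------------------------------------------------------------------- #


def _cuttable_bonds(mol: Chem.Mol) -> list[int]:
    out = []
    for bond in mol.GetBonds():
        if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        out.append(bond.GetIdx())
    return out


def _fragments_with_dummies(mol: Chem.Mol, bond_idx: int) -> tuple[Chem.Mol, Chem.Mol]:
    frag = Chem.FragmentOnBonds(mol, [bond_idx], addDummies=True, dummyLabels=[(1, 1)])
    parts = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=False)
    if len(parts) != 2:
        raise CrossoverFailure("cut did not produce two fragments")
    return parts[0], parts[1]


def _frag_charge(mol: Chem.Mol) -> int:
    return sum(a.GetFormalCharge() for a in mol.GetAtoms())


def _splice(frag_a: Chem.Mol, frag_b: Chem.Mol) -> Chem.Mol | None:
    combined = Chem.CombineMols(frag_a, frag_b)
    try:
        params = Chem.MolzipParams()
        params.label = Chem.MolzipLabel.Isotope
        zipped = Chem.molzip(combined, params)
        Chem.SanitizeMol(zipped)
    except Exception:  # noqa: BLE001 - invalid chemistry: caller retries
        return None
    return zipped


def crossover_ligands(
    lig_a: LigandSpec, lig_b: LigandSpec, rng: np.random.Generator, max_tries: int = 20
) -> LigandSpec:
    """Cut-and-splice crossover of two same-class ligands.

    A random acyclic single bond is cut in each parent and one fragment from
    each is joined at the cut, preserving the net formal charge of the class
    (for anionic ligands the charge-bearing fragments cannot both enter the
    child).  Single-atom or otherwise uncuttable ligands fall back to
    inheriting one parent ligand whole.
    """
    if lig_a.charge_class != lig_b.charge_class:
        raise ValidationError("crossover requires ligands of the same charge class")
    mol_a, mol_b = lig_a.mol(), lig_b.mol()
    bonds_a, bonds_b = _cuttable_bonds(mol_a), _cuttable_bonds(mol_b)
    target_charge = lig_a.formal_charge
    if not bonds_a or not bonds_b:
        pick = lig_a if rng.random() < 0.5 else lig_b
        return LigandSpec(pick.smiles, pick.charge_class)
    identical = lig_a.smiles == lig_b.smiles
    for _ in range(max_tries):
        ba = bonds_a[int(rng.integers(len(bonds_a)))]
        # identical parents cut the same bond so the splice is closed under identity
        bb = ba if identical else bonds_b[int(rng.integers(len(bonds_b)))]
        try:
            fa1, fa2 = _fragments_with_dummies(mol_a, ba)
            fb1, fb2 = _fragments_with_dummies(mol_b, bb)
        except CrossoverFailure:
            continue
        if identical:
            pieces = [(fa1, fb2), (fa2, fb1)]
        else:
            pieces = [(fa1, fb1), (fa1, fb2), (fa2, fb1), (fa2, fb2)]
        order = rng.permutation(len(pieces))
        for k in order:
            pa, pb = pieces[int(k)]
            if _frag_charge(pa) + _frag_charge(pb) != target_charge:
                continue
            child = _splice(pa, pb)
            if child is None:
                continue
            smiles = Chem.MolToSmiles(child)
            try:
                return LigandSpec(smiles, lig_a.charge_class)
            except ValidationError:
                continue
    raise CrossoverFailure("no valid splice found")


def crossover(
    parent_a: CatalystGraph,
    parent_b: CatalystGraph,
    rng: np.random.Generator,
    prescreen_config: PrescreenConfig | None = None,
    max_tries: int = 20,
) -> CatalystGraph:
    """One-ligand-type crossover: the child keeps the base parent's other ligand.

    The base parent and the modified ligand type are chosen at random; the
    modified ligand is the cut-and-splice product of the two parents' ligands
    of that type.  The child is re-pre-screened (donor + stereoisomer).
    """
    if parent_a.template.geometry != parent_b.template.geometry:
        raise ValidationError("parents must share a coordination template")
    base, other = (parent_a, parent_b) if rng.random() < 0.5 else (parent_b, parent_a)
    which = "anionic" if rng.random() < 0.5 else "neutral"
    if which == "anionic":
        new_lig = crossover_ligands(base.anionic, other.anionic, rng, max_tries)
        anionic, neutral = new_lig, LigandSpec(
            base.neutral.smiles, "neutral"
        )
    else:
        new_lig = crossover_ligands(base.neutral, other.neutral, rng, max_tries)
        anionic, neutral = LigandSpec(base.anionic.smiles, "anionic"), new_lig
    return prescreen_catalyst(anionic, neutral, base.template, prescreen_config)


# --------------------------------------------------------------------------- #
# Mutation
# --------------------------------------------------------------------------- #

_MUTATION_ELEMENTS = ["C", "N", "O", "F", "P", "S", "Cl"]


def _op_append_atom(mol: Chem.RWMol, rng: np.random.Generator) -> bool:
    idx = int(rng.integers(mol.GetNumAtoms()))
    atom = mol.GetAtomWithIdx(idx)
    if atom.GetFormalCharge() != 0 or atom.GetTotalNumHs() == 0:
        return False
    new = Chem.Atom(_MUTATION_ELEMENTS[int(rng.integers(len(_MUTATION_ELEMENTS)))])
    j = mol.AddAtom(new)
    mol.AddBond(idx, j, Chem.BondType.SINGLE)
    return True


def _op_delete_atom(mol: Chem.RWMol, rng: np.random.Generator) -> bool:
    candidates = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetDegree() == 1 and a.GetFormalCharge() == 0
    ]
    if not candidates or mol.GetNumAtoms() <= 1:
        return False
    mol.RemoveAtom(candidates[int(rng.integers(len(candidates)))])
    return True


def _op_substitute_atom(mol: Chem.RWMol, rng: np.random.Generator) -> bool:
    idx = int(rng.integers(mol.GetNumAtoms()))
    atom = mol.GetAtomWithIdx(idx)
    if atom.GetFormalCharge() != 0 or atom.GetIsAromatic():
        return False
    new_elem = _MUTATION_ELEMENTS[int(rng.integers(len(_MUTATION_ELEMENTS)))]
    if new_elem == atom.GetSymbol():
        return False
    atom.SetAtomicNum(Chem.GetPeriodicTable().GetAtomicNumber(new_elem))
    return True


def _op_change_bond(mol: Chem.RWMol, rng: np.random.Generator) -> bool:
    bonds = [
        b
        for b in mol.GetBonds()
        if not b.GetIsAromatic()
        and b.GetBondType() in (Chem.BondType.SINGLE, Chem.BondType.DOUBLE)
    ]
    if not bonds:
        return False
    bond = bonds[int(rng.integers(len(bonds)))]
    bond.SetBondType(
        Chem.BondType.DOUBLE
        if bond.GetBondType() == Chem.BondType.SINGLE
        else Chem.BondType.SINGLE
    )
    return True


#: pinned operator table with selection weights
MUTATION_OPERATORS: list[tuple[str, Callable, float]] = [
    ("append_atom", _op_append_atom, 0.35),
    ("delete_atom", _op_delete_atom, 0.25),
    ("substitute_atom", _op_substitute_atom, 0.25),
    ("change_bond", _op_change_bond, 0.15),
]


def mutate_ligand(
    ligand: LigandSpec, rng: np.random.Generator, max_tries: int = 20
) -> LigandSpec:
    """Apply one graph-edit operator; returns the input if no edit is valid.

    The net formal charge (hence charge class) is always preserved: operators
    never touch charged atoms.
    """
    names = [n for n, _, _ in MUTATION_OPERATORS]
    weights = np.array([w for _, _, w in MUTATION_OPERATORS])
    weights = weights / weights.sum()
    for _ in range(max_tries):
        op_name = names[int(rng.choice(len(names), p=weights))]
        op = dict((n, f) for n, f, _ in MUTATION_OPERATORS)[op_name]
        rw = Chem.RWMol(ligand.mol())
        try:
            if not op(rw, rng):
                continue
            out = rw.GetMol()
            Chem.SanitizeMol(out)
            candidate = LigandSpec(Chem.MolToSmiles(out), ligand.charge_class)
        except Exception:  # noqa: BLE001 - invalid chemistry: retry
            continue
        if find_donor_candidates(candidate):
            return candidate
    return LigandSpec(ligand.smiles, ligand.charge_class)


def mutate(
    individual: Individual,
    rng: np.random.Generator,
    config: GAConfig,
) -> CatalystGraph:
    """With probability ``mutation_rate`` mutate one randomly chosen ligand type."""
    cat = individual.catalyst
    if rng.random() >= config.mutation_rate:
        return cat
    which = "anionic" if rng.random() < 0.5 else "neutral"
    if which == "anionic":
        new = mutate_ligand(cat.anionic, rng)
        anionic, neutral = new, LigandSpec(cat.neutral.smiles, "neutral")
    else:
        new = mutate_ligand(cat.neutral, rng)
        anionic, neutral = LigandSpec(cat.anionic.smiles, "anionic"), new
    return prescreen_catalyst(anionic, neutral, cat.template, config.prescreen)


# --------------------------------------------------------------------------- #
# Population machinery
# --------------------------------------------------------------------------- #


def _score_catalyst(
    catalyst: CatalystGraph, config: GAConfig, cache: dict[str, ScoreBreakdown]
) -> ScoreBreakdown:
    key = catalyst.canonical_key()
    if key not in cache:
        cache[key] = total_score(catalyst, config.scoring)
    return cache[key]


def init_population(
    library: Sequence[LigandSpec], config: GAConfig
) -> tuple[list[Individual], dict[str, ScoreBreakdown]]:
    """Sample, pre-screen and score the initial population (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    anionic_pool = [l for l in library if l.charge_class == "anionic"]
    neutral_pool = [l for l in library if l.charge_class == "neutral"]
    usable_a, usable_n = [], []
    for pool, usable in ((anionic_pool, usable_a), (neutral_pool, usable_n)):
        for lig in pool:
            if find_donor_candidates(lig):
                usable.append(lig)
    if not usable_a or not usable_n:
        raise ValidationError(
            "library must contain at least one scoreable anionic and neutral ligand"
        )
    cache: dict[str, ScoreBreakdown] = {}
    population: list[Individual] = []
    seen: set[str] = set()
    attempts = 0
    while len(population) < config.population_size and attempts < 50 * config.population_size:
        attempts += 1
        a = usable_a[int(rng.integers(len(usable_a)))]
        n = usable_n[int(rng.integers(len(usable_n)))]
        try:
            cat = prescreen_catalyst(
                LigandSpec(a.smiles, "anionic"),
                LigandSpec(n.smiles, "neutral"),
                config.template,
                config.prescreen,
            )
        except (NoDonorError, StereoSelectionError):
            continue
        if not enforce_constraints(cat, config.constraints):
            continue
        key = cat.canonical_key()
        if key in seen and len(seen) < len(usable_a) * len(usable_n):
            continue
        seen.add(key)
        score = _score_catalyst(cat, config, cache)
        population.append(Individual(cat, score, {"op": "init"}))
    if not population:
        raise ValidationError("no scoreable individual could be built from the library")
    return population, cache


def _rank_roulette(
    population: list[Individual], rng: np.random.Generator
) -> Individual:
    order = sorted(population, key=lambda ind: ind.total)
    ranks = np.arange(1, len(order) + 1, dtype=float)
    probs = ranks / ranks.sum()
    return order[int(rng.choice(len(order), p=probs))]


def run_ga(
    library: Sequence[LigandSpec], config: GAConfig
) -> list[GenerationRecord]:
    """Evolve the population; returns one record per generation (0 = initial).

    Elitist survivor selection makes the best total score non-decreasing.
    Stops early with the recorded generations if the population collapses.
    """
    rng = np.random.default_rng(config.seed + 1)
    population, cache = init_population(library, config)
    archive = [GenerationRecord(0, list(population))]
    for gen in range(1, config.n_generations + 1):
        children: list[Individual] = []
        child_keys: set[str] = set()
        attempts = 0
        while (
            len(children) < config.population_size
            and attempts < config.max_attempts_per_child * config.population_size
        ):
            attempts += 1
            try:
                if rng.random() < config.crossover_rate and len(population) >= 2:
                    pa = _rank_roulette(population, rng)
                    pb = _rank_roulette(population, rng)
                    cat = crossover(
                        pa.catalyst, pb.catalyst, rng, config.prescreen
                    )
                    prov = {"op": "crossover"}
                else:
                    pa = _rank_roulette(population, rng)
                    cat = pa.catalyst
                    prov = {"op": "copy"}
                child = Individual(cat, None, prov)
                mutated = mutate(child, rng, config)
                if mutated is not cat:
                    child = Individual(mutated, None, {**prov, "mutated": True})
            except (CrossoverFailure, NoDonorError, StereoSelectionError, ValidationError):
                continue
            if not enforce_constraints(child.catalyst, config.constraints):
                continue
            key = child.catalyst.canonical_key()
            if key in child_keys:
                continue
            child_keys.add(key)
            child.score = _score_catalyst(child.catalyst, config, cache)
            children.append(child)
        pool = population + children
        if not pool:
            break
        # elitist survivor selection, deduplicated within the generation
        pool.sort(key=lambda ind: (-ind.total, ind.catalyst.canonical_key()))
        survivors: list[Individual] = []
        survivor_keys: set[str] = set()
        for ind in pool:
            key = ind.catalyst.canonical_key()
            if key in survivor_keys:
                continue
            survivor_keys.add(key)
            survivors.append(ind)
            if len(survivors) == config.population_size:
                break
        population = survivors
        archive.append(GenerationRecord(gen, list(population)))
    return archive


def save_archive(archive: list[GenerationRecord], path: str | Path) -> Path:
    path = Path(path)
    payload = [
        {
            "generation": rec.generation,
            "individuals": [ind.to_record() for ind in rec.individuals],
            "best_total": rec.best.total,
        }
        for rec in archive
    ]
    path.write_text(json.dumps(payload, indent=1))
    return path
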