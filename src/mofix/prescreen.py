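"""Pre-screening: pick the donor atom per ligand and the stereoisomer per catalyst.

For each candidate donor atom the binding energy of the ligand to a bare
Mo-N2 core is evaluated (cheap protocol: analytic surrogate optimum, or a
force-field pre-optimization followed by a tight-binding single point when an
external backend is configured) and the atom with the lowest binding energy
wins.  Then every stereoisomer of the full complex is evaluated once and the
lowest-energy label is kept.  Both selections are deterministic: ties break
to the smallest canonical atom index / lexicographically smallest label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem

from .complex_model import (
    CatalystGraph,
    CoordinationTemplate,
    IntermediateState,
    LigandSpec,
    SCHROCK_CYCLE,
    ValidationError,
    EmbeddingError,
    assemble_complex,
    embed_conformers,
    enumerate_stereoisomers,
    find_donor_candidates,
)
from .energy_backend import (
    BackendConfig,
    EnergyResult,
    get_backend,
)

__all__ = [
    "PrescreenConfig",
    "NoDonorError",
    "StereoSelectionError",
    "binding_energy",
    "select_donor_atom",
    "select_stereoisomer",
    "prescreen_catalyst",
]


class NoDonorError(ValidationError):
    """Ligand has no donor candidate (or none could be evaluated): catalyst invalid."""


class StereoSelectionError(RuntimeError):
    """Every stereoisomer evaluation failed: catalyst rejected."""


class BindingEvaluationError(RuntimeError):
    """A term of the binding energy did not converge; result excluded from ranking."""


@dataclass
class PrescreenConfig:
    backend: BackendConfig = field(default_factory=BackendConfig)
    use_3d: bool = False  # analytic surrogate fast path by default
    seed: int = 0
    embed_n_confs: int = 1


def _core_state() -> IntermediateState:
    return SCHROCK_CYCLE[0]


def _core_mol() -> Chem.Mol:
    """Bare [Mo-N2] probe fragment used for donor screening."""
    rw = Chem.RWMol()
    mo = Chem.Atom(42)
    mo.SetNoImplicit(True)
    i_mo = rw.AddAtom(mo)
    rw.GetAtomWithIdx(i_mo).SetProp("mofixRole", "metal")
    n1 = Chem.Atom(7); n1.SetNoImplicit(True)
    n2 = Chem.Atom(7); n2.SetNoImplicit(True)
    i1, i2 = rw.AddAtom(n1), rw.AddAtom(n2)
    for i in (i1, i2):
        rw.GetAtomWithIdx(i).SetProp("mofixRole", "moiety")
    rw.AddBond(i1, i2, Chem.BondType.TRIPLE)
    rw.AddBond(i1, i_mo, Chem.BondType.DATIVE)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    mol.SetProp("mofixStateKey", _core_state().state_key)
    return mol


def _core_plus_ligand(ligand: LigandSpec, donor_index: int) -> Chem.Mol:
    rw = Chem.RWMol(_core_mol())
    lig = ligand.mol()
    offset = rw.GetNumAtoms()
    for atom in lig.GetAtoms():
        a = Chem.Atom(atom.GetAtomicNum())
        a.SetFormalCharge(atom.GetFormalCharge())
        a.SetNumExplicitHs(atom.GetTotalNumHs())
        a.SetNoImplicit(True)
        a.SetIsAromatic(atom.GetIsAromatic())
        idx = rw.AddAtom(a)
        rw.GetAtomWithIdx(idx).SetProp("mofixRole", "ligand")
    for bond in lig.GetBonds():
        rw.AddBond(
            bond.GetBeginAtomIdx() + offset,
            bond.GetEndAtomIdx() + offset,
            bond.GetBondType(),
        )
    rw.AddBond(donor_index + offset, 0, Chem.BondType.DATIVE)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    mol.SetProp("mofixStateKey", _core_state().state_key)
    return mol


def _mol_energy(mol: Chem.Mol, config: PrescreenConfig) -> float:
    backend = get_backend(config.backend)
    if not config.use_3d and hasattr(backend, "analytic_energy"):
        return backend.analytic_energy(mol)
    confs = embed_conformers(mol, config.embed_n_confs, seed=config.seed)
    results = [backend.optimize(c) for c in confs]
    ok = [r.energy for r in results if r.converged]
    if not ok:
        raise BindingEvaluationError("no converged geometry")
    return min(ok)


def binding_energy(
    ligand: LigandSpec, donor_index: int, config: PrescreenConfig | None = None
) -> float:
    """E(core·ligand) - E(core) - E(ligand) against the bare Mo-N2 probe core."""
    config = config or PrescreenConfig()
    if donor_index not in find_donor_candidates(ligand):
        # symmetry-duplicates of listed candidates are legitimate too
        from .complex_model import symmetry_class

        classes = {symmetry_class(ligand, i) for i in find_donor_candidates(ligand)}
        if symmetry_class(ligand, donor_index) not in classes:
            raise ValidationError(
                f"atom {donor_index} is not a donor candidate of {ligand.smiles!r}"
            )
    e_pair = _mol_energy(_core_plus_ligand(ligand, donor_index), config)
    e_core = _mol_energy(_core_mol(), config)
    lig_mol = ligand.mol()
    e_lig = _mol_energy(lig_mol, config)
    return e_pair - e_core - e_lig


def select_donor_atom(
    ligand: LigandSpec, config: PrescreenConfig | None = None
) -> LigandSpec:
    """Assign the donor atom minimizing the core binding energy (ties: lowest index)."""
    config = config or PrescreenConfig()
    candidates = find_donor_candidates(ligand)
    if not candidates:
        raise NoDonorError(f"no donor candidates in {ligand.smiles!r}")
    if len(candidates) == 1:
        return ligand.with_donor(candidates[0])
    best_idx, best_e = None, None
    for idx in candidates:  # ascending index, so ties keep the smallest
        try:
            e = binding_energy(ligand, idx, config)
        except BindingEvaluationError:
            continue
        if best_e is None or e < best_e - 1e-12:
            best_idx, best_e = idx, e
    if best_idx is None:
        raise NoDonorError(f"no donor of {ligand.smiles!r} could be evaluated")
    return ligand.with_donor(best_idx)


def select_stereoisomer(
    anionic: LigandSpec,
    neutral: LigandSpec,
    template: CoordinationTemplate,
    config: PrescreenConfig | None = None,
) -> tuple[str, EnergyResult]:
    """Evaluate each stereoisomer once and return the lowest-energy label."""
    config = config or PrescreenConfig()
    labels = enumerate_stereoisomers(template)
    backend = get_backend(config.backend)
    state = _core_state()
    best: tuple[str, EnergyResult] | None = None
    for label in labels:  # sorted, so ties keep the lexicographically smallest
        try:
            mol = assemble_complex(anionic, neutral, template, label, state)
            if not config.use_3d and hasattr(backend, "analytic_energy"):
                energy = backend.analytic_energy(mol)
                result = EnergyResult(energy, None, True, backend.backend_id)
            else:
                confs = embed_conformers(mol, config.embed_n_confs, seed=config.seed)
                result = backend.optimize(confs[0])
                if not result.converged:
                    continue
        except (EmbeddingError, ValidationError):
            continue
        if best is None or result.energy < best[1].energy - 1e-12:
            best = (label, result)
    if best is None:
        raise StereoSelectionError("all stereoisomer evaluations failed")
    return best


def prescreen_catalyst(
    anionic: LigandSpec,
    neutral: LigandSpec,
    template: CoordinationTemplate,
    config: PrescreenConfig | None = None,
) -> CatalystGraph:
    """Full pre-screen: donor atoms, then stereoisomer; returns the catalyst graph."""
    config = config or PrescreenConfig()
    if anionic.donor_atom_index is None:
        anionic = select_donor_atom(anionic, config)
    if neutral.donor_atom_index is None:
        neutral = select_donor_atom(neutral, config)
    label, _result = select_stereoisomer(anionic, neutral, template, config)
    return CatalystGraph(anionic, neutral, template, label)
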