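"""The GA fitness: two reaction energies, min-max normalization, SA shaping.

The score of a catalyst is

    Score = Ep_norm * Er_norm * SA_score

where Ep is the electronic energy of the first protonation of the bound N2
(proton donor: lutidinium),

    Ep:  Mo-N2 + LutH+  ->  Mo-N2H+ + Lut

Er is the first reduction (electron donor: decamethylchromocene),

    Er:  Mo-N2H+ + CrCp*2  ->  Mo-N2H + CrCp*2+

and each complex energy comes from the lowest surviving conformer of a
4-conformer protocol: embed, check connectivity, optimize, check connectivity
again, discard conformers more than 20 kcal/mol above the best.  Reaction
energies are min-max normalized with min(x) = 100 and max(x) = -100 kcal/mol
(lower energy -> higher score, clipped into [0, 1]), so a reaction energy of
10 kcal/mol maps to 0.45 and the interval [-100, 100] spans the whole score
range.

The synthetic-accessibility term uses the Ertl-Schuffenhauer score (raw 1-10)
per ligand (anionic ligands are neutralized at the donor atom first), mapped
through a Gaussian score modifier, averaged over all ligand copies, and then
squeezed through a second modifier that flattens the upper range so catalysts
with already-reasonable SA are not over-rewarded.
"""

from __future__ import annotations

import math
import os
import sys
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from rdkit import Chem
from rdkit.Chem import RDConfig

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib module, shipped with rdkit)

from .complex_model import (
    CatalystGraph,
    IntermediateState,
    LigandSpec,
    SCHROCK_CYCLE,
    EmbeddingError,
    ValidationError,
    embed_conformers,
)
from .energy_backend import BackendConfig, check_connectivity, get_backend

__all__ = [
    "NormalizationSpec",
    "ScoreBreakdown",
    "ScoringConfig",
    "ScoringFailure",
    "normalize_energy",
    "reaction_energy_protonation",
    "reaction_energy_reduction",
    "intermediate_energy",
    "sa_score",
    "sa_squeeze",
    "total_score",
    "DONOR_SPECIES_FORMULA",
]


class ScoringFailure(RuntimeError):
    """All conformers of some intermediate were discarded; the catalyst scores 0."""


@dataclass(frozen=True)
class NormalizationSpec:
    """Min-max bounds of the energy -> score map; lower energy maps higher."""

    min_x: float = 100.0
    max_x: float = -100.0

    def __post_init__(self) -> None:
        if not self.min_x > self.max_x:
            raise ValidationError("normalization needs min_x > max_x")


def normalize_energy(x: float, spec: NormalizationSpec | None = None) -> float:
    """clip((min_x - x) / (min_x - max_x), 0, 1); 0.45 at x=10 for the defaults."""
    spec = spec or NormalizationSpec()
    return float(np.clip((spec.min_x - x) / (spec.min_x - spec.max_x), 0.0, 1.0))


@dataclass
class SAParams:
    """Pinned parameters of the two-stage SA shaping."""

    stage1_mu: float = 1.0     # best possible raw Ertl-Schuffenhauer score
    stage1_sigma: float = 2.5
    squeeze_sigma: float = 1.0893  # Gaussian branch: f(0.5) = 0.9, f(1) = 1


@dataclass
class ScoringConfig:
    backend: BackendConfig = field(default_factory=BackendConfig)
    normalization: NormalizationSpec = field(default_factory=NormalizationSpec)
    sa: SAParams = field(default_factory=SAParams)
    n_confs: int = 4
    conformer_cutoff: float = 20.0  # kcal/mol above the best conformer
    connectivity_threshold: float = 0.15
    rmsd_prune: float = 0.5
    seed: int = 0
    use_3d: bool = False  # analytic surrogate fast path by default
    include_sa: bool = True


@dataclass
class ScoreBreakdown:
    E_p: float | None
    E_r: float | None
    E_p_norm: float
    E_r_norm: float
    sa_raw_per_ligand: list[float]
    sa_score: float
    total: float
    n_conformers_used: dict[str, int]
    failure_reason: str | None = None

    def to_dict(self) -> dict:
        return {
            "E_p": self.E_p,
            "E_r": self.E_r,
            "E_p_norm": self.E_p_norm,
            "E_r_norm": self.E_r_norm,
            "sa_raw_per_ligand": self.sa_raw_per_ligand,
            "sa_score": self.sa_score,
            "total": self.total,
            "n_conformers_used": self.n_conformers_used,
            "failure_reason": self.failure_reason,
        }


# element counts for the mass/charge balance assertions
DONOR_SPECIES_FORMULA: dict[str, tuple[dict[str, int], int]] = {
    "Lut": ({"C": 7, "H": 9, "N": 1}, 0),       # 2,6-lutidine
    "LutH+": ({"C": 7, "H": 10, "N": 1}, 1),
    "CrCp2": ({"C": 20, "H": 30, "Cr": 1}, 0),  # decamethylchromocene
    "CrCp2+": ({"C": 20, "H": 30, "Cr": 1}, 1),
}


def _mol_formula(mol: Chem.Mol) -> dict[str, int]:
    counts: dict[str, int] = {}
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
        h = atom.GetTotalNumHs()
        if h:
            counts["H"] = counts.get("H", 0) + h
    return counts


def _add_formula(a: dict[str, int], b: dict[str, int]) -> dict[str, int]:
    out = dict(a)
    for k, v in b.items():
        out[k] = out.get(k, 0) + v
    return {k: v for k, v in out.items() if v}


def _assert_balanced(
    lhs_mols: list[Chem.Mol],
    lhs_species: list[str],
    rhs_mols: list[Chem.Mol],
    rhs_species: list[str],
) -> None:
    lhs_f: dict[str, int] = {}
    rhs_f: dict[str, int] = {}
    lhs_q = rhs_q = 0
    for m in lhs_mols:
        lhs_f = _add_formula(lhs_f, _mol_formula(m))
        lhs_q += Chem.GetFormalCharge(m)
    for s in lhs_species:
        f, q = DONOR_SPECIES_FORMULA[s]
        lhs_f = _add_formula(lhs_f, f)
        lhs_q += q
    for m in rhs_mols:
        rhs_f = _add_formula(rhs_f, _mol_formula(m))
        rhs_q += Chem.GetFormalCharge(m)
    for s in rhs_species:
        f, q = DONOR_SPECIES_FORMULA[s]
        rhs_f = _add_formula(rhs_f, f)
        rhs_q += q
    if lhs_f != rhs_f:
        raise ValidationError(f"mass imbalance: {lhs_f} vs {rhs_f}")
    # the reduction step transfers one electron, so charge may differ by design
    # only through the donor pair, which is included above
    if lhs_q != rhs_q:
        raise ValidationError(f"charge imbalance: {lhs_q} vs {rhs_q}")


def intermediate_energy(
    catalyst: CatalystGraph, state: IntermediateState, config: ScoringConfig
) -> tuple[float, int]:
    """Lowest surviving conformer energy of one intermediate + conformer count.

    Analytic surrogate path: graph-level optimum, one effective conformer.
    3D path: the 4-conformer protocol with connectivity checks before and
    after optimization and the 20 kcal/mol relative-energy cutoff.
    """
    mol = catalyst.assemble(state)
    backend = get_backend(config.backend)
    if not config.use_3d and hasattr(backend, "analytic_energy"):
        return backend.analytic_energy(mol), 1
    try:
        confs = embed_conformers(mol, config.n_confs, config.rmsd_prune, config.seed)
    except EmbeddingError as exc:
        raise ScoringFailure(f"embedding failed for state {state.moiety}") from exc
    energies = []
    for conf in confs:
        if not check_connectivity(conf, threshold=config.connectivity_threshold):
            continue
        result = backend.optimize(conf)
        if not result.converged or result.geometry is None:
            continue
        if not check_connectivity(result.geometry, conf.mol, config.connectivity_threshold):
            continue
        energies.append(result.energy)
    if not energies:
        raise ScoringFailure(f"all conformers discarded for state {state.moiety}")
    best = min(energies)
    survivors = [e for e in energies if e <= best + config.conformer_cutoff]
    return min(survivors), len(survivors)


def _state(moiety: str, charge: int) -> IntermediateState:
    for s in SCHROCK_CYCLE:
        if s.moiety == moiety and s.total_charge == charge:
            return s
    raise ValidationError(f"no cycle state {moiety}|{charge}")


def reaction_energy_protonation(
    catalyst: CatalystGraph, config: ScoringConfig | None = None
) -> float:
    """Ep = [E(Mo-N2H+) + E(Lut)] - [E(Mo-N2) + E(LutH+)] in kcal/mol."""
    config = config or ScoringConfig()
    backend = get_backend(config.backend)
    s_n2, s_n2h = _state("N2", 0), _state("N2H", 1)
    _assert_balanced(
        [catalyst.assemble(s_n2)], ["LutH+"], [catalyst.assemble(s_n2h)], ["Lut"]
    )
    e_n2, _ = intermediate_energy(catalyst, s_n2, config)
    e_n2h, _ = intermediate_energy(catalyst, s_n2h, config)
    return (e_n2h + backend.species_energy("Lut")) - (
        e_n2 + backend.species_energy("LutH+")
    )


def reaction_energy_reduction(
    catalyst: CatalystGraph, config: ScoringConfig | None = None
) -> float:
    """Er = [E(Mo-N2H) + E(CrCp*2+)] - [E(Mo-N2H+) + E(CrCp*2)] in kcal/mol."""
    config = config or ScoringConfig()
    backend = get_backend(config.backend)
    s_cat, s_neu = _state("N2H", 1), _state("N2H", 0)
    _assert_balanced(
        [catalyst.assemble(s_cat)], ["CrCp2"], [catalyst.assemble(s_neu)], ["CrCp2+"]
    )
    e_cat, _ = intermediate_energy(catalyst, s_cat, config)
    e_neu, _ = intermediate_energy(catalyst, s_neu, config)
    return (e_neu + backend.species_energy("CrCp2+")) - (
        e_cat + backend.species_energy("CrCp2")
    )


# --------------------------------------------------------------------------- #
# Synthetic accessibility
# --------------------------------------------------------------------------- #


def neutralize_anionic(ligand: LigandSpec) -> Chem.Mol:
    """Protonate the anionic site (add one H, zero the charge) before SA scoring."""
    mol = Chem.RWMol(ligand.mol())
    anions = [a for a in mol.GetAtoms() if a.GetFormalCharge() == -1]
    if len(anions) != 1:
        raise ValidationError(
            f"cannot neutralize {ligand.smiles!r}: expected one anionic atom"
        )
    atom = anions[0]
    atom.SetFormalCharge(0)
    atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return out


def _gauss(x: float, mu: float, sigma: float) -> float:
    return math.exp(-0.5 * ((x - mu) / sigma) ** 2)


def sa_squeeze(x: float, sigma: float = SAParams.squeeze_sigma) -> float:
    """Second-stage modifier: Gaussian toward 1 above 0.5, linear ramp below.

    Monotone and continuous with f(0)=0, f(1)=1, and f(x) >= 0.9 for
    x >= 0.5, so differences among already-accessible ligand sets are
    compressed while hopeless ones still score near zero.
    """
    if x < 0.0:
        return 0.0
    anchor = _gauss(0.5, 1.0, sigma)
    if x < 0.5:
        return x / 0.5 * anchor
    return min(_gauss(x, 1.0, sigma), 1.0)


def sa_score(
    anionic: LigandSpec,
    neutral: LigandSpec,
    n_neutral: int,
    params: SAParams | None = None,
) -> tuple[float, list[float]]:
    """Two-stage SA score in [0,1] plus the raw per-ligand values.

    Raw Ertl-Schuffenhauer scores (one per ligand copy: 3 anionic + n
    neutral) -> per-ligand Gaussian modifier -> mean -> squeeze.
    """
    params = params or SAParams()
    try:
        mol_an = neutralize_anionic(anionic)
    except ValidationError:
        return 0.0, []
    mol_ne = neutral.mol()
    raw_an = sascorer.calculateScore(mol_an)
    raw_ne = sascorer.calculateScore(mol_ne)
    raws = [raw_an] * 3 + [raw_ne] * n_neutral
    modified = [_gauss(r, params.stage1_mu, params.stage1_sigma) for r in raws]
    avg = float(np.mean(modified))
    return sa_squeeze(avg, params.squeeze_sigma), raws


# --------------------------------------------------------------------------- #
# Total score
# --------------------------------------------------------------------------- #


def total_score(catalyst: CatalystGraph, config: ScoringConfig | None = None) -> ScoreBreakdown:
    """Score = Ep_norm * Er_norm * SA; scoring failures yield total 0."""
    config = config or ScoringConfig()
    n_neutral = catalyst.template.n_neutral
    if config.include_sa:
        sa, raws = sa_score(catalyst.anionic, catalyst.neutral, n_neutral, config.sa)
    else:
        sa, raws = 1.0, []
    backend = get_backend(config.backend)
    s_n2, s_n2h_cat, s_n2h = _state("N2", 0), _state("N2H", 1), _state("N2H", 0)
    _assert_balanced(
        [catalyst.assemble(s_n2)], ["LutH+"], [catalyst.assemble(s_n2h_cat)], ["Lut"]
    )
    _assert_balanced(
        [catalyst.assemble(s_n2h_cat)], ["CrCp2"], [catalyst.assemble(s_n2h)], ["CrCp2+"]
    )
    counts: dict[str, int] = {}
    energies: dict[str, float] = {}
    try:
        for key, state in (("N2", s_n2), ("N2H+", s_n2h_cat), ("N2H", s_n2h)):
            energies[key], counts[key] = intermediate_energy(catalyst, state, config)
    except ScoringFailure as exc:
        return ScoreBreakdown(
            None, None, 0.0, 0.0, raws, sa, 0.0, counts, failure_reason=str(exc)
        )
    e_p = (energies["N2H+"] + backend.species_energy("Lut")) - (
        energies["N2"] + backend.species_energy("LutH+")
    )
    e_r = (energies["N2H"] + backend.species_energy("CrCp2+")) - (
        energies["N2H+"] + backend.species_energy("CrCp2")
    )
    p_norm = normalize_energy(e_p, config.normalization)
    r_norm = normalize_energy(e_r, config.normalization)
    return ScoreBreakdown(
        e_p, e_r, p_norm, r_norm, raws, sa, p_norm * r_norm * sa, counts
    )
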