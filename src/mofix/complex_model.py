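"""Ligands, coordination templates, assembled Mo complexes and cycle intermediates.

The chemical objects here are the vocabulary of the whole package: a
:class:`LigandSpec` is the gene the genetic algorithm evolves, a
:class:`CoordinationTemplate` fixes the metal geometry (trigonal bipyramidal
or octahedral), a :class:`CatalystGraph` is the 2D identity of a homoleptic
Mo complex (3 identical anionic ligands + 1 or 2 identical neutral ligands +
one N2 site), and :class:`IntermediateState` enumerates the 15 states of the
catalytic cycle that converts a bound N2 into two NH3 via six alternating
proton and electron transfers.

Complexes are represented as RDKit molecules in which every ligand donor atom
and the coordinating moiety nitrogen are attached to Mo by dative bonds, so
that organometallic valences sanitize cleanly.  Formal-charge bookkeeping puts
the ligand charges on the ligands (anionic = -1) and the balance on Mo, so the
total formal charge of every assembled state equals the state's total charge.
"""

from __future__ import annotations

import functools
import itertools
import json
from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit import RDLogger

# mutation/crossover retries legitimately produce invalid chemistry; keep the
# C++ logger quiet and surface failures through exceptions instead
RDLogger.DisableLog("rdApp.warning")
RDLogger.DisableLog("rdApp.error")

__all__ = [
    "LigandSpec",
    "CoordinationTemplate",
    "CatalystGraph",
    "IntermediateState",
    "Conformer",
    "SCHROCK_CYCLE",
    "MOIETY_FORMULA",
    "find_donor_candidates",
    "enumerate_stereoisomers",
    "assemble_complex",
    "assemble_with_site_ligands",
    "embed_conformers",
    "ValidationError",
    "EmbeddingError",
]


class ValidationError(ValueError):
    """Raised when a chemical object violates its invariants."""


class EmbeddingError(RuntimeError):
    """Raised when 3D embedding fails for every attempt; callers discard the catalyst."""


def _load_donor_patterns() -> dict[str, dict[str, Chem.Mol]]:
    raw = json.loads(
        resources.files("mofix.data").joinpath("donor_smarts.json").read_text()
    )
    out: dict[str, dict[str, Chem.Mol]] = {}
    for cls in ("neutral", "anionic"):
        out[cls] = {
            name: Chem.MolFromSmarts(smarts) for name, smarts in raw[cls].items()
        }
        if any(p is None for p in out[cls].values()):
            raise RuntimeError("invalid pinned donor SMARTS")
    return out


_DONOR_PATTERNS = _load_donor_patterns()


# --------------------------------------------------------------------------- #
# Ligands
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class LigandSpec:
    """A candidate monodentate ligand: SMILES, charge class and chosen donor atom.

    The SMILES is canonicalized on construction and ``donor_atom_index``
    always refers to the canonical atom order, which makes every downstream
    selection invariant to how the input SMILES was written.
    """

    smiles: str
    charge_class: str  # "anionic" | "neutral"
    donor_atom_index: int | None = None

    def __post_init__(self) -> None:
        if self.charge_class not in ("anionic", "neutral"):
            raise ValidationError(f"unknown charge class {self.charge_class!r}")
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise ValidationError(f"unparsable SMILES {self.smiles!r}")
        if len(Chem.GetMolFrags(mol)) != 1:
            raise ValidationError(f"ligand must be a single fragment: {self.smiles!r}")
        charge = Chem.GetFormalCharge(mol)
        if charge != self.formal_charge:
            raise ValidationError(
                f"{self.charge_class} ligand {self.smiles!r} has net charge {charge}"
            )
        canonical = Chem.MolToSmiles(mol)
        if canonical != self.smiles:
            # remap a donor index given on the original atom order
            if self.donor_atom_index is not None:
                order = list(
                    map(int, mol.GetPropsAsDict(True, True)["_smilesAtomOutputOrder"])
                )
                object.__setattr__(
                    self, "donor_atom_index", order.index(self.donor_atom_index)
                )
            object.__setattr__(self, "smiles", canonical)
        if self.donor_atom_index is not None:
            n = mol.GetNumAtoms()
            if not (0 <= self.donor_atom_index < n):
                raise ValidationError("donor_atom_index out of range")

    @property
    def formal_charge(self) -> int:
        return -1 if self.charge_class == "anionic" else 0

    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)

    def with_donor(self, index: int) -> "LigandSpec":
        return replace(self, donor_atom_index=index)

    @property
    def heavy_atoms(self) -> int:
        return self.mol().GetNumHeavyAtoms()


def find_donor_candidates(ligand: LigandSpec) -> list[int]:
    """All atoms matching the pinned donor patterns for the ligand's charge class.

    Matches are deduplicated by graph-symmetry equivalence class (canonical
    atom ranks without tie breaking); the smallest index of each class is
    kept.  Returns an empty list when no donor motif is present.
    """
    mol = ligand.mol()
    hits: set[int] = set()
    for pattern in _DONOR_PATTERNS[ligand.charge_class].values():
        for match in mol.GetSubstructMatches(pattern):
            hits.add(match[0])
    if not hits:
        return []
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=False))
    by_class: dict[int, int] = {}
    for idx in sorted(hits):
        by_class.setdefault(ranks[idx], idx)
    return sorted(by_class.values())


def symmetry_class(ligand: LigandSpec, index: int) -> int:
    """Graph-automorphism equivalence class of an atom (canonical rank)."""
    return list(Chem.CanonicalRankAtoms(ligand.mol(), breakTies=False))[index]


# --------------------------------------------------------------------------- #
# Coordination templates and stereoisomers
# --------------------------------------------------------------------------- #


def _proper_rotations(vectors: np.ndarray) -> list[tuple[int, ...]]:
    """Site permutations induced by proper rotations mapping the site set to itself.

    A permutation is admitted iff it preserves the Gram matrix of the site
    unit vectors and the implied orthogonal map has determinant +1.
    """
    n = len(vectors)
    gram = vectors @ vectors.T
    perms: list[tuple[int, ...]] = []
    for perm in itertools.permutations(range(n)):
        p = np.array(perm)
        if not np.allclose(gram, gram[np.ix_(p, p)], atol=1e-8):
            continue
        # solve R @ vectors.T = vectors[perm].T in the least-squares sense
        rot, *_ = np.linalg.lstsq(vectors, vectors[p], rcond=None)
        if not np.allclose(vectors @ rot, vectors[p], atol=1e-8):
            continue
        if np.linalg.det(rot) < 0:
            continue
        perms.append(perm)
    return perms


@functools.lru_cache(maxsize=None)
def _rotations_cached(site_vectors: tuple) -> tuple[tuple[int, ...], ...]:
    return tuple(_proper_rotations(np.array(site_vectors, dtype=float)))


@dataclass(frozen=True)
class CoordinationTemplate:
    """Ideal metal coordination geometry with labelled sites and rotation group."""

    geometry: str  # "TBP" | "OCT"
    n_neutral: int
    site_labels: tuple[str, ...]
    site_vectors: tuple[tuple[float, float, float], ...]
    n_anionic: int = 3

    def __post_init__(self) -> None:
        if len(self.site_labels) != len(self.site_vectors):
            raise ValidationError("site label/vector mismatch")
        if self.n_anionic + self.n_neutral + 1 != len(self.site_labels):
            raise ValidationError(
                "sites must hold exactly N2 + n_anionic + n_neutral ligands"
            )

    @property
    def n_sites(self) -> int:
        return len(self.site_labels)

    @property
    def vectors(self) -> np.ndarray:
        return np.array(self.site_vectors, dtype=float)

    @property
    def rotations(self) -> list[tuple[int, ...]]:
        return list(_rotations_cached(self.site_vectors))

    @staticmethod
    def octahedral() -> "CoordinationTemplate":
        return CoordinationTemplate(
            geometry="OCT",
            n_neutral=2,
            site_labels=("z+", "z-", "x+", "x-", "y+", "y-"),
            site_vectors=(
                (0.0, 0.0, 1.0),
                (0.0, 0.0, -1.0),
                (1.0, 0.0, 0.0),
                (-1.0, 0.0, 0.0),
                (0.0, 1.0, 0.0),
                (0.0, -1.0, 0.0),
            ),
        )

    @staticmethod
    def trigonal_bipyramidal() -> "CoordinationTemplate":
        c, s = -0.5, np.sqrt(3.0) / 2.0
        return CoordinationTemplate(
            geometry="TBP",
            n_neutral=1,
            site_labels=("ax+", "ax-", "eq1", "eq2", "eq3"),
            site_vectors=(
                (0.0, 0.0, 1.0),
                (0.0, 0.0, -1.0),
                (1.0, 0.0, 0.0),
                (c, s, 0.0),
                (c, -s, 0.0),
            ),
        )

    @staticmethod
    def from_name(name: str) -> "CoordinationTemplate":
        name = name.upper()
        if name == "OCT":
            return CoordinationTemplate.octahedral()
        if name == "TBP":
            return CoordinationTemplate.trigonal_bipyramidal()
        raise ValidationError(f"unknown template {name!r}")


@functools.lru_cache(maxsize=None)
def _enumerate_cached(
    site_vectors: tuple, n_anionic: int, n_neutral: int, distinguish: bool
) -> tuple[str, ...]:
    rotations = _rotations_cached(site_vectors)
    kinds = ["N2"] + ["A"] * n_anionic + ["A" if not distinguish else "L"] * n_neutral
    seen: set[str] = set()
    for assignment in set(itertools.permutations(kinds)):
        orbit = (
            ",".join(assignment[perm[i]] for i in range(len(assignment)))
            for perm in rotations
        )
        seen.add(min(orbit))
    return tuple(sorted(seen))


def enumerate_stereoisomers(
    template: CoordinationTemplate, distinguish_ligand_types: bool = True
) -> list[str]:
    """Canonical labels of all distinct ligand placements on the template.

    Places {N2 x1, anionic x3, neutral x n_neutral} on the sites and dedupes
    under the template's proper rotation group.  The label of an isomer is the
    lexicographically smallest site-assignment string among its rotational
    images, so labels are stable across runs.  With
    ``distinguish_ligand_types=False`` the anionic/neutral distinction is
    erased (both painted "A"), which is the correct count when both ligands
    are the same chemical species.
    """
    if template.n_anionic + template.n_neutral + 1 != template.n_sites:
        raise ValidationError("ligand count does not match template sites")
    return list(
        _enumerate_cached(
            template.site_vectors,
            template.n_anionic,
            template.n_neutral,
            distinguish_ligand_types,
        )
    )


def site_assignment_from_label(
    template: CoordinationTemplate, stereo_label: str
) -> dict[str, str]:
    kinds = stereo_label.split(",")
    if len(kinds) != template.n_sites:
        raise ValidationError("stereo label does not match template")
    return dict(zip(template.site_labels, kinds))


# --------------------------------------------------------------------------- #
# Schrock-cycle intermediates
# --------------------------------------------------------------------------- #

#: moiety -> (N count, H count)
MOIETY_FORMULA: dict[str, tuple[int, int]] = {
    "N2": (2, 0),
    "N2H": (2, 1),
    "N2H2": (2, 2),
    "N2H3": (2, 3),
    "N": (1, 0),
    "NH": (1, 1),
    "NH2": (1, 2),
    "NH3": (1, 3),
    "bare": (0, 0),
}

# moiety graph: (element, explicit H) per atom + internal bonds; atom 0 coordinates to Mo
_MOIETY_GRAPH: dict[str, tuple[list[tuple[str, int]], list[tuple[int, int, Chem.BondType]]]] = {
    "N2": ([("N", 0), ("N", 0)], [(0, 1, Chem.BondType.TRIPLE)]),
    "N2H": ([("N", 0), ("N", 1)], [(0, 1, Chem.BondType.DOUBLE)]),
    "N2H2": ([("N", 0), ("N", 2)], [(0, 1, Chem.BondType.SINGLE)]),
    # hydrazidium-like: the NH3 end binds the proximal N datively so neutral
    # valence bookkeeping stays legal
    "N2H3": ([("N", 0), ("N", 3)], [(1, 0, Chem.BondType.DATIVE)]),
    "N": ([("N", 0)], []),
    "NH": ([("N", 1)], []),
    "NH2": ([("N", 2)], []),
    "NH3": ([("N", 3)], []),
    "bare": ([], []),
}


@dataclass(frozen=True)
class IntermediateState:
    """One of the 15 catalytic-cycle states of the Mo complex."""

    index: int
    moiety: str
    total_charge: int
    entry_step: str  # start | proton | electron | NH3_release | N2_binding
    multiplicity: int

    def __post_init__(self) -> None:
        if self.moiety not in MOIETY_FORMULA:
            raise ValidationError(f"unknown moiety {self.moiety!r}")
        if self.total_charge not in (0, 1):
            raise ValidationError("cycle states are neutral or +1")

    @property
    def state_key(self) -> str:
        return f"{self.moiety}|{self.total_charge}"


def _build_cycle() -> tuple[IntermediateState, ...]:
    # (moiety, charge, entry step); multiplicity bookkeeping: doublet while the
    # cumulative number of transferred electrons is even (Mo(III)-like d count),
    # singlet otherwise.  These are overridable defaults, not physics claims.
    rows = [
        ("N2", 0, "start"),
        ("N2H", 1, "proton"),
        ("N2H", 0, "electron"),
        ("N2H2", 1, "proton"),
        ("N2H2", 0, "electron"),
        ("N2H3", 1, "proton"),
        ("N2H3", 0, "electron"),
        ("N", 0, "NH3_release"),
        ("NH", 1, "proton"),
        ("NH", 0, "electron"),
        ("NH2", 1, "proton"),
        ("NH2", 0, "electron"),
        ("NH3", 1, "proton"),
        ("NH3", 0, "electron"),
        ("bare", 0, "NH3_release"),
    ]
    states = []
    electrons = 0
    for i, (moiety, charge, step) in enumerate(rows, start=1):
        if step == "electron":
            electrons += 1
        mult = 2 if electrons % 2 == 0 else 1
        states.append(IntermediateState(i, moiety, charge, step, mult))
    return tuple(states)


SCHROCK_CYCLE: tuple[IntermediateState, ...] = _build_cycle()

#: transition closing the cycle (state 15 -> state 1 by N2 binding)
CLOSING_STEP = "N2_binding"


# --------------------------------------------------------------------------- #
# Complex assembly
# --------------------------------------------------------------------------- #


def _site_vec_prop(rw: Chem.RWMol, idx: int, template: CoordinationTemplate, site: str) -> None:
    vec = template.vectors[template.site_labels.index(site)]
    rw.GetAtomWithIdx(idx).SetProp("mofixSiteVec", ",".join(f"{x:.6f}" for x in vec))


def _append_ligand(
    rw: Chem.RWMol, ligand: LigandSpec, mo_idx: int, site: str
) -> None:
    if ligand.donor_atom_index is None:
        raise ValidationError(f"ligand {ligand.smiles!r} has no donor atom assigned")
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
        rw.GetAtomWithIdx(idx).SetProp("mofixSite", site)
        rw.GetAtomWithIdx(idx).SetProp("mofixLigandKind", ligand.charge_class)
    for bond in lig.GetBonds():
        rw.AddBond(
            bond.GetBeginAtomIdx() + offset,
            bond.GetEndAtomIdx() + offset,
            bond.GetBondType(),
        )
        rw.GetBondBetweenAtoms(
            bond.GetBeginAtomIdx() + offset, bond.GetEndAtomIdx() + offset
        ).SetIsAromatic(bond.GetIsAromatic())
    rw.AddBond(ligand.donor_atom_index + offset, mo_idx, Chem.BondType.DATIVE)


def assemble_with_site_ligands(
    site_ligands: Mapping[str, LigandSpec],
    template: CoordinationTemplate,
    state: IntermediateState,
    n2_site: str,
) -> Chem.Mol:
    """Assemble a (possibly heteroleptic) complex from an explicit site -> ligand map.

    ``site_ligands`` covers every template site except ``n2_site``, which
    carries the NxHy moiety of ``state`` (vacant for the bare state).  The Mo
    formal charge is set so the total equals ``state.total_charge``.
    """
    if set(site_ligands) | {n2_site} != set(template.site_labels):
        raise ValidationError("site map must cover every template site exactly once")
    rw = Chem.RWMol()
    mo = Chem.Atom(42)
    mo.SetNoImplicit(True)
    ligand_charge = sum(l.formal_charge for l in site_ligands.values())
    mo.SetFormalCharge(state.total_charge - ligand_charge)
    mo_idx = rw.AddAtom(mo)
    rw.GetAtomWithIdx(mo_idx).SetProp("mofixRole", "metal")
    # moiety first so its atom indices are stable across states
    atoms, bonds = _MOIETY_GRAPH[state.moiety]
    moiety_idx = []
    for elem, n_h in atoms:
        a = Chem.Atom(elem)
        a.SetNumExplicitHs(n_h)
        a.SetNoImplicit(True)
        idx = rw.AddAtom(a)
        rw.GetAtomWithIdx(idx).SetProp("mofixRole", "moiety")
        rw.GetAtomWithIdx(idx).SetProp("mofixSite", n2_site)
        moiety_idx.append(idx)
    for i, j, bt in bonds:
        rw.AddBond(moiety_idx[i], moiety_idx[j], bt)
    if moiety_idx:
        rw.AddBond(moiety_idx[0], mo_idx, Chem.BondType.DATIVE)
        _site_vec_prop(rw, moiety_idx[0], template, n2_site)
    for site in template.site_labels:
        if site == n2_site:
            continue
        ligand = site_ligands[site]
        offset = rw.GetNumAtoms()
        _append_ligand(rw, ligand, mo_idx, site)
        _site_vec_prop(rw, offset + ligand.donor_atom_index, template, site)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    if Chem.GetFormalCharge(mol) != state.total_charge:
        raise ValidationError("charge bookkeeping failed")
    mol.SetIntProp("mofixStateIndex", state.index)
    mol.SetProp("mofixStateKey", state.state_key)
    mol.SetIntProp("mofixMultiplicity", state.multiplicity)
    return mol


def assemble_complex(
    anionic: LigandSpec,
    neutral: LigandSpec,
    template: CoordinationTemplate,
    stereo_label: str,
    state: IntermediateState,
) -> Chem.Mol:
    """Assemble the homoleptic complex for one cycle state as a single RDKit graph."""
    assignment = site_assignment_from_label(template, stereo_label)
    n2_site = next(s for s, k in assignment.items() if k == "N2")
    site_ligands = {
        site: (anionic if kind == "A" else neutral)
        for site, kind in assignment.items()
        if kind != "N2"
    }
    mol = assemble_with_site_ligands(site_ligands, template, state, n2_site)
    mol.SetProp("mofixStereoLabel", stereo_label)
    return mol


@dataclass(frozen=True)
class CatalystGraph:
    """2D identity of a homoleptic Mo catalyst: ligand pair + template + stereochemistry."""

    anionic: LigandSpec
    neutral: LigandSpec
    template: CoordinationTemplate
    stereo_label: str
    metal: str = "Mo"

    def __post_init__(self) -> None:
        if self.anionic.charge_class != "anionic" or self.neutral.charge_class != "neutral":
            raise ValidationError("ligand charge classes are swapped")

    @property
    def site_assignment(self) -> dict[str, str]:
        return site_assignment_from_label(self.template, self.stereo_label)

    def assemble(self, state: IntermediateState) -> Chem.Mol:
        return assemble_complex(
            self.anionic, self.neutral, self.template, self.stereo_label, state
        )

    def canonical_key(self) -> str:
        mol = self.assemble(SCHROCK_CYCLE[0])
        return f"{Chem.MolToSmiles(mol)}|{self.stereo_label}"

    @property
    def heavy_atoms(self) -> int:
        return self.assemble(SCHROCK_CYCLE[0]).GetNumHeavyAtoms()


# --------------------------------------------------------------------------- #
# Conformers
# --------------------------------------------------------------------------- #


@dataclass
class Conformer:
    """One 3D realization of an assembled complex (explicit hydrogens)."""

    mol: Chem.Mol  # carries exactly one conformer
    total_charge: int
    multiplicity: int
    energy: float | None = None

    @property
    def symbols(self) -> list[str]:
        return [a.GetSymbol() for a in self.mol.GetAtoms()]

    @property
    def coords(self) -> np.ndarray:
        return np.array(self.mol.GetConformer().GetPositions(), dtype=float)

    def with_coords(self, coords: np.ndarray, energy: float | None = None) -> "Conformer":
        mol = Chem.Mol(self.mol)
        conf = mol.GetConformer()
        for i, xyz in enumerate(np.asarray(coords, dtype=float)):
            conf.SetAtomPosition(i, [float(x) for x in xyz])
        return Conformer(mol, self.total_charge, self.multiplicity, energy)

    @property
    def n_atoms(self) -> int:
        return self.mol.GetNumAtoms()


def _single_conf_copy(mol: Chem.Mol, conf_id: int) -> Chem.Mol:
    out = Chem.Mol(mol)
    out.RemoveAllConformers()
    out.AddConformer(mol.GetConformer(conf_id), assignId=True)
    return out


def _kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Least-squares superposition RMSD (fixed atom correspondence)."""
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = pc.T @ qc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = pc @ rot.T - qc
    return float(np.sqrt((diff**2).sum() / len(p)))


def heavy_atom_rmsd(a: Conformer, b: Conformer) -> float:
    """Superposition RMSD over heavy atoms (identity atom correspondence)."""
    heavy = [i for i, s in enumerate(a.symbols) if s != "H"]
    return _kabsch_rmsd(a.coords[heavy], b.coords[heavy])


def _rotation_onto(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-10:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, perp)
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


_MO_DONOR_LEN = 2.1  # initial Mo-donor distance, Angstrom; relaxed downstream


def _plain_etkdg(molh: Chem.Mol, n_confs: int, rmsd_prune: float, seed: int) -> list[int]:
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    params.pruneRmsThresh = float(rmsd_prune)
    params.useRandomCoords = True
    params.maxIterations = 500
    return list(AllChem.EmbedMultipleConfs(molh, numConfs=int(n_confs), params=params))


def _group_atoms(molh: Chem.Mol) -> tuple[int, dict[str, list[int]], dict[str, str]]:
    """Mo index, heavy+H atom indices per site group, and each group's role."""
    mo_idx = None
    groups: dict[str, list[int]] = {}
    roles: dict[str, str] = {}
    for atom in molh.GetAtoms():
        role = atom.GetProp("mofixRole") if atom.HasProp("mofixRole") else None
        if role == "metal":
            mo_idx = atom.GetIdx()
        elif role in ("ligand", "moiety"):
            site = atom.GetProp("mofixSite")
            groups.setdefault(site, []).append(atom.GetIdx())
            roles[site] = role
    # attach explicit hydrogens to their heavy atom's group
    for atom in molh.GetAtoms():
        if atom.GetAtomicNum() != 1 or atom.HasProp("mofixRole"):
            continue
        nb = atom.GetNeighbors()[0]
        if nb.HasProp("mofixSite"):
            groups[nb.GetProp("mofixSite")].append(atom.GetIdx())
    if mo_idx is None:
        raise ValidationError("no metal atom in complex")
    return mo_idx, groups, roles


def _embed_complex(
    molh: Chem.Mol, n_confs: int, rmsd_prune: float, seed: int
) -> list[np.ndarray]:
    """Template-based conformer generator for assembled complexes.

    Each ligand copy is ETKDG-embedded on its own (deterministic per-site
    seeds), oriented so the donor lone-pair direction points at Mo, and
    translated onto its ideal template site; moiety atoms are laid out along
    their site axis.  Conformer diversity comes from per-ligand embedding
    seeds plus deterministic spins about the site axes; the resulting pool is
    greedily pruned at ``rmsd_prune`` heavy-atom RMSD.
    """
    mo_idx, groups, roles = _group_atoms(molh)
    n_atoms = molh.GetNumAtoms()
    golden = np.pi * (3.0 - np.sqrt(5.0))
    out: list[np.ndarray] = []
    for k in range(int(n_confs)):
        coords = np.zeros((n_atoms, 3))
        failed = False
        for s_i, (site, idxs) in enumerate(sorted(groups.items())):
            vec = np.array(
                [float(v) for v in _site_vec_of_group(molh, idxs).split(",")]
            )
            donor_local = _donor_in_group(molh, idxs, mo_idx)
            sub_coords = _embed_group(molh, idxs, seed * 1009 + k * 131 + s_i)
            if sub_coords is None:
                failed = True
                break
            # orient: donor lone-pair direction -> -site vector (toward Mo)
            donor_pos = sub_coords[idxs.index(donor_local)]
            nb_pos = [
                sub_coords[idxs.index(nb.GetIdx())]
                for nb in molh.GetAtomWithIdx(donor_local).GetNeighbors()
                if nb.GetIdx() in idxs
            ]
            if nb_pos:
                lp = donor_pos - np.mean(nb_pos, axis=0)
                norm = np.linalg.norm(lp)
                lp = lp / norm if norm > 1e-8 else np.array([0.0, 0.0, 1.0])
            else:
                lp = np.array([0.0, 0.0, 1.0])
            rot = _rotation_onto(lp, -vec)
            spin = _axis_rotation(vec, golden * (k + s_i))
            placed = (sub_coords - donor_pos) @ rot.T @ spin.T
            placed += vec * _MO_DONOR_LEN
            for local, global_idx in enumerate(idxs):
                coords[global_idx] = placed[local]
        if not failed:
            out.append(coords)
    pruned: list[np.ndarray] = []
    heavy = [i for i in range(n_atoms) if molh.GetAtomWithIdx(i).GetAtomicNum() != 1]
    for c in out:
        if all(_kabsch_rmsd(c[heavy], p[heavy]) >= rmsd_prune for p in pruned):
            pruned.append(c)
    return pruned


def _site_vec_of_group(molh: Chem.Mol, idxs: list[int]) -> str:
    for i in idxs:
        if molh.GetAtomWithIdx(i).HasProp("mofixSiteVec"):
            return molh.GetAtomWithIdx(i).GetProp("mofixSiteVec")
    raise ValidationError("group has no site vector")


def _donor_in_group(molh: Chem.Mol, idxs: list[int], mo_idx: int) -> int:
    for i in idxs:
        atom = molh.GetAtomWithIdx(i)
        for nb in atom.GetNeighbors():
            if nb.GetIdx() == mo_idx:
                return i
    raise ValidationError("group is not bonded to the metal")


def _embed_group(molh: Chem.Mol, idxs: list[int], seed: int) -> np.ndarray | None:
    """ETKDG-embed one ligand/moiety group as a standalone fragment."""
    if len(idxs) == 1:
        return np.zeros((1, 3))
    rw = Chem.RWMol()
    mapping: dict[int, int] = {}
    for i in idxs:
        atom = molh.GetAtomWithIdx(i)
        a = Chem.Atom(atom.GetAtomicNum())
        a.SetFormalCharge(atom.GetFormalCharge())
        a.SetNoImplicit(True)
        a.SetIsAromatic(atom.GetIsAromatic())
        mapping[i] = rw.AddAtom(a)
    seen_bonds: set[int] = set()
    for i in idxs:
        for bond in molh.GetAtomWithIdx(i).GetBonds():
            j, l = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            if j in mapping and l in mapping and bond.GetIdx() not in seen_bonds:
                seen_bonds.add(bond.GetIdx())
                rw.AddBond(mapping[j], mapping[l], bond.GetBondType())
    frag = rw.GetMol()
    try:
        Chem.SanitizeMol(
            frag,
            Chem.SanitizeFlags.SANITIZE_ALL
            ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES,
        )
    except Exception:  # noqa: BLE001 - fall back to minimal sanitization
        frag.UpdatePropertyCache(strict=False)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    params.useRandomCoords = True
    params.maxIterations = 500
    cid = AllChem.EmbedMolecule(frag, params)
    if cid < 0:
        return None
    order = [mapping[i] for i in idxs]
    pos = np.array(frag.GetConformer(cid).GetPositions())
    return pos[order]


def embed_conformers(
    mol: Chem.Mol,
    n_confs: int,
    rmsd_prune: float = 1.0,
    seed: int = 0,
) -> list[Conformer]:
    """Generate up to ``n_confs`` 3D conformers, pruned at ``rmsd_prune`` (heavy-atom RMSD).

    Assembled complexes (molecules carrying a metal role tag) use the
    template-based generator with per-ligand ETKDG embedding; plain molecules
    use whole-molecule ETKDG.  Deterministic for a fixed seed.  Raises
    :class:`EmbeddingError` when every attempt fails; callers treat that as a
    discarded catalyst.
    """
    if n_confs < 1:
        raise ValidationError("n_confs must be >= 1")
    molh = Chem.AddHs(mol)
    charge = Chem.GetFormalCharge(molh)
    mult = molh.GetIntProp("mofixMultiplicity") if molh.HasProp("mofixMultiplicity") else 1
    is_complex = any(
        a.HasProp("mofixRole") and a.GetProp("mofixRole") == "metal"
        for a in molh.GetAtoms()
    )
    if is_complex:
        coord_sets = _embed_complex(molh, n_confs, rmsd_prune, seed)
        if not coord_sets:
            raise EmbeddingError("conformer embedding failed for all attempts")
        confs = []
        for coords in coord_sets:
            m = Chem.Mol(molh)
            conf = Chem.Conformer(m.GetNumAtoms())
            for i, xyz in enumerate(coords):
                conf.SetAtomPosition(i, [float(x) for x in xyz])
            m.RemoveAllConformers()
            m.AddConformer(conf, assignId=True)
            confs.append(Conformer(m, charge, mult))
        return confs
    cids = _plain_etkdg(molh, n_confs, rmsd_prune, seed)
    if not cids:
        raise EmbeddingError("conformer embedding failed for all attempts")
    return [Conformer(_single_conf_copy(molh, cid), charge, mult) for cid in cids]
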