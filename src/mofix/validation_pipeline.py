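"""Post-GA validation funnel and full catalytic-cycle profiles.

After a GA run the surviving catalysts pass through:

1. ``conformer_rescore`` — the scoring protocol redone with a much larger
   conformer pool (default 500, RMSD pruning 1 Å), the stereoisomer selection
   repeated (donor atoms kept fixed), and the SA factor omitted.
2. ``diversity_filter`` — Morgan-fingerprint (radius 3) Tanimoto pruning of
   near-duplicates above 0.6 similarity; one member of each offending pair is
   discarded at random (seed-deterministic).
3. ``energy_cutoff_filter`` — both reaction energies must be <= 10 kcal/mol
   (equivalently both normalized scores >= 0.45).
4. ``full_cycle_profile`` — the 15-state catalytic cycle computed
   sequentially, each state starting from the previous state's geometry with
   the NxHy moiety swapped and pre-relaxed in a frozen frame; failures fall
   back to the Mo-N2 reference geometry and a second failure discards the
   catalyst.
5. ``substitution_analysis`` — ligand-by-ligand replacement with NH2-/NH3 to
   attribute the first-protonation energy to individual ligands.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .complex_model import (
    CLOSING_STEP,
    CatalystGraph,
    IntermediateState,
    LigandSpec,
    SCHROCK_CYCLE,
    EmbeddingError,
    ValidationError,
    embed_conformers,
)
from .energy_backend import get_backend
from .scoring import (
    ScoreBreakdown,
    ScoringConfig,
    ScoringFailure,
    intermediate_energy,
)

__all__ = [
    "ReactionProfile",
    "CatalystDiscarded",
    "conformer_rescore",
    "diversity_filter",
    "energy_cutoff_filter",
    "full_cycle_profile",
    "substitution_analysis",
    "free_species_energy",
]


class CatalystDiscarded(RuntimeError):
    """The funnel removed this catalyst (failed conformer search or cycle step)."""


# --------------------------------------------------------------------------- #
# Reaction profiles
# --------------------------------------------------------------------------- #


@dataclass
class ReactionProfile:
    """Ordered energies of the 15-state cycle, relative to the resting state.

    ``step_energies[k]`` is the reaction energy of the transition out of
    state k+1 (including donor/byproduct terms); the last entry closes the
    cycle by N2 binding.  ``energies[k]`` is the cumulative energy of state
    k+1 relative to state 1 plus the donor pool, so the two telescope.
    """

    catalyst_id: str
    states: list[IntermediateState]
    energies: list[float]
    step_energies: list[float]
    step_types: list[str]
    level: str = "surrogate"

    def __post_init__(self) -> None:
        if len(self.states) != 15 or len(self.energies) != 15:
            raise ValidationError("a full cycle has 15 states")
        if len(self.step_energies) != 15 or len(self.step_types) != 15:
            raise ValidationError("a full cycle has 15 transitions (incl. closure)")
        expected_types = [s.entry_step for s in SCHROCK_CYCLE[1:]] + [CLOSING_STEP]
        if self.step_types != expected_types:
            raise ValidationError("step types deviate from the pinned cycle pattern")
        cum = np.concatenate([[0.0], np.cumsum(self.step_energies[:-1])])
        if not np.allclose(cum, self.energies, atol=1e-6):
            raise ValidationError("step energies do not telescope to state energies")

    @property
    def descriptor(self) -> float:
        """First-protonation step energy relative to the resting state."""
        return self.step_energies[0]

    @property
    def overall_reaction_energy(self) -> float:
        """Sum of all step energies: N2 + 6 LutH+ + 6 CrCp*2 -> 2 NH3 + 6 Lut + 6 CrCp*2+."""
        return float(np.sum(self.step_energies))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": [s.index for s in self.states],
                "moiety": [s.moiety for s in self.states],
                "charge": [s.total_charge for s in self.states],
                "energy": self.energies,
                "step_type": self.step_types,
                "step_energy": self.step_energies,
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "catalyst_id": self.catalyst_id,
                "level": self.level,
                "energies": self.energies,
                "step_energies": self.step_energies,
                "step_types": self.step_types,
            }
        )

    @staticmethod
    def from_json(text: str) -> "ReactionProfile":
        data = json.loads(text)
        return ReactionProfile(
            catalyst_id=data["catalyst_id"],
            states=list(SCHROCK_CYCLE),
            energies=list(data["energies"]),
            step_energies=list(data["step_energies"]),
            step_types=list(data["step_types"]),
            level=data.get("level", "unknown"),
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


# --------------------------------------------------------------------------- #
# Funnel filters
# --------------------------------------------------------------------------- #


def conformer_rescore(
    catalyst: CatalystGraph, config: ScoringConfig | None = None, n_confs: int = 500
) -> tuple[CatalystGraph, ScoreBreakdown]:
    """Re-score with a deep conformer pool; stereoisomer re-selected, SA omitted.

    The donor atoms are kept; only the stereo label may change.  Raises
    :class:`CatalystDiscarded` when any scoring intermediate loses all of its
    conformers.
    """
    from .complex_model import enumerate_stereoisomers

    base = config or ScoringConfig()
    deep = replace(
        base, n_confs=n_confs, rmsd_prune=1.0, include_sa=False
    )
    labels = enumerate_stereoisomers(catalyst.template)
    best_label, best_e = None, None
    for label in labels:
        variant = replace(catalyst, stereo_label=label)
        try:
            e, _ = intermediate_energy(variant, SCHROCK_CYCLE[0], deep)
        except (ScoringFailure, EmbeddingError):
            continue
        if best_e is None or e < best_e - 1e-12:
            best_label, best_e = label, e
    if best_label is None:
        raise CatalystDiscarded("conformer search failed for every stereoisomer")
    chosen = replace(catalyst, stereo_label=best_label)
    from .scoring import total_score

    breakdown = total_score(chosen, deep)
    if breakdown.failure_reason is not None:
        raise CatalystDiscarded(breakdown.failure_reason)
    return chosen, breakdown


def _complex_fingerprint(catalyst: CatalystGraph, radius: int):
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=2048)
    return gen.GetFingerprint(catalyst.assemble(SCHROCK_CYCLE[0]))


def diversity_filter(
    catalysts: Sequence[CatalystGraph],
    threshold: float = 0.6,
    radius: int = 3,
    seed: int = 0,
) -> list[CatalystGraph]:
    """Discard one random member of every pair above the Tanimoto threshold.

    Pairs are visited in canonical-id order, so for a fixed seed the output
    does not depend on the input ordering.  No surviving pair has similarity
    above the threshold.
    """
    order = sorted(range(len(catalysts)), key=lambda i: catalysts[i].canonical_key())
    fps = {i: _complex_fingerprint(catalysts[i], radius) for i in order}
    rng = np.random.default_rng(seed)
    alive = set(order)
    for pos_a, i in enumerate(order):
        if i not in alive:
            continue
        for j in order[pos_a + 1 :]:
            if i not in alive:
                break
            if j not in alive:
                continue
            sim = DataStructs.TanimotoSimilarity(fps[i], fps[j])
            if sim > threshold:
                drop = i if rng.random() < 0.5 else j
                alive.discard(drop)
    return [catalysts[i] for i in sorted(alive)]


def energy_cutoff_filter(
    scored: Sequence[tuple[CatalystGraph, ScoreBreakdown]],
    cutoff: float = 10.0,
) -> list[tuple[CatalystGraph, ScoreBreakdown]]:
    """Keep catalysts with both Ep and Er at most ``cutoff`` kcal/mol.

    With the default normalization a 10 kcal/mol cutoff is exactly a 0.45
    normalized-score threshold on each reaction.
    """
    out = []
    for cat, breakdown in scored:
        if breakdown.E_p is None or breakdown.E_r is None:
            continue
        if breakdown.E_p <= cutoff and breakdown.E_r <= cutoff:
            out.append((cat, breakdown))
    return out


# --------------------------------------------------------------------------- #
# Full cycle profiles
# --------------------------------------------------------------------------- #


def free_species_energy(moiety: str, config: ScoringConfig) -> float:
    """Energy of a free NH3 or N2 molecule at the configured backend level."""
    smiles = {"NH3": "N", "N2": "N#N"}[moiety]
    mol = Chem.MolFromSmiles(smiles)
    backend = get_backend(config.backend)
    if not config.use_3d and hasattr(backend, "analytic_energy"):
        return backend.analytic_energy(mol)
    confs = embed_conformers(mol, 1, seed=config.seed)
    result = backend.optimize(confs[0])
    if not result.converged:
        raise ScoringFailure(f"free {moiety} optimization failed")
    return result.energy


def _step_energy(
    step_type: str,
    e_from: float,
    e_to: float,
    backend,
    config: ScoringConfig,
) -> float:
    if step_type == "proton":
        return (e_to + backend.species_energy("Lut")) - (
            e_from + backend.species_energy("LutH+")
        )
    if step_type == "electron":
        return (e_to + backend.species_energy("CrCp2+")) - (
            e_from + backend.species_energy("CrCp2")
        )
    if step_type == "NH3_release":
        return (e_to + free_species_energy("NH3", config)) - e_from
    if step_type == CLOSING_STEP:
        return e_to - (e_from + free_species_energy("N2", config))
    raise ValidationError(f"unknown step type {step_type!r}")


def _sequential_geometries(
    catalyst: CatalystGraph, config: ScoringConfig
) -> list[float]:
    """3D path: optimize the 15 states sequentially with moiety swapping.

    The optimized geometry of state k seeds state k+1: ligand-frame atoms
    keep their coordinates, the new moiety is laid on the N2-site axis and
    pre-relaxed with everything else frozen, then the whole complex is
    relaxed.  A failed state restarts from the Mo-N2 reference; a second
    failure discards the catalyst.
    """
    backend = get_backend(config.backend)

    def _optimize_state(
        state: IntermediateState, frame_block: np.ndarray | None
    ) -> tuple[float, np.ndarray]:
        """Returns (energy, ligand-frame coordinate block of the relaxed state).

        The frame block (Mo + ligands + their H's, in a state-independent
        order) is transplanted from the previous state; the freshly embedded
        moiety is pre-relaxed against the frozen frame first.
        """
        mol = catalyst.assemble(state)
        confs = embed_conformers(mol, config.n_confs, config.rmsd_prune, config.seed)
        conf = confs[0]
        frame_idx = _ligand_frame_indices(conf.mol)
        if frame_block is not None:
            coords = conf.coords
            coords[frame_idx] = frame_block
            conf = conf.with_coords(coords)
            pre = backend.optimize(conf, frozen=frame_idx)
            conf = pre.geometry
        result = backend.optimize(conf)
        if not result.converged:
            raise ScoringFailure(f"optimization failed for state {state.index}")
        return result.energy, result.geometry.coords[frame_idx]

    energies: list[float] = []
    e0, ref_frame = _optimize_state(SCHROCK_CYCLE[0], None)
    energies.append(e0)
    prev_frame = ref_frame
    for state in SCHROCK_CYCLE[1:]:
        try:
            e, prev_frame = _optimize_state(state, prev_frame)
        except (ScoringFailure, EmbeddingError):
            try:
                e, prev_frame = _optimize_state(state, ref_frame)
            except (ScoringFailure, EmbeddingError) as exc:
                raise CatalystDiscarded(
                    f"cycle optimization failed at state {state.index}"
                ) from exc
        energies.append(e)
    return energies


def _ligand_frame_indices(molh: Chem.Mol) -> list[int]:
    """Indices of Mo + ligand atoms (+ their H's) in a canonical, state-independent order."""
    idx = []
    for atom in molh.GetAtoms():
        role = atom.GetProp("mofixRole") if atom.HasProp("mofixRole") else None
        if role == "metal":
            idx.append(atom.GetIdx())
        elif role == "ligand":
            idx.append(atom.GetIdx())
            for nb in atom.GetNeighbors():
                if nb.GetAtomicNum() == 1 and not nb.HasProp("mofixRole"):
                    idx.append(nb.GetIdx())
    return idx


def full_cycle_profile(
    catalyst: CatalystGraph, config: ScoringConfig | None = None
) -> ReactionProfile:
    """Compute the full 15-state reaction profile for one catalyst."""
    config = config or ScoringConfig()
    backend = get_backend(config.backend)
    if not config.use_3d and hasattr(backend, "analytic_energy"):
        abs_energies = [
            backend.analytic_energy(catalyst.assemble(state)) for state in SCHROCK_CYCLE
        ]
    else:
        abs_energies = _sequential_geometries(catalyst, config)
    step_types = [s.entry_step for s in SCHROCK_CYCLE[1:]] + [CLOSING_STEP]
    step_energies = []
    for k, step_type in enumerate(step_types):
        e_from = abs_energies[k]
        e_to = abs_energies[k + 1] if k + 1 < 15 else abs_energies[0]
        step_energies.append(_step_energy(step_type, e_from, e_to, backend, config))
    rel = [0.0]
    for de in step_energies[:-1]:
        rel.append(rel[-1] + de)
    return ReactionProfile(
        catalyst_id=catalyst.canonical_key(),
        states=list(SCHROCK_CYCLE),
        energies=rel,
        step_energies=step_energies,
        step_types=step_types,
        level=backend.backend_id if hasattr(backend, "backend_id") else "unknown",
    )


# --------------------------------------------------------------------------- #
# Ligand substitution analysis
# --------------------------------------------------------------------------- #

_SUB_ANIONIC = LigandSpec("[NH2-]", "anionic", 0)
_SUB_NEUTRAL = LigandSpec("N", "neutral", 0)


def _protonation_energy_for_sites(
    catalyst: CatalystGraph,
    substituted: frozenset[str],
    config: ScoringConfig,
) -> float:
    """Ep of the complex with the given sites replaced by NH2-/NH3 (single points)."""
    from .complex_model import assemble_with_site_ligands

    backend = get_backend(config.backend)
    assignment = catalyst.site_assignment
    n2_site = next(s for s, k in assignment.items() if k == "N2")
    site_ligands = {}
    for site, kind in assignment.items():
        if kind == "N2":
            continue
        if site in substituted:
            site_ligands[site] = _SUB_ANIONIC if kind == "A" else _SUB_NEUTRAL
        else:
            site_ligands[site] = catalyst.anionic if kind == "A" else catalyst.neutral
    s_n2 = SCHROCK_CYCLE[0]
    s_n2h = SCHROCK_CYCLE[1]
    e_n2 = backend.analytic_energy(
        assemble_with_site_ligands(site_ligands, catalyst.template, s_n2, n2_site)
    )
    e_n2h = backend.analytic_energy(
        assemble_with_site_ligands(site_ligands, catalyst.template, s_n2h, n2_site)
    )
    return (e_n2h + backend.species_energy("Lut")) - (
        e_n2 + backend.species_energy("LutH+")
    )


def substitution_analysis(
    catalyst: CatalystGraph, config: ScoringConfig | None = None
) -> pd.DataFrame:
    """Two-stage NH2-/NH3 ligand substitution scan of the protonation energy.

    Stage ``individual``: each ligand site replaced on its own.  Stage
    ``cumulative``: sites replaced one after the other in descending order of
    their individual energy increase (ties broken by site label).  The
    reported ``delta`` is always relative to the unsubstituted catalyst.
    """
    config = config or ScoringConfig()
    e_ref = _protonation_energy_for_sites(catalyst, frozenset(), config)
    sites = [s for s, k in catalyst.site_assignment.items() if k != "N2"]
    rows = []
    individual: dict[str, float] = {}
    for site in sorted(sites):
        e_sub = _protonation_energy_for_sites(catalyst, frozenset({site}), config)
        individual[site] = e_sub - e_ref
        rows.append(
            {
                "stage": "individual",
                "sites": site,
                "ligand_kind": catalyst.site_assignment[site],
                "E_p": e_sub,
                "delta": e_sub - e_ref,
            }
        )
    order = sorted(sites, key=lambda s: (-individual[s], s))
    done: set[str] = set()
    for site in order:
        done.add(site)
        e_sub = _protonation_energy_for_sites(catalyst, frozenset(done), config)
        rows.append(
            {
                "stage": "cumulative",
                "sites": ",".join(sorted(done)),
                "ligand_kind": catalyst.site_assignment[site],
                "E_p": e_sub,
                "delta": e_sub - e_ref,
            }
        )
    return pd.DataFrame(rows)
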