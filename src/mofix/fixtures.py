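"""Offline test fixtures: toy ligand libraries, planted-optimum GA benchmarks,
and synthetic reaction-profile ensembles.

Nothing here is downloaded: the ligand pools are small curated SMILES lists
spanning the donor classes the pre-screen recognizes (amines, phosphines,
carbenes and oxygens for neutral ligands; halides, alkoxides, amides and
carbanions for anionic ones), kept small (<= 12 heavy atoms) so a full
pre-screen + scoring run completes in seconds on one CPU.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .complex_model import (
    LigandSpec,
    SCHROCK_CYCLE,
    find_donor_candidates,
)
from .energy_backend import default_surrogate_params
from .validation_pipeline import ReactionProfile
from .volcano import STEP_IDS

__all__ = [
    "NEUTRAL_POOL",
    "ANIONIC_POOL",
    "toy_ligand_library",
    "PlantedBenchmark",
    "planted_optimum_benchmark",
    "synthetic_profiles",
]

#: curated neutral donors: amines (sp3 + aromatic), phosphines, carbene, oxygens
NEUTRAL_POOL = [
    "N",               # ammonia
    "CN",              # methylamine
    "CN(C)C",          # trimethylamine
    "c1ccncc1",        # pyridine
    "Cc1cccnc1",       # 3-picoline
    "c1c[nH]cn1",      # imidazole
    "P",               # phosphine
    "CP(C)C",          # trimethylphosphine
    "CCP(CC)CC",       # triethylphosphine
    "CN1C=CN(C)[C]1",  # N,N'-dimethyl NHC carbene
    "COC",             # dimethyl ether
    "O",               # water
    "C=O",             # formaldehyde (carbonyl O donor)
    "C1CCOC1",         # tetrahydrofuran
]

#: curated anionic donors: halides, alkoxides/hydroxide, amides, carbanions
ANIONIC_POOL = [
    "[F-]",
    "[Cl-]",
    "[Br-]",
    "[OH-]",
    "C[O-]",           # methoxide
    "CC[O-]",          # ethoxide
    "[NH2-]",          # amide
    "C[N-]C",          # dimethylamide
    "[NH-]N",          # hydrazide
    "[CH3-]",          # methyl carbanion
    "C=[CH-]",         # vinyl carbanion
    "[c-]1ccccc1",     # phenyl carbanion
]


def toy_ligand_library(
    n_anionic: int, n_neutral: int, seed: int = 0, path: str | Path | None = None
) -> list[LigandSpec]:
    """Sample a ligand library from the curated pools (deterministic per seed).

    Every returned ligand parses and has at least one donor candidate.  When
    the request exceeds a pool, the pool is cycled.  With ``path`` the
    library is also written in the package's .smi/CSV format.
    """
    rng = np.random.default_rng(seed)
    out: list[LigandSpec] = []
    for pool, n, cls in (
        (ANIONIC_POOL, n_anionic, "anionic"),
        (NEUTRAL_POOL, n_neutral, "neutral"),
    ):
        idx = list(rng.permutation(len(pool)))
        chosen = list(itertools.islice(itertools.cycle(idx), n))
        for i in chosen:
            lig = LigandSpec(pool[i], cls)
            assert find_donor_candidates(lig), f"pool ligand without donor: {pool[i]}"
            out.append(lig)
    if path is not None:
        from .io import write_ligand_library

        write_ligand_library(path, out)
    return out


# --------------------------------------------------------------------------- #
# Planted-optimum GA benchmark
# --------------------------------------------------------------------------- #


@dataclass
class PlantedBenchmark:
    """A GA test landscape with a known best solution.

    Exactly one neutral ligand family in the library carries the motif; the
    surrogate grants ``bonus`` kcal/mol to the Mo-N2H+ intermediate of
    complexes containing it, which lowers the protonation energy (and hence
    raises the score) of motif-bearing catalysts only.
    """

    library: list[LigandSpec]
    surrogate_params: dict
    motif_smarts: str
    bonus: float


def planted_optimum_benchmark(
    motif_smarts: str = "[#15]",
    bonus: float = -40.0,
    seed: int = 0,
) -> PlantedBenchmark:
    """Library + surrogate parameters where the phosphine family is the optimum.

    The default motif is a phosphorus donor; only one neutral pool member in
    the benchmark library matches it.  ``bonus`` is applied to both N2H
    states, so Ep drops by ``|bonus|`` for motif carriers while Er is
    unaffected (the bonus cancels between the N2H+ and N2H states).
    """
    anionic = ["[Cl-]", "[OH-]", "C[O-]", "[NH2-]"]
    neutral = ["N", "CN", "c1ccncc1", "CP(C)C"]  # exactly one phosphine
    library = [LigandSpec(s, "anionic") for s in anionic] + [
        LigandSpec(s, "neutral") for s in neutral
    ]
    params = default_surrogate_params()
    params["motif"] = {
        "smarts": motif_smarts,
        "bonus": float(bonus),
        "states": ["N2H|1", "N2H|0"],
    }
    return PlantedBenchmark(library, params, motif_smarts, float(bonus))


# --------------------------------------------------------------------------- #
# Synthetic reaction-profile ensembles
# --------------------------------------------------------------------------- #


def synthetic_profiles(
    n: int,
    slopes: Sequence[float] | None = None,
    intercepts: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    descriptor_range: tuple[float, float] = (-5.0, 30.0),
) -> list[ReactionProfile]:
    """Profiles whose step energies follow planted linear relations.

    The descriptor (first-protonation step energy) is sampled uniformly; step
    k (k >= 2) is ``slopes[k] * x + intercepts[k]`` plus Gaussian noise.  The
    first step is the descriptor itself (slope 1, intercept 0, no noise), and
    cumulative state energies are the partial sums of the steps, so every
    profile satisfies the telescoping invariant by construction.
    """
    rng = np.random.default_rng(seed)
    n_steps = len(STEP_IDS)
    if slopes is None:
        slopes = [1.0] + [round(float(s), 3) for s in rng.uniform(-1.5, 1.5, n_steps - 1)]
    if intercepts is None:
        intercepts = [0.0] + [round(float(b), 3) for b in rng.uniform(-20, 20, n_steps - 1)]
    slopes = list(slopes)
    intercepts = list(intercepts)
    if len(slopes) != n_steps or len(intercepts) != n_steps:
        raise ValueError(f"need {n_steps} slopes and intercepts")
    profiles = []
    for i in range(n):
        x = float(rng.uniform(*descriptor_range))
        steps = [x]
        for k in range(1, n_steps):
            y = slopes[k] * x + intercepts[k]
            if noise_sd > 0:
                y += float(rng.normal(0.0, noise_sd))
            steps.append(y)
        rel = [0.0]
        for de in steps[:-1]:
            rel.append(rel[-1] + de)
        profiles.append(
            ReactionProfile(
                catalyst_id=f"synthetic-{i:03d}",
                states=list(SCHROCK_CYCLE),
                energies=rel,
                step_energies=steps,
                step_types=[s.entry_step for s in SCHROCK_CYCLE[1:]] + ["N2_binding"],
                level="synthetic",
            )
        )
    return profiles
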