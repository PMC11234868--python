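"""Linear scaling relations and volcano construction over cycle profiles.

Across a family of catalysts, the energy of each cycle step often scales
linearly with a single descriptor — here the first protonation energy
relative to the Mo-N2 resting state.  Each step is fitted by ordinary least
squares against the descriptor; relations with R² below a cutoff (default
0.2) are set aside.  The volcano's limiting curve is the pointwise maximum
of the retained lines over a descriptor grid; its apex (the argmin of the
limiting curve) marks the best compromise the family can reach, and the line
attaining the maximum at each grid point is the potential-determining step
(pds).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .complex_model import ValidationError
from .validation_pipeline import ReactionProfile

__all__ = [
    "ScalingRelation",
    "VolcanoModel",
    "fit_scaling_relations",
    "build_volcano",
    "plot_volcano",
]

#: human-readable ids for the 15 transitions (the resulting intermediate)
STEP_IDS = [
    "Mo-N2H+", "Mo-N2H", "Mo-N2H2+", "Mo-N2H2", "Mo-N2H3+", "Mo-N2H3",
    "Mo-N(+NH3)", "Mo-NH+", "Mo-NH", "Mo-NH2+", "Mo-NH2", "Mo-NH3+",
    "Mo-NH3", "Mo(+NH3)", "Mo-N2(binding)",
]


@dataclass
class ScalingRelation:
    step_id: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    x: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)

    def predict(self, descriptor: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(descriptor) + self.intercept


@dataclass
class VolcanoModel:
    relations: list[ScalingRelation]
    grid: np.ndarray
    limiting: np.ndarray
    pds: list[list[str]]
    apex_descriptor: float
    apex_energy: float
    boundary_apex: bool

    def to_json(self) -> str:
        return json.dumps(
            {
                "relations": [
                    {
                        "step_id": r.step_id,
                        "slope": r.slope,
                        "intercept": r.intercept,
                        "r_squared": r.r_squared,
                        "n_points": r.n_points,
                    }
                    for r in self.relations
                ],
                "grid": self.grid.tolist(),
                "limiting": self.limiting.tolist(),
                "pds": self.pds,
                "apex_descriptor": self.apex_descriptor,
                "apex_energy": self.apex_energy,
                "boundary_apex": self.boundary_apex,
            }
        )


def fit_scaling_relations(
    profiles: Sequence[ReactionProfile],
    cutoff: float = 0.2,
) -> tuple[list[ScalingRelation], list[ScalingRelation]]:
    """OLS fit of every step energy against the first-protonation descriptor.

    Returns (retained, rejected): relations with R² >= cutoff and the rest.
    The descriptor step itself fits with slope 1 and R² 1 by construction.
    """
    if len(profiles) < 3:
        raise ValidationError("need at least 3 profiles to fit scaling relations")
    x = np.array([p.descriptor for p in profiles], dtype=float)
    if np.ptp(x) < 1e-12:
        raise ValidationError("degenerate descriptor: zero variance across profiles")
    retained, rejected = [], []
    for k, step_id in enumerate(STEP_IDS):
        y = np.array([p.step_energies[k] for p in profiles], dtype=float)
        if np.ptp(y) < 1e-14:
            # flat step: perfectly predictable, slope 0
            rel = ScalingRelation(step_id, 0.0, float(y[0]), 1.0, len(x), x, y)
        else:
            fit = stats.linregress(x, y)
            rel = ScalingRelation(
                step_id,
                float(fit.slope),
                float(fit.intercept),
                float(fit.rvalue**2),
                len(x),
                x,
                y,
            )
        (retained if rel.r_squared >= cutoff else rejected).append(rel)
    return retained, rejected


def build_volcano(
    relations: Sequence[ScalingRelation],
    grid: np.ndarray | None = None,
    n_grid: int = 201,
) -> VolcanoModel:
    """Pointwise-maximum limiting curve and its apex over a descriptor grid.

    The default grid spans the observed descriptor range extended by 20% on
    each side.  Ties at line intersections credit every attaining step.
    """
    relations = list(relations)
    if len(relations) < 1:
        raise ValidationError("need at least one retained relation")
    if grid is None:
        xs = np.concatenate([r.x for r in relations if r.x is not None])
        lo, hi = float(xs.min()), float(xs.max())
        span = hi - lo if hi > lo else max(abs(hi), 1.0)
        grid = np.linspace(lo - 0.2 * span, hi + 0.2 * span, n_grid)
    grid = np.asarray(grid, dtype=float)
    lines = np.stack([r.predict(grid) for r in relations])
    limiting = lines.max(axis=0)
    tol = 1e-9 * max(1.0, float(np.abs(limiting).max()))
    pds = [
        [relations[i].step_id for i in range(len(relations)) if lines[i, g] >= limiting[g] - tol]
        for g in range(len(grid))
    ]
    apex_idx = int(np.argmin(limiting))
    boundary = apex_idx in (0, len(grid) - 1)
    slopes = [r.slope for r in relations]
    if all(s >= 0 for s in slopes) or all(s <= 0 for s in slopes):
        boundary = True
    return VolcanoModel(
        relations=relations,
        grid=grid,
        limiting=limiting,
        pds=pds,
        apex_descriptor=float(grid[apex_idx]),
        apex_energy=float(limiting[apex_idx]),
        boundary_apex=boundary,
    )


def relations_to_csv(
    retained: Sequence[ScalingRelation],
    rejected: Sequence[ScalingRelation],
    path: str | Path,
) -> Path:
    rows = [
        {
            "step_id": r.step_id,
            "slope": r.slope,
            "intercept": r.intercept,
            "r_squared": r.r_squared,
            "n_points": r.n_points,
            "retained": keep,
        }
        for rels, keep in ((retained, True), (rejected, False))
        for r in rels
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def plot_volcano(model: VolcanoModel, path: str | Path) -> Path:
    """Write a volcano plot (limiting curve + individual scaling lines)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for rel in model.relations:
        ax.plot(model.grid, rel.predict(model.grid), lw=0.8, alpha=0.6, label=rel.step_id)
    ax.plot(model.grid, model.limiting, "k-", lw=2.2, label="limiting (pds)")
    ax.axvline(model.apex_descriptor, color="gray", ls="--", lw=0.8)
    ax.set_xlabel("first protonation energy vs resting state (kcal/mol)")
    ax.set_ylabel("step energy (kcal/mol)")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
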