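"""File formats: ligand libraries (.smi / CSV), XYZ geometries, profile tables."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .complex_model import Conformer, LigandSpec, ValidationError

__all__ = [
    "read_ligand_library",
    "write_ligand_library",
    "write_xyz",
    "read_xyz",
]


def write_ligand_library(path: str | Path, ligands: Sequence[LigandSpec]) -> Path:
    """Write a ligand library; ``.csv`` gets a header, ``.smi`` is TSV.

    Columns: SMILES, id, charge_class.  Ids are ``L000``-style ordinals.
    """
    path = Path(path)
    rows = [
        {"smiles": l.smiles, "id": f"L{i:03d}", "charge_class": l.charge_class}
        for i, l in enumerate(ligands)
    ]
    if path.suffix == ".csv":
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        with open(path, "w") as fh:
            for r in rows:
                fh.write(f"{r['smiles']}\t{r['id']}\t{r['charge_class']}\n")
    return path


def read_ligand_library(path: str | Path) -> list[LigandSpec]:
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path)
        records = df[["smiles", "charge_class"]].itertuples(index=False)
    else:
        rows = []
        for line in path.read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"malformed library line: {line!r}")
            rows.append((parts[0], parts[2]))
        records = rows
    return [LigandSpec(smiles, charge_class) for smiles, charge_class in records]


def write_xyz(path: str | Path, conformer: Conformer, state: str | None = None) -> Path:
    path = Path(path)
    lines = [str(conformer.n_atoms)]
    comment = f"charge={conformer.total_charge} multiplicity={conformer.multiplicity}"
    if state is not None:
        comment += f" state={state}"
    lines.append(comment)
    for sym, (x, y, z) in zip(conformer.symbols, conformer.coords):
        lines.append(f"{sym} {x:18.10f} {y:18.10f} {z:18.10f}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_xyz(path: str | Path) -> tuple[list[str], np.ndarray, dict]:
    """Read one XYZ frame; returns (symbols, coords, metadata-from-comment)."""
    lines = Path(path).read_text().splitlines()
    n = int(lines[0])
    meta = {}
    for token in lines[1].split():
        if "=" in token:
            k, v = token.split("=", 1)
            meta[k] = v
    symbols, coords = [], []
    for line in lines[2 : 2 + n]:
        parts = line.split()
        symbols.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    return symbols, np.array(coords), meta
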