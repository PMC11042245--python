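"""Readers and writers for the formats the pipeline consumes and emits."""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable

from rdkit import Chem


def read_smiles_file(path: str | Path) -> list[str]:
    """SMILES text file: one molecule per line, optional whitespace-separated id."""
    smiles = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smiles.append(line.split()[0])
    if not smiles:
        raise ValueError(f"no SMILES found in {path}")
    return smiles


def read_sdf_file(path: str | Path) -> list[str]:
    """SDF (V2000) file -> SMILES list; unparseable blocks are skipped."""
    supplier = Chem.SDMolSupplier(str(path))
    smiles = [Chem.MolToSmiles(mol) for mol in supplier if mol is not None]
    if not smiles:
        raise ValueError(f"no parseable molecule in {path}")
    return smiles


def read_library(path: str | Path) -> list[str]:
    """Dispatch on extension: .sdf -> SDF, anything else -> SMILES text."""
    path = Path(path)
    if path.suffix.lower() == ".sdf":
        return read_sdf_file(path)
    return read_smiles_file(path)


def write_csv(
    path: str | Path, rows: Iterable[dict], fieldnames: list[str] | None = None
) -> None:
    rows = list(rows)
    if not rows and fieldnames is None:
        raise ValueError("nothing to write and no fieldnames given")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames or list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)


def read_curated_csv(path: str | Path) -> list[dict]:
    """Curated dataset CSV -> list of row dicts with typed fields."""
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    for row in rows:
        row["pchembl"] = float(row["pchembl"])
        row["n_source_records"] = int(row["n_source_records"])
        row["active"] = row["active"] in ("True", "true", "1")
    return rows


def _json_default(obj):
    # numpy scalars leak into reports; serialise them as plain numbers
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_json(path: str | Path, payload: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=_json_default) + "\n"
    )
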