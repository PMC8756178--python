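"""Readers and writers for molecule records and prediction outputs.

Supported inputs: SMILES lists (one per line, optional whitespace-separated
id), CSV with columns ``id, smiles, pka_acidic, pka_basic`` (empty cell =
missing label), and SDF (labels read from the ``PKA_ACIDIC`` /
``PKA_BASIC`` properties).  All readers standardize structures on ingest.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .chemgraph import MoleculeRecord, standardize_with_flag

__all__ = [
    "read_smiles_file",
    "read_csv",
    "read_sdf",
    "read_any",
    "write_predictions",
]

log = logging.getLogger(__name__)


def _record(record_id: str, raw: str,
            acidic: Optional[float] = None, basic: Optional[float] = None) -> MoleculeRecord:
    smiles, flagged = standardize_with_flag(raw)
    return MoleculeRecord(
        record_id=record_id,
        raw_structure=raw,
        standardized_smiles=smiles,
        acidic_label=acidic,
        basic_label=basic,
        non_neutralizable=flagged,
    )


def read_smiles_file(path: str) -> list[MoleculeRecord]:
    """One SMILES per line; an optional second token becomes the record id."""
    records = []
    for k, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        rid = parts[1] if len(parts) > 1 else f"mol{k:05d}"
        records.append(_record(rid, parts[0]))
    return records


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return float(value)


def read_csv(path: str) -> list[MoleculeRecord]:
    """CSV with columns [id, smiles, pka_acidic, pka_basic]."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        records.append(
            _record(
                str(row["id"]),
                str(row["smiles"]),
                _opt_float(row.get("pka_acidic")),
                _opt_float(row.get("pka_basic")),
            )
        )
    return records


def read_sdf(path: str) -> list[MoleculeRecord]:
    """SDF records; labels from named properties PKA_ACIDIC / PKA_BASIC."""
    records = []
    for k, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            log.warning("skipping unreadable SDF record %d", k)
            continue
        rid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{k:05d}"
        acidic = float(mol.GetProp("PKA_ACIDIC")) if mol.HasProp("PKA_ACIDIC") else None
        basic = float(mol.GetProp("PKA_BASIC")) if mol.HasProp("PKA_BASIC") else None
        records.append(_record(rid, Chem.MolToSmiles(mol), acidic, basic))
    return records


def read_any(path: str) -> list[MoleculeRecord]:
    suffix = Path(path).suffix.lower()
    if suffix in (".smi", ".txt"):
        return read_smiles_file(path)
    if suffix == ".csv":
        return read_csv(path)
    if suffix == ".sdf":
        return read_sdf(path)
    raise ValueError(f"unrecognized molecule file type: {path}")


def write_predictions(rows: Sequence[dict], path: str) -> None:
    """Write prediction rows (macro + per-site micro values) as CSV."""
    pd.DataFrame(list(rows)).to_csv(path, index=False)
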