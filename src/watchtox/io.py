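"""Readers and writers for the corpus tables.

Three on-disk tables feed the pipeline, each UTF-8 CSV with a header row
(JSON-lines accepted as an alternate dialect, selected by a ``.jsonl``
suffix):

* ``drugs`` — drug_id, label, withdrawal_reasons, atc_codes, smiles,
  fingerprint (0/1 string), plus one column per chemical descriptor;
* ``activities`` — drug_id, protein_accession, ic50_nm;
* ``profiles`` — protein_accession, sequence_length, plus one column per
  raw structural feature.

Reads are lossless round trips of writes. Rows violating a type invariant
(non-positive IC50, duplicate drug_id, negative structural counts) are
dropped and reported rather than aborting the load; genuinely malformed
files (missing mandatory columns) are hard errors.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import DrugRecord, Label, ProteinStructureProfile, TargetActivity

__all__ = ["read_dataset", "write_dataset", "MANDATORY_COLUMNS"]

log = logging.getLogger(__name__)

_LIST_SEP = "|"
_DRUG_RESERVED = ("drug_id", "label", "withdrawal_reasons", "atc_codes", "smiles", "fingerprint")

MANDATORY_COLUMNS = {
    "drugs": ("drug_id", "label"),
    "activities": ("drug_id", "protein_accession", "ic50_nm"),
    "profiles": ("protein_accession", "sequence_length"),
}


def _coerce_cell(value):
    """Parse a CSV cell: numeric if possible, else the raw string."""
    if isinstance(value, (int, float, bool)):
        return value
    try:
        return float(value)
    except (TypeError, ValueError):
        return value


def _load_rows(path: Path) -> list[dict]:
    if path.suffix in (".jsonl", ".ndjson"):
        with open(path, encoding="utf-8") as fh:
            return [json.loads(line) for line in fh if line.strip()]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return df.to_dict("records")


def _require_columns(rows: list[dict], schema: str) -> None:
    if not rows:
        return
    missing = [c for c in MANDATORY_COLUMNS[schema] if c not in rows[0]]
    if missing:
        raise ValueError(
            f"{schema} table is missing mandatory columns: {', '.join(missing)}"
        )


def read_dataset(path, schema: str, return_rejected: bool = False):
    """Load one corpus table into typed records.

    Parameters
    ----------
    path : str or Path
    schema : {"drugs", "activities", "profiles"}
    return_rejected : bool
        When true, also return the list of (row-number, reason) rejection
        reports for rows that failed a type invariant.
    """
    path = Path(path)
    if schema not in MANDATORY_COLUMNS:
        raise ValueError(f"unknown schema {schema!r}")
    rows = _load_rows(path)
    _require_columns(rows, schema)
    parser = {"drugs": _parse_drug, "activities": _parse_activity, "profiles": _parse_profile}[schema]

    records: list = []
    rejected: list[tuple[int, str]] = []
    seen_keys: set[str] = set()
    for i, row in enumerate(rows):
        try:
            rec = parser(row)
        except (ValueError, KeyError) as exc:
            rejected.append((i, str(exc)))
            continue
        key = getattr(rec, "drug_id", None) or getattr(rec, "protein_accession")
        if schema in ("drugs", "profiles"):
            if key in seen_keys:
                rejected.append((i, f"duplicate id {key!r}"))
                continue
            seen_keys.add(key)
        records.append(rec)
    for i, reason in rejected:
        log.warning("%s row %d rejected: %s", schema, i, reason)
    if return_rejected:
        return records, rejected
    return records


def _split_list(cell: str) -> list[str]:
    cell = cell or ""
    return [part for part in str(cell).split(_LIST_SEP) if part != ""]


def _parse_drug(row: dict) -> DrugRecord:
    fp_cell = str(row.get("fingerprint", "") or "")
    fingerprint = (
        np.frombuffer(fp_cell.encode(), dtype=np.uint8) - ord("0") if fp_cell else None
    )
    if fingerprint is not None and not np.isin(fingerprint, (0, 1)).all():
        raise ValueError(f"fingerprint of {row['drug_id']!r} is not a 0/1 string")
    chem: dict[str, object] = {}
    for col, cell in row.items():
        if col in _DRUG_RESERVED:
            continue
        if cell is None or cell == "":
            continue
        chem[col] = _coerce_cell(cell)
    return DrugRecord(
        drug_id=str(row["drug_id"]),
        label=Label(str(row["label"])),
        withdrawal_reasons=_split_list(row.get("withdrawal_reasons", "")),
        atc_codes=_split_list(row.get("atc_codes", "")),
        smiles=str(row["smiles"]) if row.get("smiles") else None,
        chem_features=chem,
        fingerprint=fingerprint,
    )


def _parse_activity(row: dict) -> TargetActivity:
    return TargetActivity(
        drug_id=str(row["drug_id"]),
        protein_accession=str(row["protein_accession"]),
        ic50_nm=float(row["ic50_nm"]),
    )


def _parse_profile(row: dict) -> ProteinStructureProfile:
    features = {
        col: float(cell)
        for col, cell in row.items()
        if col not in ("protein_accession", "sequence_length") and cell != ""
    }
    return ProteinStructureProfile(
        protein_accession=str(row["protein_accession"]),
        sequence_length=int(float(row["sequence_length"])),
        raw_features=features,
    )


def _format_number(value) -> str:
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value)


def write_dataset(records: Sequence, path, schema: str) -> None:
    """Write typed records to CSV (or JSON-lines by ``.jsonl`` suffix)."""
    path = Path(path)
    if schema == "drugs":
        chem_cols = sorted({k for r in records for k in r.chem_features})
        rows = []
        for r in records:
            row = {
                "drug_id": r.drug_id,
                "label": r.label.value,
                "withdrawal_reasons": _LIST_SEP.join(r.withdrawal_reasons),
                "atc_codes": _LIST_SEP.join(r.atc_codes),
                "smiles": r.smiles or "",
                "fingerprint": "".join(map(str, r.fingerprint)) if r.fingerprint is not None else "",
            }
            for c in chem_cols:
                v = r.chem_features.get(c)
                row[c] = "" if v is None else _format_number(v)
            rows.append(row)
        columns = list(_DRUG_RESERVED) + chem_cols
    elif schema == "activities":
        rows = [
            {"drug_id": a.drug_id, "protein_accession": a.protein_accession,
             "ic50_nm": _format_number(a.ic50_nm)}
            for a in records
        ]
        columns = list(MANDATORY_COLUMNS["activities"])
    elif schema == "profiles":
        feat_cols = sorted({k for p in records for k in p.raw_features})
        rows = []
        for p in records:
            row = {"protein_accession": p.protein_accession,
                   "sequence_length": str(p.sequence_length)}
            for c in feat_cols:
                v = p.raw_features.get(c)
                row[c] = "" if v is None else _format_number(v)
            rows.append(row)
        columns = ["protein_accession", "sequence_length"] + feat_cols
    else:
        raise ValueError(f"unknown schema {schema!r}")

    if path.suffix in (".jsonl", ".ndjson"):
        with open(path, "w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")
    else:
        pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
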