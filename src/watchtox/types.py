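"""Domain types for the withdrawal-prediction pipeline.

The pipeline works with four tabular views of a drug corpus:

* ``fingerprint`` — folded circular (Morgan/ECFP-like) substructure bits,
* ``chem`` — physicochemical descriptors and formulation flags,
* ``target`` — binary drug x protein incidence derived from IC50 records,
* ``target_feature`` — IC50-weighted structural features of inhibited proteins.

Records are plain dataclasses; dense views live in :class:`FeatureMatrix`,
a thin named-rows/named-columns wrapper around a numpy array.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Label",
    "View",
    "DrugRecord",
    "TargetActivity",
    "ProteinStructureProfile",
    "FeatureMatrix",
    "CHEM_NUMERIC_FEATURES",
    "CHEM_FLAG_FEATURES",
    "CHIRALITY_CATEGORIES",
]


class Label(str, enum.Enum):
    """Withdrawal status of a drug.

    ``INVESTIGATIONAL`` drugs (clinical-trial candidates) are screening
    inputs only and never enter training corpora.
    """

    WITHDRAWN = "withdrawn"
    NOT_WITHDRAWN = "not_withdrawn"
    INVESTIGATIONAL = "investigational"


class View(str, enum.Enum):
    """The four feature views a drug corpus is projected into."""

    FINGERPRINT = "fingerprint"
    CHEM = "chem"
    TARGET = "target"
    TARGET_FEATURE = "target_feature"


#: Continuous / count-valued chemical descriptors (ChEMBL naming).
CHEM_NUMERIC_FEATURES: tuple[str, ...] = (
    "alogp",
    "cx_logp",
    "cx_logd",
    "cx_most_apka",
    "cx_most_bpka",
    "aromatic_rings",
    "full_mwt",
    "mw_freebase",
    "mw_monoisotopic",
    "hba",
    "hbd",
    "hba_lipinski",
    "hbd_lipinski",
    "heavy_atoms",
    "num_lipinski_ro5_violations",
    "num_ro5_violations",
    "qed_weighted",
    "psa",
    "rtb",
)

#: Binary 0/1 descriptors: acid/base character, prodrug status, route of
#: administration, rule-of-three pass.
CHEM_FLAG_FEATURES: tuple[str, ...] = (
    "acid",
    "base",
    "neutral",
    "zwitterion",
    "prodrug",
    "oral",
    "parenteral",
    "topical",
    "ro3_pass",
)

#: One-hot categories for molecular chirality (ChEMBL vocabulary).
CHIRALITY_CATEGORIES: tuple[str, ...] = (
    "achiral",
    "racemic",
    "single_stereoisomer",
)


@dataclass
class DrugRecord:
    """One drug: identity, withdrawal label, annotations and structure.

    ``chem_features`` maps descriptor name -> value; a value may be numeric,
    a 0/1 flag, a chirality category string, or ``None`` for explicitly
    missing. ``fingerprint`` optionally carries a precomputed bit vector so
    synthetic corpora do not require a chemistry backend.
    """

    drug_id: str
    label: Label
    withdrawal_reasons: list[str] = field(default_factory=list)
    atc_codes: list[str] = field(default_factory=list)
    smiles: str | None = None
    chem_features: dict[str, object] = field(default_factory=dict)
    fingerprint: np.ndarray | None = None

    def __post_init__(self) -> None:
        if isinstance(self.label, str) and not isinstance(self.label, Label):
            self.label = Label(self.label)
        if self.fingerprint is not None:
            self.fingerprint = np.asarray(self.fingerprint, dtype=np.uint8)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DrugRecord):
            return NotImplemented
        fp_equal = (
            (self.fingerprint is None and other.fingerprint is None)
            or (
                self.fingerprint is not None
                and other.fingerprint is not None
                and np.array_equal(self.fingerprint, other.fingerprint)
            )
        )
        return fp_equal and (
            self.drug_id,
            self.label,
            self.withdrawal_reasons,
            self.atc_codes,
            self.smiles,
            self.chem_features,
        ) == (
            other.drug_id,
            other.label,
            other.withdrawal_reasons,
            other.atc_codes,
            other.smiles,
            other.chem_features,
        )


@dataclass(frozen=True)
class TargetActivity:
    """A (drug, protein, IC50) bioactivity triple; IC50 in nM, > 0."""

    drug_id: str
    protein_accession: str
    ic50_nm: float

    def __post_init__(self) -> None:
        if not self.ic50_nm > 0:
            raise ValueError(
                f"ic50_nm must be positive, got {self.ic50_nm!r} for "
                f"({self.drug_id}, {self.protein_accession})"
            )


@dataclass
class ProteinStructureProfile:
    """Raw per-protein structural feature counts plus sequence length.

    Raw features are residue or segment counts (helix residues, contacts,
    transmembrane segments, ...) and are length-normalized downstream.
    """

    protein_accession: str
    sequence_length: int
    raw_features: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sequence_length < 1:
            raise ValueError(
                f"sequence_length must be >= 1, got {self.sequence_length} "
                f"for {self.protein_accession}"
            )
        for name, value in self.raw_features.items():
            if value < 0:
                raise ValueError(
                    f"raw feature {name!r} of {self.protein_accession} is "
                    f"negative ({value})"
                )


class FeatureMatrix:
    """Named drugs x named features dense real matrix, tagged with its view."""

    def __init__(
        self,
        row_ids: Sequence[str],
        col_names: Sequence[str],
        values: np.ndarray,
        view: View | str,
        normalized: bool = False,
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (len(row_ids), len(col_names)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"({len(row_ids)} rows, {len(col_names)} cols)"
            )
        if np.isnan(values).any():
            raise ValueError("FeatureMatrix may not contain missing values")
        view = View(view)
        if view is View.FINGERPRINT and not np.isin(values, (0.0, 1.0)).all():
            raise ValueError("fingerprint view must contain only 0/1 entries")
        self.row_ids = list(row_ids)
        self.col_names = list(col_names)
        self.values = values
        self.view = view
        self.normalized = bool(normalized)
        self._row_index = {r: i for i, r in enumerate(self.row_ids)}
        if len(self._row_index) != len(self.row_ids):
            raise ValueError("duplicate drug_id in row_ids")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, drug_id: str) -> np.ndarray:
        return self.values[self._row_index[drug_id]]

    def subset_rows(self, drug_ids: Sequence[str]) -> "FeatureMatrix":
        """Rows restricted to ``drug_ids``, in the given order."""
        idx = [self._row_index[d] for d in drug_ids]
        return FeatureMatrix(
            list(drug_ids), self.col_names, self.values[idx], self.view, self.normalized
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_names)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, p = self.shape
        norm = "normalized" if self.normalized else "raw"
        return f"<FeatureMatrix view={self.view.value} {n}x{p} {norm}>"


def labels_vector(records: Sequence[DrugRecord]) -> np.ndarray:
    """Binary label vector (1 = withdrawn) for training-eligible records."""
    out = []
    for r in records:
        if r.label is Label.INVESTIGATIONAL:
            raise ValueError(
                f"investigational drug {r.drug_id} has no training label"
            )
        out.append(1 if r.label is Label.WITHDRAWN else 0)
    return np.asarray(out, dtype=int)


def as_mapping(records: Sequence[DrugRecord]) -> Mapping[str, DrugRecord]:
    return {r.drug_id: r for r in records}
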