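"""Assembly of the four per-drug feature views.

``build_chem_matrix`` / ``build_target_matrix`` / ``build_fingerprint_matrix``
construct single views; :class:`ViewBuilder` fits the full layout (column
sets, imputation medians, per-protein IC50 maxima) on a training corpus and
projects any drug list — including held-out or investigational drugs —
onto exactly that layout, so no information from non-training drugs leaks
into column choice, imputation or IC50 normalization.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np

from .fingerprints import encode_fingerprint, fingerprint_bit_names
from .target_features import build_target_feature_matrix, max_ic50_by_protein
from .types import (
    CHEM_FLAG_FEATURES,
    CHEM_NUMERIC_FEATURES,
    CHIRALITY_CATEGORIES,
    DrugRecord,
    FeatureMatrix,
    ProteinStructureProfile,
    TargetActivity,
    View,
)

__all__ = [
    "build_chem_matrix",
    "build_target_matrix",
    "build_fingerprint_matrix",
    "ViewBuilder",
]

log = logging.getLogger(__name__)


def _chem_columns(records: Sequence[DrugRecord]) -> list[str]:
    """Stable chem column order: known numerics, flags, chirality one-hots,
    then any unrecognized numeric descriptors alphabetically."""
    observed = {k for r in records for k in r.chem_features}
    cols = [c for c in CHEM_NUMERIC_FEATURES if c in observed]
    cols += [c for c in CHEM_FLAG_FEATURES if c in observed]
    if "chirality" in observed:
        cols += [f"chirality_{c}" for c in CHIRALITY_CATEGORIES]
    known = set(CHEM_NUMERIC_FEATURES) | set(CHEM_FLAG_FEATURES) | {"chirality"}
    cols += sorted(observed - known)
    return cols


def _chem_cell(record: DrugRecord, col: str) -> float | None:
    if col.startswith("chirality_"):
        cat = record.chem_features.get("chirality")
        if cat is None:
            return None
        return 1.0 if str(cat) == col[len("chirality_"):] else 0.0
    v = record.chem_features.get(col)
    if v is None:
        return None
    if isinstance(v, bool):
        return 1.0 if v else 0.0
    return float(v)


def build_chem_matrix(
    records: Sequence[DrugRecord],
    columns: Sequence[str] | None = None,
    medians: Mapping[str, float] | None = None,
) -> FeatureMatrix:
    """Chemical-descriptor view: numerics pass through, flags and chirality
    become 0/1 columns, missing values are imputed with ``medians``
    (training-set medians; computed from ``records`` when not given).

    Records with no chemical features at all are excluded with a warning.
    """
    if not records:
        raise ValueError("no drug records given")
    usable = [r for r in records if r.chem_features]
    for r in records:
        if not r.chem_features:
            log.warning("drug %s has no chemical features; excluded from chem view", r.drug_id)
    if columns is None:
        columns = _chem_columns(usable)
    raw = np.full((len(usable), len(columns)), np.nan)
    for i, r in enumerate(usable):
        for j, col in enumerate(columns):
            cell = _chem_cell(r, col)
            if cell is not None:
                raw[i, j] = cell
    if medians is None:
        with np.errstate(all="ignore"):
            med = np.nanmedian(raw, axis=0)
        medians = {c: (0.0 if np.isnan(m) else float(m)) for c, m in zip(columns, med)}
    for j, col in enumerate(columns):
        mask = np.isnan(raw[:, j])
        raw[mask, j] = medians.get(col, 0.0)
    return FeatureMatrix([r.drug_id for r in usable], list(columns), raw, View.CHEM)


def chem_medians(records: Sequence[DrugRecord], columns: Sequence[str]) -> dict[str, float]:
    """Per-column medians over observed (non-missing) values."""
    raw = np.full((len(records), len(columns)), np.nan)
    for i, r in enumerate(records):
        for j, col in enumerate(columns):
            cell = _chem_cell(r, col)
            if cell is not None:
                raw[i, j] = cell
    with np.errstate(all="ignore"):
        med = np.nanmedian(raw, axis=0)
    return {c: (0.0 if np.isnan(m) else float(m)) for c, m in zip(columns, med)}


def build_target_matrix(
    activities: Iterable[TargetActivity],
    drugs: Sequence[str],
    proteins: Sequence[str] | None = None,
    ic50_cutoff_nm: float | None = None,
) -> FeatureMatrix:
    """Binary drug x protein incidence view.

    Entry is 1 when the drug has at least one activity record for the
    protein passing ``ic50_cutoff_nm`` (default: any record counts).
    """
    acts = [a for a in activities if ic50_cutoff_nm is None or a.ic50_nm <= ic50_cutoff_nm]
    if proteins is None:
        proteins = sorted({a.protein_accession for a in acts})
    col_index = {p: j for j, p in enumerate(proteins)}
    row_index = {d: i for i, d in enumerate(drugs)}
    values = np.zeros((len(drugs), len(proteins)))
    for a in acts:
        i = row_index.get(a.drug_id)
        j = col_index.get(a.protein_accession)
        if i is not None and j is not None:
            values[i, j] = 1.0
    return FeatureMatrix(list(drugs), list(proteins), values, View.TARGET)


def build_fingerprint_matrix(
    records: Sequence[DrugRecord], n_bits: int | None = None
) -> FeatureMatrix:
    """Fingerprint view from precomputed bit vectors or SMILES encoding."""
    rows = []
    for r in records:
        if r.fingerprint is not None:
            rows.append(np.asarray(r.fingerprint, dtype=float))
        elif r.smiles is not None:
            bits = n_bits if n_bits is not None else 512
            rows.append(encode_fingerprint(r.smiles, n_bits=bits, drug_id=r.drug_id).astype(float))
        else:
            raise ValueError(f"drug {r.drug_id} has neither a fingerprint nor a structure")
    widths = {row.shape[0] for row in rows}
    if len(widths) > 1:
        raise ValueError(f"inconsistent fingerprint widths: {sorted(widths)}")
    width = widths.pop() if widths else (n_bits or 512)
    values = np.vstack(rows) if rows else np.zeros((0, width))
    return FeatureMatrix(
        [r.drug_id for r in records], fingerprint_bit_names(width), values, View.FINGERPRINT
    )


class ViewBuilder:
    """Fits the four-view layout on a training corpus, then projects drugs.

    After :meth:`fit`, :meth:`transform` maps any drug list (with its
    activity records) onto the training layout: same columns, training
    imputation medians, training per-protein IC50 maxima.
    """

    def __init__(self, ic50_cutoff_nm: float | None = None, eq2_denominator: bool = True,
                 pooled_target_features: bool = False) -> None:
        self.ic50_cutoff_nm = ic50_cutoff_nm
        self.eq2_denominator = eq2_denominator
        self.pooled_target_features = pooled_target_features
        self.fitted = False

    def fit(
        self,
        records: Sequence[DrugRecord],
        activities: Sequence[TargetActivity],
        profiles: Sequence[ProteinStructureProfile],
    ) -> "ViewBuilder":
        train_ids = {r.drug_id for r in records}
        train_acts = [a for a in activities if a.drug_id in train_ids]
        self.chem_columns_ = _chem_columns([r for r in records if r.chem_features])
        self.chem_medians_ = chem_medians(records, self.chem_columns_)
        profiled = {p.protein_accession for p in profiles}
        self.proteins_ = sorted({a.protein_accession for a in train_acts})
        self.s_ic50_max_ = max_ic50_by_protein(
            a for a in train_acts if a.protein_accession in profiled
        )
        self.profiles_ = list(profiles)
        ref_tf = build_target_feature_matrix(
            profiles, train_acts, [r.drug_id for r in records],
            denominator=self.eq2_denominator, pooled=self.pooled_target_features,
        )
        self.target_feature_columns_ = ref_tf.col_names
        self.n_bits_ = None
        for r in records:
            if r.fingerprint is not None:
                self.n_bits_ = int(len(r.fingerprint))
                break
        self.fitted = True
        return self

    def transform(
        self,
        records: Sequence[DrugRecord],
        activities: Sequence[TargetActivity],
    ) -> dict[View, FeatureMatrix]:
        if not self.fitted:
            raise RuntimeError("ViewBuilder.transform called before fit")
        ids = [r.drug_id for r in records]
        id_set = set(ids)
        acts = [a for a in activities if a.drug_id in id_set]
        return {
            View.FINGERPRINT: build_fingerprint_matrix(records, n_bits=self.n_bits_),
            View.CHEM: build_chem_matrix(records, self.chem_columns_, self.chem_medians_),
            View.TARGET: build_target_matrix(
                acts, ids, self.proteins_, self.ic50_cutoff_nm
            ),
            View.TARGET_FEATURE: build_target_feature_matrix(
                self.profiles_, acts, ids,
                s_ic50_max=self.s_ic50_max_, columns=self.target_feature_columns_,
                denominator=self.eq2_denominator, pooled=self.pooled_target_features,
            ),
        }
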