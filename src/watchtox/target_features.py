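"""IC50-weighted protein structural features (the target_feature view).

Each protein's raw structural counts (helix residues, contacts, ...) are
first normalized by sequence length to per-residue rates, then weighted by
the potency of the drug-protein interaction:

    F = f * (max(sIC50) - pIC50 + 1) / max(sIC50)

where ``f`` is the length-normalized feature, ``pIC50`` the IC50 (nM) of
the drug-protein pair, and ``sIC50`` the set of IC50 values recorded for
that protein across the training corpus. The weight is largest for the
most potent binder of the protein (F -> f * (max+1-min)/max ~= f) and
decays linearly to f/max(sIC50) for the weakest. An alternate reading
without the denominator is available via ``denominator=False``.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np

from .types import FeatureMatrix, ProteinStructureProfile, TargetActivity, View

__all__ = [
    "length_normalize",
    "eq2_weight",
    "min_ic50_by_pair",
    "max_ic50_by_protein",
    "build_target_feature_matrix",
]

log = logging.getLogger(__name__)


def length_normalize(profile: ProteinStructureProfile) -> dict[str, float]:
    """Raw structural counts divided by protein sequence length."""
    n = profile.sequence_length
    return {name: value / n for name, value in profile.raw_features.items()}


def eq2_weight(
    f: float, p_ic50: float, s_ic50_max: float, denominator: bool = True
) -> float:
    """Potency weighting of a length-normalized protein feature.

    Strictly decreasing in ``p_ic50`` (weaker binding -> smaller weight);
    equals ``f / s_ic50_max`` at ``p_ic50 == s_ic50_max``.
    """
    if s_ic50_max <= 0:
        raise ValueError(f"s_ic50_max must be positive, got {s_ic50_max}")
    if f < 0:
        raise ValueError(f"feature value must be nonnegative, got {f}")
    weight = s_ic50_max - p_ic50 + 1.0
    if denominator:
        weight /= s_ic50_max
    return f * weight


def min_ic50_by_pair(
    activities: Iterable[TargetActivity],
) -> dict[tuple[str, str], float]:
    """Strongest (minimum) IC50 per (drug, protein) pair."""
    best: dict[tuple[str, str], float] = {}
    for a in activities:
        key = (a.drug_id, a.protein_accession)
        if key not in best or a.ic50_nm < best[key]:
            best[key] = a.ic50_nm
    return best


def max_ic50_by_protein(activities: Iterable[TargetActivity]) -> dict[str, float]:
    """Weakest (maximum) IC50 recorded per protein over the given corpus.

    Pass training-corpus activities only: the sIC50 set must never include
    held-out drugs.
    """
    worst: dict[str, float] = {}
    for a in activities:
        p = a.protein_accession
        if p not in worst or a.ic50_nm > worst[p]:
            worst[p] = a.ic50_nm
    return worst


def build_target_feature_matrix(
    profiles: Sequence[ProteinStructureProfile],
    activities: Sequence[TargetActivity],
    drugs: Sequence[str],
    s_ic50_max: Mapping[str, float] | None = None,
    columns: Sequence[str] | None = None,
    denominator: bool = True,
    pooled: bool = False,
) -> FeatureMatrix:
    """Per-drug matrix of potency-weighted protein structural features.

    One column per (protein, structural feature) pair by default, named
    ``{accession}:{feature}``; ``pooled=True`` instead sums weights over
    proteins to one column per structural feature. A drug with no activity
    record against a protein has 0 in that protein's columns.

    ``s_ic50_max`` (per-protein IC50 maxima) defaults to the maxima of the
    supplied activities; pass stored training-corpus maxima when
    transforming held-out drugs. ``columns`` fixes the column set (and
    order) for conforming held-out matrices to a training layout.
    """
    profile_map = {p.protein_accession: p for p in profiles}
    kept = [a for a in activities if a.protein_accession in profile_map]
    dropped = len(activities) - len(kept)
    if dropped:
        log.warning(
            "%d activity records dropped: protein has no structure profile", dropped
        )
    if s_ic50_max is None:
        s_ic50_max = max_ic50_by_protein(kept)
    pair_ic50 = min_ic50_by_pair(kept)

    normalized = {acc: length_normalize(p) for acc, p in profile_map.items()}
    if columns is None:
        feature_names = sorted({f for feats in normalized.values() for f in feats})
        if pooled:
            columns = feature_names
        else:
            proteins = sorted({a.protein_accession for a in kept})
            columns = [f"{acc}:{feat}" for acc in proteins for feat in feature_names]
    col_index = {c: i for i, c in enumerate(columns)}

    values = np.zeros((len(drugs), len(columns)))
    row_index = {d: i for i, d in enumerate(drugs)}
    for (drug_id, acc), p_ic50 in pair_ic50.items():
        if drug_id not in row_index or acc not in s_ic50_max:
            continue
        smax = s_ic50_max[acc]
        p_eff = min(p_ic50, smax)  # held-out pair may exceed the training max
        for feat, f in normalized[acc].items():
            name = feat if pooled else f"{acc}:{feat}"
            j = col_index.get(name)
            if j is None:
                continue
            values[row_index[drug_id], j] += eq2_weight(f, p_eff, smax, denominator)

    return FeatureMatrix(list(drugs), list(columns), values, View.TARGET_FEATURE)
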