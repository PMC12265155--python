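"""Consensus feature selection and class-contrast summaries.

Three selectors — recursive feature elimination with 5-fold
cross-validation over a random forest (RFECV), a zero-variance filter, and
top-25% univariate chi-squared selection — are each run on ten balanced
80% resamples of the corpus (seeds 0-9). A feature's per-method score is
10 x (times selected / repeats); the combined consensus score is the
unweighted mean of the three, on the same 0-10 scale.

"Balanced 80%" undersamples the majority class to parity, then takes 80%
of the balanced pool: with 120 withdrawn vs 1511 not-withdrawn drugs the
resample is 96 + 96.

``class_contrast`` reports the withdrawn / not-withdrawn log2 ratio of a
feature's class summaries (means for continuous features, class-normalized
frequencies for 0/1 flags) with a two-sample significance test (Welch for
continuous, Fisher exact for flags).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFECV, chi2
from sklearn.model_selection import StratifiedKFold

from .enrichment import fisher_exact_2x2
from .types import DrugRecord, FeatureMatrix, Label

__all__ = [
    "SelectionScore",
    "ContrastResult",
    "balanced_resample",
    "select_rfecv",
    "select_variance",
    "select_univariate",
    "consensus_score",
    "class_contrast",
]

SELECTION_SEEDS = tuple(range(10))
RESAMPLE_FRACTION = 0.8
UNIVARIATE_FRACTION = 0.25


@dataclass
class SelectionScore:
    """Per-feature consensus of the three selectors, out of 10."""

    feature_name: str
    per_method: dict[str, float]
    combined: float
    #: per_seed[s] = mean selection indicator over the three methods at seed s.
    per_seed: list[float]


@dataclass(frozen=True)
class ContrastResult:
    feature_name: str
    withdrawn_summary: float
    not_withdrawn_summary: float
    log2_ratio: float  # nan when a class summary is nonpositive
    p_value: float
    significant: bool


def balanced_resample(
    records: Sequence[DrugRecord],
    fraction: float = RESAMPLE_FRACTION,
    seed: int = 0,
) -> list[DrugRecord]:
    """Class-balanced subsample: round(fraction x minority count) per class.

    Deterministic per seed; sampling without replacement within class.
    """
    withdrawn = [r for r in records if r.label is Label.WITHDRAWN]
    not_withdrawn = [r for r in records if r.label is Label.NOT_WITHDRAWN]
    if len(withdrawn) < 2 or len(not_withdrawn) < 2:
        raise ValueError("balanced resampling needs >= 2 drugs per class")
    per_class = int(round(fraction * min(len(withdrawn), len(not_withdrawn))))
    rng = np.random.default_rng(seed)
    out: list[DrugRecord] = []
    for group in (withdrawn, not_withdrawn):
        idx = rng.choice(len(group), size=per_class, replace=False)
        out.extend(group[i] for i in sorted(idx))
    return out


def select_rfecv(
    matrix: FeatureMatrix,
    labels: np.ndarray,
    seed: int = 0,
    n_trees: int = 100,
) -> set[str]:
    """Features kept by recursive elimination (step 1) under 5-fold
    cross-validated random-forest scoring."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("RFECV needs both classes present")
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    selector = RFECV(forest, step=1, cv=cv, n_jobs=1)
    selector.fit(matrix.values, labels)
    return {c for c, keep in zip(matrix.col_names, selector.support_) if keep}


def select_variance(matrix: FeatureMatrix) -> set[str]:
    """Features with strictly positive variance on the given rows."""
    variances = matrix.values.var(axis=0)
    return {c for c, v in zip(matrix.col_names, variances) if v > 0}


def select_univariate(
    matrix: FeatureMatrix,
    labels: np.ndarray,
    fraction: float = UNIVARIATE_FRACTION,
) -> set[str]:
    """Top ceil(fraction x p) features by the chi-squared statistic.

    Requires nonnegative feature values (min-max normalize first); ties at
    the cutoff break by feature name so the selection is deterministic.
    """
    if (matrix.values < 0).any():
        raise ValueError(
            "chi-squared selection needs nonnegative features; min-max "
            "normalize the matrix first"
        )
    scores, _ = chi2(matrix.values, np.asarray(labels))
    scores = np.nan_to_num(scores, nan=0.0)  # constant columns score 0
    k = math.ceil(fraction * len(matrix.col_names))
    ranked = sorted(
        zip(matrix.col_names, scores), key=lambda cs: (-cs[1], cs[0])
    )
    return {name for name, _ in ranked[:k]}


def _minmax(matrix: FeatureMatrix) -> FeatureMatrix:
    # local min-max scaling of a subsample; constant columns map to 0
    lo = matrix.values.min(axis=0)
    hi = matrix.values.max(axis=0)
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    values = (matrix.values - lo) / safe
    values[:, span == 0] = 0.0
    return FeatureMatrix(matrix.row_ids, matrix.col_names, values, matrix.view, normalized=True)


def consensus_score(
    records: Sequence[DrugRecord],
    matrix: FeatureMatrix,
    seeds: Sequence[int] = SELECTION_SEEDS,
    fraction: float = RESAMPLE_FRACTION,
) -> list[SelectionScore]:
    """Consensus importance of every feature across selectors and resamples.

    For each seed a balanced ``fraction`` resample is drawn, min-max scaled
    within the resample, and each selector marks the features it keeps.
    Per-method score = 10 x selections / len(seeds); combined = mean of the
    three methods. Sorted descending by combined score, ties by name.
    """
    methods = ("rfecv", "variance", "univariate")
    counts = {c: {m: 0 for m in methods} for c in matrix.col_names}
    per_seed_hits = {c: [] for c in matrix.col_names}
    for seed in seeds:
        sub_records = balanced_resample(records, fraction, seed)
        ids = [r.drug_id for r in sub_records]
        labels = np.array([1 if r.label is Label.WITHDRAWN else 0 for r in sub_records])
        sub = _minmax(matrix.subset_rows(ids))
        picked = {
            "rfecv": select_rfecv(sub, labels, seed),
            "variance": select_variance(sub),
            "univariate": select_univariate(sub, labels),
        }
        for c in matrix.col_names:
            hits = 0
            for m in methods:
                if c in picked[m]:
                    counts[c][m] += 1
                    hits += 1
            per_seed_hits[c].append(hits / len(methods))

    out = []
    for c in matrix.col_names:
        per_method = {m: 10.0 * counts[c][m] / len(seeds) for m in methods}
        combined = sum(per_method.values()) / len(methods)
        out.append(SelectionScore(c, per_method, combined, per_seed_hits[c]))
    out.sort(key=lambda s: (-s.combined, s.feature_name))
    return out


def _is_flag(values: np.ndarray) -> bool:
    return bool(np.isin(values[~np.isnan(values)], (0.0, 1.0)).all())


def class_contrast(
    records: Sequence[DrugRecord],
    feature: str,
    alpha: float = 0.05,
) -> ContrastResult:
    """Withdrawn vs not-withdrawn contrast of one chemical feature.

    Continuous features compare class means with a Welch two-sample test;
    0/1 flags compare class-normalized frequencies with a Fisher exact
    test. The log2 ratio is undefined (nan) when a class summary is
    nonpositive, never +/-inf.
    """
    groups: dict[Label, list[float]] = {Label.WITHDRAWN: [], Label.NOT_WITHDRAWN: []}
    for r in records:
        if r.label not in groups:
            continue
        v = r.chem_features.get(feature)
        if v is None or isinstance(v, str):
            continue
        groups[r.label].append(float(v))
    w = np.asarray(groups[Label.WITHDRAWN])
    nw = np.asarray(groups[Label.NOT_WITHDRAWN])
    if len(w) == 0 or len(nw) == 0:
        raise ValueError(f"feature {feature!r} observed in only one class")

    if _is_flag(w) and _is_flag(nw):
        ws, ns = w.mean(), nw.mean()
        a, b = int(w.sum()), int(len(w) - w.sum())
        c, d = int(nw.sum()), int(len(nw) - nw.sum())
        _, p = fisher_exact_2x2(a, b, c, d)
    else:
        ws, ns = float(w.mean()), float(nw.mean())
        p = float(stats.ttest_ind(w, nw, equal_var=False).pvalue)

    ratio = math.log2(ws / ns) if ws > 0 and ns > 0 else math.nan
    return ContrastResult(feature, float(ws), float(ns), ratio, p, p < alpha)
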