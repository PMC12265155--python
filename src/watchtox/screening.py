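"""Repeated-seed screening of investigational drugs.

An ensemble is trained independently under each of ten seeds (0-9); every
candidate drug receives one hard withdrawal label per seed (probability
threshold 0.5), and the labels are summed into a 0-10 vote count. The
closer the count is to 10, the stronger the withdrawal signal; by default
only unanimous candidates (10/10) are flagged.

Candidates never enter training corpora or normalization statistics: each
model projects them through its own training-corpus view layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ensemble import EnsembleModel
from .types import DrugRecord, TargetActivity

__all__ = ["ScreenResult", "screen", "report"]

N_MODELS = 10
FLAG_VOTES = 10


@dataclass(frozen=True)
class ScreenResult:
    drug_id: str
    votes: int
    per_seed_probabilities: tuple[float, ...]
    flagged: bool


def screen(
    models: Sequence[EnsembleModel],
    candidates: Sequence[DrugRecord],
    activities: Sequence[TargetActivity],
    flag_votes: int = FLAG_VOTES,
    allow_partial: bool = False,
) -> list[ScreenResult]:
    """Vote-count screening of candidate drugs under the per-seed models.

    Requires the full complement of ten models unless ``allow_partial``;
    the vote is invariant to model order.
    """
    if len(models) < N_MODELS and not allow_partial:
        raise ValueError(
            f"screening expects {N_MODELS} per-seed models, got {len(models)} "
            "(pass allow_partial=True to override)"
        )
    if not candidates:
        return []
    probs = np.column_stack(
        [m.predict_proba(candidates, activities) for m in models]
    )
    labels = probs >= 0.5
    out = []
    for i, rec in enumerate(candidates):
        votes = int(labels[i].sum())
        out.append(
            ScreenResult(
                drug_id=rec.drug_id,
                votes=votes,
                per_seed_probabilities=tuple(float(p) for p in probs[i]),
                flagged=votes >= flag_votes,
            )
        )
    return out


def report(results: Sequence[ScreenResult]) -> tuple[pd.DataFrame, dict[str, float]]:
    """Ranked screening table plus summary fractions.

    Sorted by votes descending, ties by drug_id; the summary reports the
    fraction of all candidates with votes in at least half the runs and
    the fraction flagged.
    """
    if not results:
        raise ValueError("no screening results to report")
    ordered = sorted(results, key=lambda r: (-r.votes, r.drug_id))
    n_seeds = len(ordered[0].per_seed_probabilities)
    rows = []
    for r in ordered:
        row = {"drug_id": r.drug_id, "votes": r.votes, "flagged": r.flagged}
        row.update({f"p_seed{j}": p for j, p in enumerate(r.per_seed_probabilities)})
        rows.append(row)
    table = pd.DataFrame(rows)
    summary = {
        "n_candidates": float(len(ordered)),
        "fraction_votes_ge_half": float(
            np.mean([r.votes >= n_seeds / 2 for r in ordered])
        ),
        "fraction_flagged": float(np.mean([r.flagged for r in ordered])),
        "mean_votes": float(np.mean([r.votes for r in ordered])),
    }
    return table, summary
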