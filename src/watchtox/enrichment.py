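"""Withdrawal-reason landscape and ATC level-1 enrichment analysis.

Withdrawal reasons are free-text regulatory annotations; a shipped,
user-editable curation table maps them onto canonical labels and the organ
system most affected. ATC (Anatomical Therapeutic Chemical) codes classify
drugs by site of action; the first letter is the anatomical main group (14
groups in the WHO standard). Enrichment of each group among withdrawn
versus not-withdrawn drugs is tested with a two-sided Fisher exact test,
Bonferroni-corrected over the groups tested (0.05/14 = 0.0036 for the full
standard).

The exact test is computed from the fixed-margin hypergeometric definition
in exact integer arithmetic: with margins fixed, every table shares the
denominator C(n, a+c), so the two-sided p-value is the ratio of summed
integer numerators over tables no more probable than the observed one.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

from .types import DrugRecord, Label

__all__ = [
    "load_reason_map",
    "normalize_reason",
    "summarize_reasons",
    "atc_level1",
    "fisher_exact_2x2",
    "enrich_all",
    "bonferroni_threshold",
    "EnrichmentResult",
    "ReasonSummary",
    "ATC_LEVEL1_GROUPS",
]

log = logging.getLogger(__name__)

#: The 14 anatomical main groups of the WHO ATC standard.
ATC_LEVEL1_GROUPS = tuple("ABCDGHJLMNPRSV")

ALPHA = 0.05


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    a: int  # withdrawn, in category
    b: int  # withdrawn, not in category
    c: int  # not withdrawn, in category
    d: int  # not withdrawn, not in category
    odds_ratio: float
    p_value: float
    significant_raw: bool
    significant_bonferroni: bool


@dataclass(frozen=True)
class ReasonSummary:
    organ_system: str
    count: int
    fraction: float


def load_reason_map(path: str | Path | None = None) -> dict[str, tuple[str, str]]:
    """Load the reason curation table: raw label -> (canonical, organ system).

    Defaults to the table shipped with the package; keys are case-folded
    and whitespace-trimmed.
    """
    if path is None:
        source = resources.files("watchtox.data").joinpath("reason_map.csv")
        text = source.read_text(encoding="utf-8")
        rows = list(csv.DictReader(text.splitlines()))
    else:
        with open(path, encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
    mapping = {}
    for row in rows:
        mapping[row["raw"].strip().casefold()] = (
            row["canonical"].strip(),
            row["organ_system"].strip(),
        )
    return mapping


def normalize_reason(
    raw: str, mapping: dict[str, tuple[str, str]]
) -> tuple[str, str]:
    """Map a free-text withdrawal reason to (canonical label, organ system).

    Exact match after case-folding and trimming; unmapped strings pass
    through tagged ``uncurated``.
    """
    key = raw.strip().casefold()
    if key in mapping:
        return mapping[key]
    return raw, "uncurated"


def summarize_reasons(
    records: Sequence[DrugRecord],
    mapping: dict[str, tuple[str, str]] | None = None,
) -> list[ReasonSummary]:
    """Count withdrawal-reason assignments by organ system.

    A drug may contribute several reasons; fractions are over all reason
    assignments, so they sum to 1.
    """
    if mapping is None:
        mapping = load_reason_map()
    counts: dict[str, int] = {}
    for r in records:
        for reason in r.withdrawal_reasons:
            _, system = normalize_reason(reason, mapping)
            counts[system] = counts.get(system, 0) + 1
    total = sum(counts.values())
    return [
        ReasonSummary(system, n, n / total)
        for system, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def atc_level1(code: str) -> str:
    """Anatomical main group: the uppercase first letter of an ATC code."""
    if not code:
        raise ValueError("empty ATC code")
    return code[0].upper()


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test of a 2x2 table with fixed margins.

    Returns (odds ratio ad/bc, two-sided p). The p-value sums the
    hypergeometric probabilities of every table with the observed margins
    whose probability does not exceed the observed table's; computed in
    exact integer arithmetic over the common denominator C(n, a+c).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be nonnegative")
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero table")
    r1, r2, c1 = a + b, c + d, a + c
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    num_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = 0
    for k in range(lo, hi + 1):
        num_k = math.comb(r1, k) * math.comb(r2, c1 - k)
        if num_k <= num_obs:
            total += num_k
    p = total / math.comb(n, c1)
    return odds, min(p, 1.0)


def enrich_all(
    records: Sequence[DrugRecord],
    alpha: float = ALPHA,
    bonferroni_k: int | None = None,
) -> list[EnrichmentResult]:
    """Fisher-exact enrichment of each observed ATC level-1 group among
    withdrawn versus not-withdrawn drugs.

    Drugs without any ATC code are omitted; a drug with codes in several
    groups counts once in each. ``bonferroni_k`` defaults to 14 (the full
    ATC level-1 standard), giving the conventional 0.05/14 = 0.0036
    threshold; pass the number of observed groups to correct over those
    instead.
    """
    withdrawn, not_withdrawn = [], []
    for r in records:
        if r.label is Label.INVESTIGATIONAL:
            continue
        letters = {atc_level1(code) for code in r.atc_codes if code}
        if not letters:
            log.info("drug %s has no ATC code; omitted from enrichment", r.drug_id)
            continue
        (withdrawn if r.label is Label.WITHDRAWN else not_withdrawn).append(letters)
    if not withdrawn or not not_withdrawn:
        raise ValueError("enrichment needs both withdrawn and not-withdrawn drugs")

    observed = sorted(set().union(*withdrawn, *not_withdrawn))
    k = bonferroni_k if bonferroni_k is not None else len(ATC_LEVEL1_GROUPS)
    threshold = alpha / k
    results = []
    for letter in observed:
        a = sum(letter in s for s in withdrawn)
        c = sum(letter in s for s in not_withdrawn)
        b, d = len(withdrawn) - a, len(not_withdrawn) - c
        odds, p = fisher_exact_2x2(a, b, c, d)
        results.append(
            EnrichmentResult(
                category=letter, a=a, b=b, c=c, d=d,
                odds_ratio=odds, p_value=p,
                significant_raw=p < alpha,
                significant_bonferroni=p < threshold,
            )
        )
    return results


def bonferroni_threshold(alpha: float = ALPHA, k: int = len(ATC_LEVEL1_GROUPS)) -> float:
    """Family-wise corrected significance threshold alpha / k."""
    return alpha / k
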