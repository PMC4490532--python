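"""Summary statistics over cleavage calls.

Category censuses (overall and stratified by the miRNA conservation
class carried as input annotation) use integer round-half-up
percentages, computed in exact integer arithmetic so that stored
percentages always recompute from the counts. Target tallies count
distinct target identifiers per miRNA, not call positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cleavage import CleavageCall

CATEGORIES = (0, 1, 2, 3, 4)
HIGH_CONFIDENCE = (0, 1, 2)


def round_half_up_pct(count: int, total: int) -> int:
    """Integer percentage of count/total, .5 rounded up, exact arithmetic."""
    if total == 0:
        return 0
    return (200 * count + total) // (2 * total)


@dataclass
class CategoryCensus:
    """Per-stratum category counts and integer percentages."""

    stratum: str
    n_sites: int
    n_targets: int = 0  # distinct target ids: the second denominator
    counts: dict[int, int] = field(default_factory=dict)
    percentages: dict[int, int] = field(default_factory=dict)
    high_confidence: int = 0
    high_confidence_pct: int = 0


def _census(stratum: str, categories: Sequence[int], n_targets: int = 0) -> CategoryCensus:
    n = len(categories)
    counts = {c: sum(1 for x in categories if x == c) for c in CATEGORIES}
    high = sum(counts[c] for c in HIGH_CONFIDENCE)
    return CategoryCensus(
        stratum=stratum,
        n_sites=n,
        n_targets=n_targets,
        counts=counts,
        percentages={c: round_half_up_pct(counts[c], n) for c in CATEGORIES} if n else {},
        high_confidence=high,
        high_confidence_pct=round_half_up_pct(high, n),
    )


def category_census(
    calls: Iterable[CleavageCall],
    class_of: Mapping[str, str] | None = None,
) -> list[CategoryCensus]:
    """Census of call categories, overall plus one stratum per class label.

    ``class_of`` maps miRNA ids to conservation labels; calls from
    unmapped miRNAs fall into an 'unlabeled' stratum. The stratified
    censuses partition the 'all' census.
    """
    calls = list(calls)
    out = [
        _census(
            "all",
            [c.category for c in calls],
            n_targets=len({c.transcript_id for c in calls}),
        )
    ]
    if class_of is not None:
        strata: dict[str, list[CleavageCall]] = {}
        for call in calls:
            strata.setdefault(class_of.get(call.mirna_id, "unlabeled"), []).append(call)
        for label in sorted(strata):
            out.append(
                _census(
                    label,
                    [c.category for c in strata[label]],
                    n_targets=len({c.transcript_id for c in strata[label]}),
                )
            )
    return out


def census_from_categories(stratum: str, categories: Sequence[int]) -> CategoryCensus:
    """Census directly from a list of category labels (for external tables)."""
    return _census(stratum, list(categories))


@dataclass(frozen=True)
class MiRNATargetTally:
    mirna_id: str
    mclass: str
    n_targets: int


def targets_per_mirna(
    calls: Iterable[CleavageCall],
    class_of: Mapping[str, str] | None = None,
) -> tuple[list[MiRNATargetTally], dict]:
    """Distinct targets per miRNA plus a min/max summary.

    A transcript called at several positions by one miRNA counts once.
    The summary lists the miRNAs with four or more targets.
    """
    targets: dict[str, set[str]] = {}
    for call in calls:
        targets.setdefault(call.mirna_id, set()).add(call.transcript_id)
    tallies = [
        MiRNATargetTally(
            mirna_id=mid,
            mclass=(class_of or {}).get(mid, "unlabeled"),
            n_targets=len(tids),
        )
        for mid, tids in sorted(targets.items())
    ]
    if tallies:
        ns = [t.n_targets for t in tallies]
        summary = {
            "min_targets": min(ns),
            "max_targets": max(ns),
            "mirnas_with_4_or_more": sorted(
                t.mirna_id for t in tallies if t.n_targets >= 4
            ),
        }
    else:
        summary = {"min_targets": 0, "max_targets": 0, "mirnas_with_4_or_more": []}
    return tallies, summary


def census_frame(censuses: Sequence[CategoryCensus]) -> pd.DataFrame:
    rows = []
    for c in censuses:
        row = {"stratum": c.stratum, "n_sites": c.n_sites, "n_targets": c.n_targets}
        for cat in CATEGORIES:
            row[f"cat{cat}_n"] = c.counts.get(cat, 0)
            row[f"cat{cat}_pct"] = c.percentages.get(cat, 0)
        row["high_confidence_n"] = c.high_confidence
        row["high_confidence_pct"] = c.high_confidence_pct
        rows.append(row)
    return pd.DataFrame(rows)


def tallies_frame(tallies: Sequence[MiRNATargetTally]) -> pd.DataFrame:
    return pd.DataFrame(
        [(t.mirna_id, t.mclass, t.n_targets) for t in tallies],
        columns=["mirna_id", "class", "n_targets"],
    )
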