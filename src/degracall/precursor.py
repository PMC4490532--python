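"""Hairpin precursor analysis.

Degradome tags inside a pre-miRNA reveal its processing: perfectly
matched products map the DCL1 excision coordinates of the mature
strands, while 5'-end signal in the middle of the miRNA/miRNA* region
betrays slicing of the precursor guided by its own mature strand — a
negative feedback loop buffering mature-strand abundance. Jointly with
transcript calls, per-arm call counts identify duplexes in which both
strands (miR and miRNA*) are functional guides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from . import align
from ._seq import MatureMiRNA, family_key
from .cleavage import CleavageCall, call_cleavages
from .preprocess import DegradomeTag
from .profiles import build_profiles, map_tags


@dataclass(frozen=True)
class PrecursorProduct:
    """An exact sequence occurrence inside a hairpin, 1-based inclusive span."""

    precursor_id: str
    query_id: str
    sequence: str
    count: float
    length: int
    span_start: int
    span_end: int


@dataclass(frozen=True)
class FeedbackLoop:
    """A precursor sliced by a mature strand of its own family."""

    precursor_id: str
    cleaving_strand_id: str
    cleavage_position: int
    category: int
    partner_strand_id: str | None = None


@dataclass(frozen=True)
class StarPair:
    """A duplex whose 5p and 3p strands both have cleavage calls."""

    duplex_id: str
    fivep_id: str
    threep_id: str
    fivep_calls: int
    threep_calls: int


def locate_products(
    queries: dict[str, tuple[str, float]],
    precursors: dict[str, str],
) -> list[PrecursorProduct]:
    """Find every exact occurrence of each query inside each precursor.

    ``queries`` maps a query id to (sequence, degradome count); catalog
    miRNAs without tag support carry count 0. Overlapping occurrences
    are all reported.
    """
    products: list[PrecursorProduct] = []
    for pid in sorted(precursors):
        seq = precursors[pid]
        for qid in sorted(queries):
            qseq, count = queries[qid]
            start = 0
            while True:
                i = seq.find(qseq, start)
                if i < 0:
                    break
                products.append(
                    PrecursorProduct(
                        precursor_id=pid,
                        query_id=qid,
                        sequence=qseq,
                        count=count,
                        length=len(qseq),
                        span_start=i + 1,
                        span_end=i + len(qseq),
                    )
                )
                start = i + 1
    return products


def product_queries(
    tags: Sequence[DegradomeTag], catalog: Sequence[MatureMiRNA]
) -> dict[str, tuple[str, float]]:
    """Default query set: observed tags plus catalog mature sequences.

    A catalog strand whose sequence equals an observed tag inherits the
    tag's count; tag-only queries are named by their sequence.
    """
    by_seq = {t.sequence: t.count for t in tags}
    queries: dict[str, tuple[str, float]] = {}
    for m in catalog:
        queries[m.id] = (m.sequence, by_seq.get(m.sequence, 0))
    known = {seq for seq, _ in queries.values()}
    for t in tags:
        if t.sequence not in known:
            queries[t.sequence] = (t.sequence, t.count)
    return queries


def precursor_self_targets(
    catalog: Sequence[MatureMiRNA],
    precursors: dict[str, str],
    tags: Sequence[DegradomeTag],
    max_score: float = align.DEFAULT_MAX_SCORE,
    window: int = 1,
) -> list[CleavageCall]:
    """Run the full target pipeline with precursors as the transcript set."""
    hits, _ = map_tags(tags, precursors)
    profiles = build_profiles(hits)
    alignments = align.scan_catalog(list(catalog), precursors, max_score=max_score)
    return call_cleavages(alignments, profiles, window=window)


def _strand_family(strand_id: str, by_id: dict[str, MatureMiRNA]) -> str:
    m = by_id.get(strand_id)
    return family_key(m.family) if m is not None else family_key(strand_id)


def detect_feedback_loops(
    precursor_calls: Iterable[CleavageCall],
    catalog: Sequence[MatureMiRNA],
    precursor_families: dict[str, str] | None = None,
) -> list[FeedbackLoop]:
    """Flag precursor calls whose cleaving strand comes from that precursor's family.

    ``precursor_families`` optionally maps precursor ids to family
    labels; by default families are derived from the identifiers. When
    both arms of one duplex cleave the same precursor, the two loops
    cross-reference each other through ``partner_strand_id``.
    """
    by_id = {m.id: m for m in catalog}
    loops: list[tuple[CleavageCall, str]] = []
    for call in precursor_calls:
        if precursor_families and call.transcript_id in precursor_families:
            pre_fam = family_key(precursor_families[call.transcript_id])
        else:
            pre_fam = family_key(call.transcript_id)
        strand_fam = _strand_family(call.mirna_id, by_id)
        if strand_fam == pre_fam:
            loops.append((call, strand_fam))

    # Cross-reference arms cleaving the same precursor.
    strands_on = {}
    for call, _ in loops:
        strands_on.setdefault(call.transcript_id, set()).add(call.mirna_id)
    out = []
    for call, _ in loops:
        partners = strands_on[call.transcript_id] - {call.mirna_id}
        out.append(
            FeedbackLoop(
                precursor_id=call.transcript_id,
                cleaving_strand_id=call.mirna_id,
                cleavage_position=call.cleavage_position,
                category=call.category,
                partner_strand_id=sorted(partners)[0] if partners else None,
            )
        )
    return out


def functional_star_pairs(
    all_calls: Iterable[CleavageCall], catalog: Sequence[MatureMiRNA]
) -> list[StarPair]:
    """Duplexes in which both arms have >= 1 call (transcripts and precursors jointly).

    Strands lacking arm annotation are skipped with a warning.
    """
    by_id: dict[str, MatureMiRNA] = {}
    for m in catalog:
        if m.arm not in {"5p", "3p"}:
            warnings.warn(f"strand {m.id} lacks arm annotation; skipped", stacklevel=2)
            continue
        by_id[m.id] = m

    call_counts: dict[str, int] = {}
    for call in all_calls:
        if call.mirna_id in by_id:
            call_counts[call.mirna_id] = call_counts.get(call.mirna_id, 0) + 1

    duplexes: dict[str, dict[str, MatureMiRNA]] = {}
    for m in by_id.values():
        duplexes.setdefault(m.family, {})[m.arm] = m

    pairs = []
    for fam in sorted(duplexes):
        arms = duplexes[fam]
        if "5p" not in arms or "3p" not in arms:
            continue
        n5 = call_counts.get(arms["5p"].id, 0)
        n3 = call_counts.get(arms["3p"].id, 0)
        if n5 >= 1 and n3 >= 1:
            pairs.append(
                StarPair(
                    duplex_id=fam,
                    fivep_id=arms["5p"].id,
                    threep_id=arms["3p"].id,
                    fivep_calls=n5,
                    threep_calls=n3,
                )
            )
    return pairs


def products_frame(products: Sequence[PrecursorProduct]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            (p.precursor_id, p.query_id, p.sequence, p.count, p.length, p.span_start, p.span_end)
            for p in products
        ],
        columns=["precursor_id", "query_id", "sequence", "count", "length", "span_start", "span_end"],
    )
    return df.sort_values(
        ["precursor_id", "span_start", "query_id"], kind="mergesort"
    ).reset_index(drop=True)


def loops_frame(loops: Sequence[FeedbackLoop]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            (l.precursor_id, l.cleaving_strand_id, l.cleavage_position, l.category, l.partner_strand_id or "")
            for l in loops
        ],
        columns=["precursor_id", "cleaving_strand_id", "cleavage_position", "category", "partner_strand_id"],
    )
    return df.sort_values(
        ["precursor_id", "cleaving_strand_id", "cleavage_position"], kind="mergesort"
    ).reset_index(drop=True)


def star_pairs_frame(pairs: Sequence[StarPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.duplex_id, p.fivep_id, p.threep_id, p.fivep_calls, p.threep_calls) for p in pairs],
        columns=["duplex_id", "fivep_id", "threep_id", "fivep_calls", "threep_calls"],
    )
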