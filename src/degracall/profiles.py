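"""Exact sense-strand tag mapping and per-transcript 5'-end profiles.

A degradome tag's 5' end marks the uncapped 5' terminus of a decay
fragment; summed per transcript position, these 5'-end counts form the
signature profile that the category classifier compares against. Only
exact, sense-strand matches are used; a tag matching several loci
contributes its full count at each (a ``fractional`` mode divides by
the locus multiplicity instead).
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Iterable, Sequence

import pandas as pd

from .preprocess import DegradomeTag


@dataclass(frozen=True)
class TagHit:
    """One exact occurrence of a tag on a transcript (1-based 5' position)."""

    tag: str
    transcript_id: str
    position: int
    count: float


@dataclass
class DegradomeProfile:
    """Per-transcript map of 1-based positions to summed 5'-end counts."""

    transcript_id: str
    signature: dict[int, float]

    @property
    def total_signal(self) -> float:
        return sum(self.signature.values())

    @property
    def occupied_positions(self) -> list[int]:
        return sorted(self.signature)


@dataclass(frozen=True)
class ProfileStats:
    """Summary of a profile's occupied positions: the classifier's inputs."""

    max_count: float
    n_max_positions: int
    median_count: float


def _occurrences(tag: str, seq: str) -> list[int]:
    """All (possibly overlapping) 0-based occurrences of ``tag`` in ``seq``."""
    out, start = [], 0
    while True:
        i = seq.find(tag, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def map_tags(
    tags: Sequence[DegradomeTag],
    transcripts: dict[str, str],
    fractional: bool = False,
) -> tuple[list[TagHit], int]:
    """Map tags to transcripts; returns (hits, unannotated read count).

    Every exact sense-strand occurrence is reported. With
    ``fractional=True`` a tag hitting k loci carries count/k per locus
    instead of its full count.
    """
    hits: list[TagHit] = []
    unannotated = 0
    order = sorted(transcripts)
    for tag in tags:
        found: list[tuple[str, int]] = []
        for tid in order:
            for i in _occurrences(tag.sequence, transcripts[tid]):
                found.append((tid, i + 1))
        if not found:
            unannotated += tag.count
            continue
        count = tag.count / len(found) if fractional else tag.count
        for tid, pos in found:
            hits.append(TagHit(tag.sequence, tid, pos, count))
    return hits, unannotated


def build_profiles(hits: Iterable[TagHit]) -> dict[str, DegradomeProfile]:
    """Sum hit counts by (transcript, 5' position)."""
    sigs: dict[str, dict[int, float]] = {}
    for hit in hits:
        sigs.setdefault(hit.transcript_id, {}).setdefault(hit.position, 0)
        sigs[hit.transcript_id][hit.position] += hit.count
    return {
        tid: DegradomeProfile(tid, dict(sorted(sig.items())))
        for tid, sig in sorted(sigs.items())
    }


def profile_stats(profile: DegradomeProfile) -> ProfileStats:
    """Max, number of maxima, and median over occupied positions.

    Positions with no signature are excluded from the median (the
    profile records observed decay ends, not the full transcript).
    Raises ``ValueError`` on an empty profile: no degradome evidence.
    """
    counts = list(profile.signature.values())
    if not counts:
        raise ValueError(f"profile for {profile.transcript_id} has no degradome evidence")
    mx = max(counts)
    return ProfileStats(
        max_count=mx,
        n_max_positions=sum(1 for c in counts if c == mx),
        median_count=median(counts),
    )


def hits_frame(hits: Sequence[TagHit]) -> pd.DataFrame:
    df = pd.DataFrame(
        [(h.tag, h.transcript_id, h.position, h.count) for h in hits],
        columns=["tag", "transcript_id", "position", "count"],
    )
    return df.sort_values(["transcript_id", "position", "tag"], kind="mergesort").reset_index(drop=True)


def profiles_frame(profiles: dict[str, DegradomeProfile]) -> pd.DataFrame:
    rows = [
        (tid, pos, cnt)
        for tid, prof in sorted(profiles.items())
        for pos, cnt in sorted(prof.signature.items())
    ]
    return pd.DataFrame(rows, columns=["transcript_id", "position", "count"])
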