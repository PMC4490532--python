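"""Degradome-supported cleavage calls and category 0-4 classification.

A complementary site becomes a call when the transcript's 5'-end
profile has signal within a small window of the canonical slicing
coordinate. Each supported position is classified by the CleaveLand
convention, comparing its signature count with the transcript-wide
maximum and median over occupied positions:

* category 4 — a single raw read at the position (lowest confidence;
  this test precedes all others, so a lone read that is also the
  transcript maximum still falls here),
* category 0 — the unique transcript maximum, with more than one read,
* category 1 — equal to a maximum attained at several positions,
* category 2 — below the maximum but above the median,
* category 3 — at or below the median.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .align import TargetAlignment
from .profiles import DegradomeProfile, ProfileStats, profile_stats

DEFAULT_WINDOW = 1
EXTENDED_WINDOW = 3


@dataclass(frozen=True)
class CleavageCall:
    """A degradome-supported cleavage site on one alignment.

    ``offset`` is the supporting position minus the canonical slicing
    coordinate; with the default window it is in {-1, 0, 1}.
    """

    alignment: TargetAlignment
    cleavage_position: int
    raw_tags: float
    category: int
    offset: int

    @property
    def mirna_id(self) -> str:
        return self.alignment.mirna_id

    @property
    def transcript_id(self) -> str:
        return self.alignment.transcript_id

    @property
    def score(self) -> float:
        return self.alignment.score


def classify_site(stats: ProfileStats, count_at_site: float) -> int:
    """Category 0-4 of a supported position given the profile summary."""
    if count_at_site < 1:
        raise ValueError("a call needs at least one raw read")
    if count_at_site == 1:
        return 4
    if count_at_site == stats.max_count:
        return 0 if stats.n_max_positions == 1 else 1
    if count_at_site > stats.median_count:
        return 2
    return 3


def call_cleavages(
    alignments: Iterable[TargetAlignment],
    profiles: dict[str, DegradomeProfile],
    window: int = DEFAULT_WINDOW,
) -> list[CleavageCall]:
    """Intersect alignments with profiles.

    For each alignment, every occupied position within ``window`` nt of
    the canonical slicing coordinate yields one independently
    classified call; alignments without support yield nothing.
    """
    if window < 0:
        raise ValueError("window half-width must be >= 0")
    calls: list[CleavageCall] = []
    stats_cache: dict[str, ProfileStats] = {}
    for aln in alignments:
        prof = profiles.get(aln.transcript_id)
        if prof is None:
            continue
        if aln.transcript_id not in stats_cache:
            stats_cache[aln.transcript_id] = profile_stats(prof)
        stats = stats_cache[aln.transcript_id]
        for pos in sorted(prof.signature):
            if abs(pos - aln.canonical_cleavage) <= window:
                count = prof.signature[pos]
                calls.append(
                    CleavageCall(
                        alignment=aln,
                        cleavage_position=pos,
                        raw_tags=count,
                        category=classify_site(stats, count),
                        offset=pos - aln.canonical_cleavage,
                    )
                )
    return calls


def tplot_table(profile: DegradomeProfile, calls: Sequence[CleavageCall]) -> pd.DataFrame:
    """t-plot data: one row per occupied position, call sites flagged."""
    if not profile.signature:
        raise ValueError("cannot build a t-plot for an empty profile")
    call_positions = {
        c.cleavage_position for c in calls if c.transcript_id == profile.transcript_id
    }
    rows = [
        (pos, cnt, pos in call_positions)
        for pos, cnt in sorted(profile.signature.items())
    ]
    return pd.DataFrame(rows, columns=["position", "count", "is_call_site"])


def tplot_figure(
    profile: DegradomeProfile, calls: Sequence[CleavageCall], path: str | Path
) -> None:
    """Render the t-plot: signature abundance vs position, calls as red dots."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = tplot_table(profile, calls)
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.vlines(table["position"], 0, table["count"], color="0.6", linewidth=1)
    hit = table[table["is_call_site"]]
    ax.plot(hit["position"], hit["count"], "o", color="red", markersize=5, zorder=3)
    ax.set_xlabel(f"position on {profile.transcript_id} (nt)")
    ax.set_ylabel("degradome signature (reads)")
    fig.tight_layout()
    fig.savefig(str(path))
    plt.close(fig)


def calls_frame(calls: Sequence[CleavageCall]) -> pd.DataFrame:
    """Tabular calls with the columns of a degradome target table."""
    rows = [
        (
            c.mirna_id,
            c.transcript_id,
            c.cleavage_position,
            c.category,
            c.raw_tags,
            c.score,
            c.offset,
        )
        for c in calls
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "mirna_id",
            "target_id",
            "cleavage_position",
            "category",
            "raw_tags",
            "score",
            "offset",
        ],
    )
    return df.sort_values(
        ["mirna_id", "target_id", "cleavage_position"], kind="mergesort"
    ).reset_index(drop=True)
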