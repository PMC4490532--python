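"""Raw degradome reads -> collapsed, filtered unique tags with counts.

The quality rules are length- and composition-based only: tags shorter
than 18 nt, tags containing ambiguous bases, and reads without a
recognizable 3' adapter are discarded; tags matching the ncRNA
contaminant set (rRNA/tRNA/sn(o)RNA stand-ins) are removed by exact
substring membership. PARE tags are 5'-defined, so trimming never
touches the 5' end.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._seq import VALID_BASES, iter_reads, normalize

DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 24
DEFAULT_MIN_OVERLAP = 5

NO_ADAPTER = "no_adapter"
TOO_SHORT = "too_short"
TOO_LONG = "too_long"
AMBIGUOUS = "ambiguous"
HOMOPOLYMER = "homopolymer"


@dataclass(frozen=True)
class DegradomeTag:
    """A collapsed unique tag: sequence plus the raw reads behind it."""

    sequence: str
    count: int


@dataclass
class LibraryStats:
    """Per-library accounting.

    ``raw_reads = retained_reads + sum(rejected.values()) + ncrna_removed``
    always holds; ``length_histogram`` maps tag length to (reads,
    fraction of retained reads). ``unannotated`` is filled by the
    mapping stage (reads whose tag matches no transcript).
    """

    raw_reads: int = 0
    retained_reads: int = 0
    retained_fraction: float = 0.0
    unique_tags: int = 0
    length_histogram: dict[int, tuple[int, float]] = field(default_factory=dict)
    ncrna_removed: int = 0
    unannotated: int = 0
    rejected: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "raw_reads": self.raw_reads,
            "retained_reads": self.retained_reads,
            "retained_fraction": self.retained_fraction,
            "unique_tags": self.unique_tags,
            "length_histogram": {
                str(k): {"reads": c, "fraction": f}
                for k, (c, f) in sorted(self.length_histogram.items())
            },
            "ncrna_removed": self.ncrna_removed,
            "unannotated": self.unannotated,
            "rejected": dict(self.rejected),
        }


def trim_adapter(read: str, adapter: str, min_overlap: int = DEFAULT_MIN_OVERLAP) -> str | None:
    """Return the tag preceding the 3' adapter, or None if no adapter is found.

    The tag is the read prefix before the leftmost occurrence of the
    full adapter; failing that, before an adapter prefix of at least
    ``min_overlap`` nt flush with the read 3' end (the adapter ran off
    the sequenced length). The 5' end of the read is never altered.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    read = normalize(read)
    adapter = normalize(adapter)
    idx = read.find(adapter)
    if idx >= 0:
        return read[:idx]
    max_k = min(len(adapter) - 1, len(read))
    for k in range(max_k, min_overlap - 1, -1):
        if read.endswith(adapter[:k]):
            return read[: len(read) - k]
    return None


def tag_rejection_reason(
    seq: str,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int | None = DEFAULT_MAX_LEN,
    max_homopolymer_frac: float | None = None,
) -> str | None:
    """Why a trimmed tag fails quality filtering, or None if it passes.

    ``max_homopolymer_frac`` optionally rejects low-complexity tags in
    which any single base exceeds that fraction (an extension beyond
    the composition rules; off by default).
    """
    if len(seq) < min_len:
        return TOO_SHORT
    if max_len is not None and len(seq) > max_len:
        return TOO_LONG
    if any(b not in VALID_BASES for b in seq):
        return AMBIGUOUS
    if max_homopolymer_frac is not None and seq:
        if max(seq.count(b) for b in "ACGT") / len(seq) >= max_homopolymer_frac:
            return HOMOPOLYMER
    return None


def filter_tags(
    tags: Iterable[DegradomeTag],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int | None = DEFAULT_MAX_LEN,
) -> tuple[list[DegradomeTag], dict[str, int]]:
    """Partition tags into kept and per-reason rejection tallies (in reads)."""
    kept: list[DegradomeTag] = []
    tallies: Counter[str] = Counter()
    for tag in tags:
        reason = tag_rejection_reason(tag.sequence, min_len, max_len)
        if reason is None:
            kept.append(tag)
        else:
            tallies[reason] += tag.count
    return kept, dict(tallies)


def remove_ncrna(
    tags: Sequence[DegradomeTag], ncrna: dict[str, str] | Iterable[str]
) -> tuple[list[DegradomeTag], int]:
    """Drop tags occurring as exact substrings of any ncRNA sequence.

    Returns the kept tags and the number of removed reads. An empty
    ncRNA set is the identity transform.
    """
    seqs = list(ncrna.values()) if isinstance(ncrna, dict) else [normalize(s) for s in ncrna]
    kept, removed = [], 0
    for tag in tags:
        if any(tag.sequence in s for s in seqs):
            removed += tag.count
        else:
            kept.append(tag)
    return kept, removed


def collapse_tags(sequences: Iterable[str]) -> list[DegradomeTag]:
    """Merge identical sequences into unique tags with summed counts.

    Output is sorted by descending count then sequence, for stable files.
    """
    counts = Counter(sequences)
    return [
        DegradomeTag(seq, n)
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def _histogram(tags: Sequence[DegradomeTag]) -> dict[int, tuple[int, float]]:
    by_len: Counter[int] = Counter()
    for tag in tags:
        by_len[len(tag.sequence)] += tag.count
    total = sum(by_len.values())
    return {k: (c, c / total if total else 0.0) for k, c in sorted(by_len.items())}


def preprocess_reads(
    reads: Iterable[str],
    adapter: str,
    ncrna: dict[str, str] | Iterable[str] = (),
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int | None = DEFAULT_MAX_LEN,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    clip5: int = 0,
    max_homopolymer_frac: float | None = None,
) -> tuple[list[DegradomeTag], LibraryStats]:
    """Full preprocessing: trim -> quality filter -> collapse -> ncRNA removal.

    ``clip5`` removes a fixed-length 5' adapter before the 3' adapter
    search (use only when the 5' adapter was not stripped upstream:
    the trimmed tag's first base is the degradome 5' end).
    """
    raw = 0
    tallies: Counter[str] = Counter()
    clean: list[str] = []
    for read in reads:
        raw += 1
        if clip5:
            read = read[clip5:]
        tag = trim_adapter(read, adapter, min_overlap)
        if tag is None:
            tallies[NO_ADAPTER] += 1
            continue
        reason = tag_rejection_reason(tag, min_len, max_len, max_homopolymer_frac)
        if reason is not None:
            tallies[reason] += 1
            continue
        clean.append(tag)
    tags = collapse_tags(clean)
    tags, ncrna_removed = remove_ncrna(tags, ncrna)
    retained = sum(t.count for t in tags)
    stats = LibraryStats(
        raw_reads=raw,
        retained_reads=retained,
        retained_fraction=retained / raw if raw else 0.0,
        unique_tags=len(tags),
        length_histogram=_histogram(tags),
        ncrna_removed=ncrna_removed,
        rejected=dict(tallies),
    )
    return tags, stats


def preprocess_file(
    reads_path: str | Path,
    adapter: str,
    ncrna: dict[str, str] | Iterable[str] = (),
    **kwargs,
) -> tuple[list[DegradomeTag], LibraryStats]:
    return preprocess_reads(iter_reads(reads_path), adapter, ncrna, **kwargs)


def write_tags(tags: Sequence[DegradomeTag], path: str | Path) -> None:
    pd.DataFrame(
        [(t.sequence, t.count) for t in tags], columns=["sequence", "count"]
    ).to_csv(path, sep="\t", index=False)


def read_tags(path: str | Path) -> list[DegradomeTag]:
    df = pd.read_csv(path, sep="\t")
    return [DegradomeTag(normalize(s), int(c)) for s, c in zip(df["sequence"], df["count"])]
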