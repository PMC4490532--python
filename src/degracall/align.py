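"""Plant-style miRNA:target alignment with a penalty score.

Plant miRNAs pair with their target transcripts almost end-to-end, and
RISC slices the target between the nucleotides opposite miRNA positions
10 and 11 (counted from the miRNA 5' end). Candidate sites are scored
with the widely used plant penalty scheme: Watson-Crick pair 0, G:U
wobble 0.5, mismatch 1.0, with penalties doubled over the functionally
critical miRNA positions 2-13. Alignments are ungapped and antiparallel:
miRNA position i pairs with transcript position ``site_start + L - i``
for a site occupying ``[site_start, site_start + L - 1]`` (1-based,
inclusive), so the canonical slicing coordinate — the transcript base
paired to miRNA nt 10 — is ``site_start + L - 10``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import MatureMiRNA, complement, normalize

MATCH, GU, MISMATCH = "match", "gu", "mismatch"

#: miRNA positions (1-based, 5'->3') over which penalties are doubled.
CORE_START, CORE_END = 2, 13

#: Default maximum penalty for a reported site.
DEFAULT_MAX_SCORE = 4.5

_PAIR_CHAR = {MATCH: "|", GU: "o", MISMATCH: "."}

# G:U wobble partners, DNA alphabet: miRNA G pairs target U (=T), miRNA U (=T) pairs target G.
_GU_PARTNER = {"G": "T", "T": "G"}


def pair_state(mirna_base: str, transcript_base: str) -> str:
    """Classify one antiparallel base pair.

    Ambiguous transcript bases (anything outside ACGT) never pair and
    are classified as mismatches.
    """
    if transcript_base == complement(mirna_base) and transcript_base in "ACGT":
        return MATCH
    if _GU_PARTNER.get(mirna_base) == transcript_base:
        return GU
    return MISMATCH


def position_penalty(state: str, mirna_position: int) -> float:
    """Penalty of one pairing state at a 1-based miRNA position."""
    if state == MATCH:
        base = 0.0
    elif state == GU:
        base = 0.5
    elif state == MISMATCH:
        base = 1.0
    else:
        raise ValueError(f"unknown pairing state: {state!r}")
    if mirna_position < 1:
        raise ValueError(f"miRNA position must be >= 1, got {mirna_position}")
    return base * 2 if CORE_START <= mirna_position <= CORE_END else base


@dataclass(frozen=True)
class TargetAlignment:
    """An ungapped antiparallel miRNA:transcript pairing.

    ``pairing[i-1]`` is the state opposite miRNA position i; coordinates
    are 1-based inclusive on the transcript.
    """

    mirna_id: str
    transcript_id: str
    site_start: int
    site_end: int
    pairing: tuple[str, ...]
    score: float
    canonical_cleavage: int

    @property
    def pairing_string(self) -> str:
        """Textual pairing, 5'->3' on the miRNA: '|' match, 'o' G:U, '.' mismatch."""
        return "".join(_PAIR_CHAR[s] for s in self.pairing)


def score_site(
    mirna: str | MatureMiRNA,
    transcript: str,
    site_start: int,
    mirna_id: str = "",
    transcript_id: str = "",
) -> TargetAlignment:
    """Score the miRNA against the transcript window starting at ``site_start``.

    Raises ``ValueError`` if the window does not lie fully inside the
    transcript.
    """
    if isinstance(mirna, MatureMiRNA):
        mirna_id = mirna_id or mirna.id
        mirna = mirna.sequence
    mirna = normalize(mirna)
    L = len(mirna)
    if site_start < 1 or site_start + L - 1 > len(transcript):
        raise ValueError(
            f"site [{site_start}, {site_start + L - 1}] outside transcript of length {len(transcript)}"
        )
    states = []
    score = 0.0
    for i in range(1, L + 1):
        tbase = transcript[site_start + L - i - 1]  # antiparallel partner, 0-based index
        state = pair_state(mirna[i - 1], tbase)
        states.append(state)
        score += position_penalty(state, i)
    return TargetAlignment(
        mirna_id=mirna_id,
        transcript_id=transcript_id,
        site_start=site_start,
        site_end=site_start + L - 1,
        pairing=tuple(states),
        score=score,
        canonical_cleavage=site_start + L - 10,
    )


def _window_scores(mirna: str, transcript: str) -> np.ndarray:
    """Penalty score of every window of the transcript (vectorized).

    Entry k is the score of the site starting at 1-based position k+1.
    """
    L = len(mirna)
    t = np.frombuffer(transcript.encode("ascii"), dtype=np.uint8)
    if t.size < L:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(t, L)
    # Window column j pairs miRNA position L - j.
    mir_col = np.frombuffer(mirna[::-1].encode("ascii"), dtype=np.uint8)
    comp_col = np.frombuffer(
        "".join(complement(c) for c in mirna[::-1]).encode("ascii"), dtype=np.uint8
    )
    gu_col = np.frombuffer(
        "".join(_GU_PARTNER.get(c, "\0") for c in mirna[::-1]).encode("ascii"),
        dtype=np.uint8,
    )
    pen = np.full(win.shape, 1.0)
    pen[win == gu_col] = 0.5
    pen[win == comp_col] = 0.0
    pos = L - np.arange(L)  # miRNA position per column
    weights = np.where((pos >= CORE_START) & (pos <= CORE_END), 2.0, 1.0)
    return pen @ weights


def scan_targets(
    mirna: str | MatureMiRNA,
    transcripts: dict[str, str],
    max_score: float = DEFAULT_MAX_SCORE,
    mirna_id: str = "",
) -> list[TargetAlignment]:
    """Report every transcript window whose penalty score is <= ``max_score``.

    All offsets of all transcripts are examined; hits are ordered by
    (transcript_id, site_start).
    """
    if max_score < 0:
        raise ValueError("max_score must be >= 0")
    if isinstance(mirna, MatureMiRNA):
        mirna_id = mirna_id or mirna.id
        mirna = mirna.sequence
    mirna = normalize(mirna)
    hits = []
    for tid in sorted(transcripts):
        seq = transcripts[tid]
        scores = _window_scores(mirna, seq)
        for k in np.flatnonzero(scores <= max_score + 1e-9):
            aln = score_site(mirna, seq, int(k) + 1, mirna_id=mirna_id, transcript_id=tid)
            hits.append(aln)
    return hits


def scan_catalog(
    catalog: list[MatureMiRNA],
    transcripts: dict[str, str],
    max_score: float = DEFAULT_MAX_SCORE,
) -> list[TargetAlignment]:
    """Scan every strand of a mature-miRNA catalog against a transcript set."""
    out = []
    for mir in catalog:
        out.extend(scan_targets(mir, transcripts, max_score=max_score))
    return out
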