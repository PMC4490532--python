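"""Sequence utilities and FASTA/FASTQ I/O shared across the package.

All internal sequence space is DNA-alphabet: RNA inputs (mature miRNA
catalogs are usually given as RNA) are normalized U->T on the way in.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGT")


def normalize(seq: str) -> str:
    """Uppercase and convert RNA (U) to DNA (T)."""
    return seq.upper().replace("U", "T")


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a FASTA file into (id, description, sequence) triples.

    Sequences are normalized to the DNA alphabet.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, rec.description, normalize(str(rec.seq))))
    return out


def write_fasta(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    """Write (id, description, sequence) triples as FASTA."""
    seqrecs = []
    for rid, desc, seq in records:
        # SeqIO emits ">id description"; keep description free of the id.
        seqrecs.append(SeqRecord(Seq(seq), id=rid, description=desc))
    SeqIO.write(seqrecs, str(path), "fasta")


def iter_reads(path: str | Path) -> Iterator[str]:
    """Yield raw read sequences from a FASTA or FASTQ file.

    Format is chosen from the file extension (.fastq/.fq -> FASTQ,
    anything else -> FASTA). Sequences are normalized but otherwise
    untouched: adapter trimming and filtering happen downstream.
    """
    p = Path(path)
    fmt = "fastq" if p.suffix.lower() in {".fastq", ".fq"} else "fasta"
    for rec in SeqIO.parse(str(p), fmt):
        yield normalize(str(rec.seq))


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path, quality: str = "I") -> None:
    """Write (read_id, sequence) pairs as FASTQ with a uniform quality string."""
    recs = []
    for rid, seq in reads:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [ord(quality) - 33] * len(seq)
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


# ---------------------------------------------------------------------------
# miRNA catalog records

@dataclass(frozen=True)
class MatureMiRNA:
    """A mature small-RNA strand with its duplex annotation.

    ``arm`` is '5p' or '3p' (placement on the hairpin); ``family`` groups
    the two strands of one duplex (and the hairpin they come from);
    ``mclass`` is the conservation label carried as input annotation
    (conserved / non-conserved / novel); ``guide`` marks the strand
    annotated as the dominant (miR) strand, the other being the star.
    """

    id: str
    sequence: str
    arm: str | None
    family: str
    mclass: str
    guide: bool = True


_ARM_SUFFIX = re.compile(r"[-_.](5p|3p)$", re.IGNORECASE)


def family_key(name: str) -> str:
    """Collapse a miRNA/precursor identifier to its family key.

    Strips arm suffixes and precursor prefixes, then keeps the
    ``mir<letters><digits>`` stem: pto-miR475a-3p, pto-MIR475b and
    Precur-MIR475a all map to 'mir475'; novel names like pto-miRS11
    map to 'mirs11'.
    """
    s = name.lower()
    s = _ARM_SUFFIX.sub("", s)
    for pre in ("precursor-", "precur-", "pre-"):
        if s.startswith(pre):
            s = s[len(pre):]
            break
    m = re.search(r"mir[a-z]*?\d+", s)
    return m.group(0) if m else s


def _parse_attrs(description: str) -> dict[str, str]:
    return dict(m.groups() for m in re.finditer(r"(\w+)=(\S+)", description))


def parse_mirna_fasta(path: str | Path) -> list[MatureMiRNA]:
    """Load a mature miRNA catalog.

    Headers follow ``>name|5p family=... class=... guide=0/1``; every
    field except the name is optional. Arm falls back to a -5p/-3p name
    suffix, family to :func:`family_key`, class to 'unlabeled', guide
    to true.
    """
    out = []
    for rid, desc, seq in read_fasta(path):
        attrs = _parse_attrs(desc)
        name, arm = rid, None
        if "|" in rid:
            name, tail = rid.split("|", 1)
            if tail.lower() in {"5p", "3p"}:
                arm = tail.lower()
        if arm is None:
            m = _ARM_SUFFIX.search(name)
            arm = m.group(1).lower() if m else attrs.get("arm")
        out.append(
            MatureMiRNA(
                id=name,
                sequence=seq,
                arm=arm,
                family=attrs.get("family", family_key(name)),
                mclass=attrs.get("class", "unlabeled"),
                guide=attrs.get("guide", "1") != "0",
            )
        )
    return out
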