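"""Synthetic degradome study generator with known ground truth.

Emulates the composition of a plant degradome (PARE) library: a
transcript set carrying planted miRNA complementary sites, a mature
miRNA catalog with 5p/3p duplex strands excised from stem-loop hairpin
precursors, an ncRNA contaminant set, and a raw read library in which

* each planted site contributes reads whose 5' ends sit exactly at the
  canonical slicing coordinate (opposite miRNA nt 10), with Poisson (or
  negative-binomial) counts,
* random decay background contributes single reads with uniform 5' ends,
* contaminant reads are drawn from the ncRNA set,
* hairpins shed both their processed mature strands and, for designated
  self-targeting hairpins, slicing products guided by their own miR
  strand (the substrate of feedback-loop detection),
* tag lengths follow an 18-24 nt distribution dominated by 20- and
  21-mers, every read carries a 3' adapter, and a small configurable
  fraction of reads is corrupted (too short after trimming, ambiguous
  base, or missing adapter) to exercise the quality filters.

Everything is driven by one :class:`SimConfig`; a fixed seed gives
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import align
from ._seq import MatureMiRNA, complement, revcomp, write_fasta, write_fastq

BASES = "ACGT"

# Paper-style tag length distribution: 20-mers and 21-mers dominate.
DEFAULT_TAG_LENGTH_WEIGHTS = {
    18: 0.004, 19: 0.004, 20: 0.5961, 21: 0.3837, 22: 0.004, 23: 0.004, 24: 0.0082,
}

#: Illumina TruSeq small-RNA 3' adapter (a free protocol choice).
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass
class SimConfig:
    """Study conditions for one simulated degradome experiment.

    Defaults describe a desk-scale library: 50 transcripts of 500-2000
    nt, 10 miRNA duplexes with 3 planted guide sites each at a mean
    signal of 20 reads, uniform decay background of 0.005 expected 5'
    ends per position, 5 duplexes whose star strand is also functional,
    5 hairpins carrying self-directed slicing signal, and 6 extra sites
    planted with exactly one supporting read.
    """

    seed: int = 0
    n_transcripts: int = 50
    transcript_length_range: tuple[int, int] = (500, 2000)
    n_mirna_families: int = 10
    mirna_length: int = 21
    sites_per_mirna: int = 3
    signal_mean: float = 20.0
    background_rate: float = 0.005
    contaminant_fraction: float = 0.25
    adapter: str = DEFAULT_ADAPTER
    tag_length_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_TAG_LENGTH_WEIGHTS)
    )
    corrupt_fraction: float = 0.0064
    # Duplex / hairpin geometry
    star_edit_range: tuple[int, int] = (1, 3)
    loop_length_range: tuple[int, int] = (8, 20)
    n_dual_duplexes: int = 5
    n_self_target_hairpins: int = 5
    dual_star_sites: int = 1
    single_read_sites: int = 6
    product_signal_mean: float = 5.0
    # Contaminant set
    n_ncrna: int = 5
    ncrna_length_range: tuple[int, int] = (150, 1500)
    # Count model: Poisson by default; dispersion > 0 switches the signal
    # draw to a negative binomial with that size parameter.
    nb_dispersion: float = 0.0
    read_format: str = "fastq"

    def validate(self) -> None:
        if self.n_transcripts < 0 or self.n_mirna_families < 0:
            raise ValueError("counts must be non-negative")
        lo, hi = self.transcript_length_range
        if lo > hi or lo <= 0:
            raise ValueError(f"degenerate transcript length range ({lo}, {hi})")
        if not 18 <= self.mirna_length <= 24:
            raise ValueError("mirna_length must lie in [18, 24]")
        for rate in (self.signal_mean, self.background_rate, self.product_signal_mean):
            if rate < 0 or not np.isfinite(rate):
                raise ValueError("rates must be finite and >= 0")
        if not 0 <= self.contaminant_fraction < 1:
            raise ValueError("contaminant_fraction must lie in [0, 1)")
        if not 0 <= self.corrupt_fraction <= 1:
            raise ValueError("corrupt_fraction must lie in [0, 1]")
        if not self.adapter:
            raise ValueError("adapter must be non-empty")
        if self.read_format not in {"fastq", "fasta"}:
            raise ValueError("read_format must be 'fastq' or 'fasta'")


@dataclass(frozen=True)
class GroundTruthSite:
    """A planted miRNA complementary site with its drawn read support."""

    mirna_id: str
    transcript_id: str
    site_start: int
    canonical_cleavage: int
    planted_score: float
    planted_signal: int
    forced_single: bool = False


@dataclass(frozen=True)
class Hairpin:
    """A stem-loop precursor with 1-based inclusive arm coordinates."""

    id: str
    sequence: str
    family: str
    arm5_id: str
    arm5_start: int
    arm5_end: int
    arm3_id: str
    arm3_start: int
    arm3_end: int
    guide_arm: str  # '5p' or '3p'
    self_target: bool = False

    @property
    def guide_id(self) -> str:
        return self.arm5_id if self.guide_arm == "5p" else self.arm3_id

    def star_span(self) -> tuple[int, int]:
        """Span of the star arm (the window the guide strand pairs with)."""
        if self.guide_arm == "5p":
            return self.arm3_start, self.arm3_end
        return self.arm5_start, self.arm5_end


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def generate_transcriptome(config: SimConfig, rng: np.random.Generator | None = None) -> dict[str, str]:
    """Random-composition transcripts with unique identifiers."""
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = config.transcript_length_range
    out: dict[str, str] = {}
    for i in range(config.n_transcripts):
        length = int(rng.integers(lo, hi + 1))
        out[f"tx{i + 1:04d}"] = _random_seq(rng, length)
    return out


def generate_ncrna(config: SimConfig, rng: np.random.Generator | None = None) -> dict[str, str]:
    """Random stand-ins for the rRNA/tRNA/sn(o)RNA contaminant set."""
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = config.ncrna_length_range
    return {
        f"ncrna{i + 1:03d}": _random_seq(rng, int(rng.integers(lo, hi + 1)))
        for i in range(config.n_ncrna)
    }


def _mismatch_base(rng: np.random.Generator, mirna_base: str) -> str:
    """A transcript base that pairs as a mismatch opposite ``mirna_base``."""
    options = [b for b in BASES if align.pair_state(mirna_base, b) == align.MISMATCH]
    return str(rng.choice(options))


def _draw_edits(
    rng: np.random.Generator, mirna_seq: str, n_edits: int, max_score: float
) -> list[tuple[int, str]]:
    """Draw a per-position edit list (miRNA position, state) with bounded score.

    At most two edits fall inside the doubled 2-13 core, so a worst case
    of two core mismatches plus one peripheral mismatch stays at 5.0;
    redraws additionally enforce the requested score bound.
    """
    L = len(mirna_seq)
    for _ in range(200):
        positions = rng.choice(np.arange(1, L + 1), size=n_edits, replace=False)
        edits = []
        for p in sorted(int(x) for x in positions):
            can_gu = mirna_seq[p - 1] in "GT"
            state = align.GU if can_gu and rng.random() < 0.5 else align.MISMATCH
            edits.append((p, state))
        score = sum(align.position_penalty(s, p) for p, s in edits)
        n_core = sum(1 for p, _ in edits if align.CORE_START <= p <= align.CORE_END)
        if score <= max_score and n_core <= 2:
            return edits
    raise RuntimeError("could not draw an edit list within the score bound")


def edited_complement(
    rng: np.random.Generator, mirna_seq: str, edits: list[tuple[int, str]]
) -> str:
    """The target-side window (5'->3') complementary to ``mirna_seq`` under ``edits``.

    With an empty edit list this is the exact reverse complement; a
    ('gu', p) edit replaces the partner of miRNA position p with its
    wobble base, a ('mismatch', p) edit with a random non-pairing base.
    """
    window = list(revcomp(mirna_seq))
    L = len(mirna_seq)
    for p, state in edits:
        m = mirna_seq[p - 1]
        if state == align.GU:
            if m not in "GT":
                raise ValueError(f"G:U edit at miRNA position {p} needs a G or U base")
            window[L - p] = "G" if m == "T" else "T"
        elif state == align.MISMATCH:
            window[L - p] = _mismatch_base(rng, m)
        else:
            raise ValueError(f"unknown edit state {state!r}")
    return "".join(window)


def generate_hairpins(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[MatureMiRNA], list[Hairpin]]:
    """Build miRNA duplexes and the hairpins that excise them.

    Each hairpin is 5' flank + 5p arm + loop + 3p arm + 3' flank, the
    star arm being the reverse complement of the miR arm with 1-3
    planted mismatch/G:U positions (so the folded stem pairs). Arm
    coordinates are recorded 1-based inclusive; -5p/-3p suffixes follow
    arm placement. Conservation classes are assigned round-robin
    (conserved / non-conserved / novel) as input annotation.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    classes = ["conserved", "non-conserved", "novel"]
    catalog: list[MatureMiRNA] = []
    hairpins: list[Hairpin] = []
    L = config.mirna_length
    for i in range(config.n_mirna_families):
        fam = f"syn-mir{i + 1}"
        mclass = classes[i % 3]
        guide_seq = _random_seq(rng, L)
        lo, hi = config.star_edit_range
        n_edits = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
        edits = _draw_edits(rng, guide_seq, n_edits, max_score=4.5) if n_edits else []
        star_arm = edited_complement(rng, guide_seq, edits)
        guide_arm_side = "5p" if rng.random() < 0.5 else "3p"
        # Hairpin sequence order is 5p arm then 3p arm; the star arm string
        # pairs with the guide regardless of which side carries the guide.
        arm5_seq, arm3_seq = (
            (guide_seq, star_arm) if guide_arm_side == "5p" else (star_arm, guide_seq)
        )
        flank5 = _random_seq(rng, int(rng.integers(5, 31)))
        loop = _random_seq(rng, int(rng.integers(*config.loop_length_range)))
        # 3' flank of >= 15 nt so tags starting at the mid-star slicing
        # position (star_start + L - 10) fit up to 24 nt inside the hairpin.
        flank3 = _random_seq(rng, int(rng.integers(15, 31)))
        seq = flank5 + arm5_seq + loop + arm3_seq + flank3
        a5s = len(flank5) + 1
        a5e = a5s + L - 1
        a3s = a5e + len(loop) + 1
        a3e = a3s + L - 1
        hp_id = f"syn-MIR{i + 1}"
        id5, id3 = f"syn-miR{i + 1}-5p", f"syn-miR{i + 1}-3p"
        dual = i < config.n_dual_duplexes
        for arm, mid, mseq in (("5p", id5, arm5_seq), ("3p", id3, arm3_seq)):
            catalog.append(
                MatureMiRNA(
                    id=mid,
                    sequence=mseq,
                    arm=arm,
                    family=fam,
                    mclass=mclass,
                    guide=(arm == guide_arm_side),
                )
            )
        hairpins.append(
            Hairpin(
                id=hp_id,
                sequence=seq,
                family=fam,
                arm5_id=id5,
                arm5_start=a5s,
                arm5_end=a5e,
                arm3_id=id3,
                arm3_start=a3s,
                arm3_end=a3e,
                guide_arm=guide_arm_side,
                self_target=i < config.n_self_target_hairpins,
            )
        )
        _ = dual  # dual-functionality is resolved at site-planting time
    return catalog, hairpins


def plant_site(
    transcript_seq: str,
    mirna_seq: str,
    site_start: int,
    edits: list[tuple[int, str]],
    rng: np.random.Generator,
) -> tuple[str, float]:
    """Write a complementary site into a transcript; return (sequence, score).

    ``edits`` lists (miRNA position, state) deviations from perfect
    complementarity. The returned score is computed by re-scoring the
    planted window with :func:`align.score_site`, so it is consistent
    with the caller's scoring by construction.
    """
    L = len(mirna_seq)
    if site_start < 1 or site_start + L - 1 > len(transcript_seq):
        raise ValueError(
            f"site at {site_start} overlaps the boundary of a transcript of "
            f"length {len(transcript_seq)}"
        )
    window = edited_complement(rng, mirna_seq, edits)
    new_seq = transcript_seq[: site_start - 1] + window + transcript_seq[site_start - 1 + L:]
    aln = align.score_site(mirna_seq, new_seq, site_start)
    return new_seq, aln.score


def plant_target_sites(
    transcripts: dict[str, str],
    catalog: list[MatureMiRNA],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], list[GroundTruthSite]]:
    """Plant complementary sites and record ground truth.

    Guides receive ``sites_per_mirna`` sites each; star strands of the
    first ``n_dual_duplexes`` duplexes receive ``dual_star_sites`` sites
    (making those duplexes dual-functional); ``single_read_sites`` extra
    guide sites are planted with their read support forced to one.
    Transcripts are used without replacement while any remain unplanted,
    so sites interfere as little as the budget allows. ``planted_signal``
    is left at 0 here and drawn by :func:`simulate_reads`.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    transcripts = dict(transcripts)
    guides = [m for m in catalog if m.guide]
    dual_families = {f"syn-mir{i + 1}" for i in range(config.n_dual_duplexes)}
    stars = [m for m in catalog if not m.guide and m.family in dual_families]

    jobs: list[tuple[MatureMiRNA, bool]] = []
    for m in guides:
        jobs.extend((m, False) for _ in range(config.sites_per_mirna))
    for m in stars:
        jobs.extend((m, False) for _ in range(config.dual_star_sites))
    for k in range(config.single_read_sites):
        if guides:
            jobs.append((guides[k % len(guides)], True))

    order = list(transcripts)
    rng.shuffle(order)
    pool = list(order)
    occupied: dict[str, list[tuple[int, int]]] = {tid: [] for tid in transcripts}
    truth: list[GroundTruthSite] = []
    L = config.mirna_length
    max_tag = max(config.tag_length_weights)
    for mir, forced in jobs:
        if not pool:
            pool = list(order)
        tid = pool.pop(0)
        seq = transcripts[tid]
        # Leave room for the longest tag downstream of the slicing position.
        upper = len(seq) - L - (max_tag - 10)
        if upper < 1:
            raise ValueError(f"transcript {tid} too short to host a site")
        for _ in range(100):
            s = int(rng.integers(1, upper + 1))
            if all(not (s <= e and s + L - 1 >= b) for b, e in occupied[tid]):
                break
        else:
            continue  # no free window; drop this site
        n_edits = int(rng.integers(0, 4))
        edits = _draw_edits(rng, mir.sequence, n_edits, max_score=4.5) if n_edits else []
        new_seq, score = plant_site(seq, mir.sequence, s, edits, rng)
        transcripts[tid] = new_seq
        occupied[tid].append((s, s + L - 1))
        truth.append(
            GroundTruthSite(
                mirna_id=mir.id,
                transcript_id=tid,
                site_start=s,
                canonical_cleavage=s + L - 10,
                planted_score=score,
                planted_signal=0,
                forced_single=forced,
            )
        )
    return transcripts, truth


def _draw_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean == 0:
        return 0
    if dispersion > 0:
        p = dispersion / (dispersion + mean)
        return int(rng.negative_binomial(dispersion, p))
    return int(rng.poisson(mean))


def _draw_tag_length(rng: np.random.Generator, weights: dict[int, float]) -> int:
    lengths = sorted(weights)
    w = np.array([weights[k] for k in lengths], dtype=float)
    return int(rng.choice(lengths, p=w / w.sum()))


def simulate_reads(
    transcripts: dict[str, str],
    truth: list[GroundTruthSite],
    hairpins: list[Hairpin],
    ncrna: dict[str, str],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str]], list[GroundTruthSite], pd.DataFrame]:
    """Emit the raw read library; returns (reads, truth with signals, hairpin truth).

    Reads are (id, sequence) pairs with the 3' adapter appended (except
    for adapter-dropping corruptions). The returned truth list has
    ``planted_signal`` filled with the realized draw; the hairpin table
    records per-hairpin self-target positions and signals.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    reads: list[tuple[str, str]] = []
    counter = 0

    def emit(seq_source: str, pos: int, source: str, length: int | None = None) -> None:
        nonlocal counter
        counter += 1
        n = length if length is not None else _draw_tag_length(rng, config.tag_length_weights)
        n = min(n, len(seq_source) - pos + 1)
        tag = seq_source[pos - 1: pos - 1 + n]
        read = tag + config.adapter
        if config.corrupt_fraction and rng.random() < config.corrupt_fraction:
            mode = int(rng.integers(0, 3))
            if mode == 0:  # too short after trimming
                read = tag[: int(rng.integers(10, 18))] + config.adapter
            elif mode == 1:  # ambiguous base
                j = int(rng.integers(0, len(tag)))
                read = tag[:j] + "N" + tag[j + 1:] + config.adapter
            else:  # adapter lost
                read = tag
            source = source + "_corrupt"
        reads.append((f"read{counter:07d}|{source}", read))

    # Planted cleavage signal
    truth_out: list[GroundTruthSite] = []
    for site in truth:
        n = 1 if site.forced_single else _draw_count(rng, config.signal_mean, config.nb_dispersion)
        for _ in range(n):
            emit(transcripts[site.transcript_id], site.canonical_cleavage, "signal")
        truth_out.append(dataclasses.replace(site, planted_signal=n))

    # Hairpin processing products and self-directed slicing
    hp_rows = []
    for hp in hairpins:
        for arm_id, start in ((hp.arm5_id, hp.arm5_start), (hp.arm3_id, hp.arm3_start)):
            n = _draw_count(rng, config.product_signal_mean, 0.0)
            for _ in range(n):
                emit(hp.sequence, start, "product", length=config.mirna_length)
        self_pos, self_n = 0, 0
        if hp.self_target:
            star_start, _ = hp.star_span()
            self_pos = star_start + config.mirna_length - 10
            self_n = _draw_count(rng, config.signal_mean, config.nb_dispersion)
            for _ in range(self_n):
                emit(hp.sequence, self_pos, "selfcleave")
        hp_rows.append(
            {
                "hairpin_id": hp.id,
                "family": hp.family,
                "guide_arm": hp.guide_arm,
                "arm5_start": hp.arm5_start,
                "arm5_end": hp.arm5_end,
                "arm3_start": hp.arm3_start,
                "arm3_end": hp.arm3_end,
                "self_target": int(hp.self_target),
                "self_target_position": self_pos,
                "self_target_signal": self_n,
            }
        )

    # Uniform decay background
    for tid in sorted(transcripts):
        seq = transcripts[tid]
        if len(seq) < 18:
            continue
        n_bg = _draw_count(rng, config.background_rate * len(seq), 0.0)
        for _ in range(n_bg):
            pos = int(rng.integers(1, len(seq) - 18 + 2))
            emit(seq, pos, "background")

    # ncRNA contaminants: fraction f of the final library
    if config.contaminant_fraction > 0 and ncrna:
        f = config.contaminant_fraction
        n_cont = int(round(len(reads) * f / (1 - f)))
        ids = sorted(ncrna)
        for _ in range(n_cont):
            nid = ids[int(rng.integers(0, len(ids)))]
            seq = ncrna[nid]
            if len(seq) < 18:
                continue
            pos = int(rng.integers(1, len(seq) - 18 + 2))
            emit(seq, pos, "contaminant")

    rng.shuffle(reads)
    return reads, truth_out, pd.DataFrame(hp_rows)


@dataclass
class SimResult:
    """In-memory handles plus file paths of one simulation."""

    config: SimConfig
    transcripts: dict[str, str]
    catalog: list[MatureMiRNA]
    hairpins: list[Hairpin]
    ncrna: dict[str, str]
    reads: list[tuple[str, str]]
    truth_sites: list[GroundTruthSite]
    truth_hairpins: pd.DataFrame
    outdir: Path | None = None


def simulate(config: SimConfig, outdir: str | Path | None = None) -> SimResult:
    """Run the full generator and (optionally) write the dataset to disk.

    Files written: transcripts.fasta, mirnas.fasta, hairpins.fasta,
    ncrna.fasta, reads.fastq (or .fasta), truth_sites.tsv,
    truth_hairpins.tsv.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    transcripts = generate_transcriptome(config, rng)
    catalog, hairpins = generate_hairpins(config, rng)
    ncrna = generate_ncrna(config, rng)
    transcripts, truth = plant_target_sites(transcripts, catalog, config, rng)
    reads, truth, hp_truth = simulate_reads(transcripts, truth, hairpins, ncrna, config, rng)

    result = SimResult(
        config=config,
        transcripts=transcripts,
        catalog=catalog,
        hairpins=hairpins,
        ncrna=ncrna,
        reads=reads,
        truth_sites=truth,
        truth_hairpins=hp_truth,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(((tid, "", s) for tid, s in transcripts.items()), outdir / "transcripts.fasta")
        write_fasta(
            (
                (
                    f"{m.id}|{m.arm}",
                    f"family={m.family} class={m.mclass} guide={int(m.guide)}",
                    m.sequence,
                )
                for m in catalog
            ),
            outdir / "mirnas.fasta",
        )
        write_fasta(
            (
                (
                    hp.id,
                    f"family={hp.family} guide_arm={hp.guide_arm} "
                    f"arm5={hp.arm5_start}-{hp.arm5_end} arm3={hp.arm3_start}-{hp.arm3_end}",
                    hp.sequence,
                )
                for hp in hairpins
            ),
            outdir / "hairpins.fasta",
        )
        write_fasta(((nid, "", s) for nid, s in ncrna.items()), outdir / "ncrna.fasta")
        if config.read_format == "fastq":
            write_fastq(reads, outdir / "reads.fastq")
        else:
            write_fasta(((rid, "", s) for rid, s in reads), outdir / "reads.fasta")
        pd.DataFrame([dataclasses.asdict(s) for s in truth]).to_csv(
            outdir / "truth_sites.tsv", sep="\t", index=False
        )
        hp_truth.to_csv(outdir / "truth_hairpins.tsv", sep="\t", index=False)
        result.outdir = outdir
    return result
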