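# Methods

## Model and assumptions

`degracall` implements degradome-supported validation of small-RNA
cleavage targets under the standard plant slicing model: an ungapped,
antiparallel miRNA:mRNA duplex, RISC scission between target bases
paired to miRNA nucleotides 10 and 11, and a 5'-monophosphate decay
fragment whose sequenced 5' end marks the cut. Three simplifications
are deliberate and global:

- **Exact-match mapping.** Tags are mapped to transcripts (and
  precursors) by exact sense-strand substring matching only. This makes
  the mapper deterministic and dependency-free at desk scale; it does
  not model sequencing errors or SNPs, and antisense or intron-aware
  (genomic) mapping is out of scope.
- **Ungapped alignment.** The penalty scheme (mismatch 1, G:U 0.5,
  doubled over miRNA positions 2–13) admits no bulges. Some published
  degradome calls in poplar involve single-nucleotide bulges; those are
  invisible here. All scores representable under the scheme are
  multiples of 0.5, so float arithmetic is exact.
- **Composition-based QC only.** Reads are rejected for a missing 3'
  adapter, trimmed length < 18 nt, or ambiguous bases — never for base
  quality. PARE tags are 5'-defined, so trimming never alters a 5' end;
  a 5' adapter, when present, must be removed upstream (a fixed-length
  5' clip option exists for libraries where it was not).

ncRNA contamination (rRNA/tRNA/sn(o)RNA) is removed by exact substring
membership of the tag in any contaminant sequence — a deterministic
stand-in for homology annotation, adequate because degradome rRNA
contamination is dominated by exact fragments.

## Category classification

Categories follow the CleaveLand convention. Decisions that the
definitions leave open, and how they are resolved here:

- The **median is taken over occupied positions only** (positions with
  at least one 5'-end read). Including zero positions would collapse
  the median to 0 on almost every transcript and inflate category 2.
  The alternative is isolated in `ProfileStats` should anyone want it.
- The **single-read test precedes the maximum test**: category 0
  explicitly requires more than one raw read, so a lone read that also
  happens to be the transcript maximum is category 4.
- **Ties at the median go to category 3** ("equal to or less than the
  median").
- The call **window half-width defaults to ±1 nt** around the canonical
  slicing coordinate, with an extended ±3 mode. Published analyses
  accept small register shifts (family members whose alignments place
  the cut 2 nt apart; runs of adjacent supported positions); every call
  records its `offset` so downstream filtering stays possible.
- Census percentages are **round-half-up integers** computed in exact
  integer arithmetic `(200·c + n) // (2n)`; stored percentages always
  recompute from counts. (Published tables occasionally print
  percentages inconsistent with any rounding of their own counts, e.g.
  45% for 29/66 where round-half-up gives 44; such values are treated
  as typographical and not reproduced.)

Score threshold: the default `max_score` is 4.5 — the largest value at
which plant degradome studies typically still report calls — and can be
raised to the conventional looser 7.0.

## The synthetic study generator

The generator's defaults define the study conditions used throughout
the tests and the acceptance script:

| parameter | default | meaning |
|---|---|---|
| n_transcripts / length range | 50, 500–2000 nt | random-composition transcript set |
| n_mirna_families | 10 | one hairpin + 5p/3p duplex each |
| mirna_length | 21 nt | guide and star strand length |
| sites_per_mirna | 3 | planted complementary sites per guide |
| signal_mean | 20 | Poisson mean reads at each planted slicing position |
| background_rate | 0.005 | expected background 5' ends per transcript position |
| contaminant_fraction | 0.25 | share of the library drawn from the ncRNA set |
| corrupt_fraction | 0.0064 | reads corrupted to exercise QC (≈99.4% retention) |
| tag_length_weights | 20 nt 59.6%, 21 nt 38.4% | 18–24 nt, matching observed degradome length profiles |
| n_dual_duplexes | 5 | duplexes whose star strand also receives a planted site |
| n_self_target_hairpins | 5 | hairpins given guide-directed self-slicing signal |
| single_read_sites | 6 | extra sites with support forced to exactly 1 read |
| star_edit_range | 1–3 | mismatch/G:U edits between the two arms |

Planted sites are drawn with 0–3 edits constrained to total score
≤ 4.5 and at most two edits inside the doubled 2–13 core, so every
planted site is discoverable at the default threshold by construction;
the recorded `planted_score` is produced by re-scoring the planted
window with the same scorer the pipeline uses, making truth-consistency
an exact invariant. Sites are assigned to distinct transcripts while
any remain unused, so planted signals do not compete for the
transcript maximum at the default budget.

Hairpins are 5' flank + 5p arm + loop (8–20 nt) + 3p arm + 3' flank,
the star arm being the reverse complement of the guide with the planted
edits (so the folded stem pairs). The 5' flank is 5–30 nt; the 3' flank
is 15–30 nt so that a tag of up to 24 nt whose 5' end sits at the
mid-star slicing position (star_start + L − 10) always fits inside the
hairpin. Hairpins also shed reads equal to their mature arm sequences
(mean 5 per arm), which is what the precursor-product table detects;
because these are fixed 21-mers they shift the realized tag-length
distribution a few points toward 21 nt relative to the configured
weights.

Counts are Poisson by default — the simplest model in which category
outcomes are tuned by a single mean — with a negative-binomial option
(`nb_dispersion`) for overdispersion robustness checks. Background 5'
ends are uniform per position, the implicit null of positionless decay.
FASTQ qualities are uniform because QC is not quality-based.

**What the generator does not emulate:** sequencing error substitutions
inside tags, PCR duplicates, expression-level heterogeneity between
transcripts, secondary structure of hairpins (arm coordinates are
declared, not folded), and partial-degradation 5' ends correlated with
structure. Passing tests therefore demonstrate the correctness of the
algorithmic pipeline under its stated model, not robustness to real
library artifacts.

## Family and duplex resolution

Feedback loops require matching a cleaving strand to its source
precursor. Families are taken from explicit `family=` annotation when
present (the generator always writes it); otherwise identifiers are
collapsed with a name heuristic (`pto-miR475a-3p`, `pto-MIR475b` and
`Precur-MIR475a` → `mir475`). Dual-functional duplexes are duplexes
with ≥ 1 call on each arm, counting transcript and precursor calls
jointly; strands lacking 5p/3p arm annotation are skipped with a
warning.

## Problem sizes and determinism

The default study (≈1,600 reads, ≈60 transcript/precursor scans of
≤ 2 kb sequence) runs end-to-end in under a second; the test suite and
the acceptance script use these sizes, which are sufficient for every
recovery statistic they assert. All randomness flows from one
`numpy.random.default_rng(seed)`; outputs are written in fixed sort
orders, so a fixed seed yields byte-identical artifact directories.

## Known limitations

- Multi-mapping tags contribute their full count at every locus
  (standard degradome practice; a `fractional` mode divides by locus
  multiplicity instead). Categories on paralogous transcripts are
  therefore not independent.
- No p-values are attached to calls; confidence is ordinal (category).
- The homopolymer filter (≥ 80% one base) is available but off by
  default: it is an extension beyond composition QC, not part of the
  core rule set.
- Precursor "cleavage sites" are the spans of matched products, not
  inferred DCL1 scission points.
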