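# degracall

Degradome / PARE (parallel analysis of RNA ends) sequencing analysis for
plant miRNA target validation.

When a plant miRNA-loaded RISC slices its target, it leaves an uncapped
5' monophosphate end precisely between the nucleotides paired to miRNA
positions 10 and 11. Degradome sequencing captures those uncapped 5'
ends genome-wide, so a pile-up of tag 5' ends at the predicted slicing
coordinate of a complementary site is direct, transcriptome-wide
evidence of cleavage. `degracall` takes raw degradome reads, a
transcript set, a mature miRNA catalog (with 5p/3p arm annotation) and
pre-miRNA hairpins, and produces:

- collapsed, quality-filtered unique tags with library statistics,
- per-transcript 5'-end signature profiles and *t*-plot tables/figures,
- miRNA complementary sites scored with the standard plant penalty
  scheme (mismatch 1, G:U wobble 0.5, penalties doubled over miRNA
  positions 2–13, ungapped),
- degradome-supported cleavage calls classified into CleaveLand-style
  confidence categories 0–4,
- precursor processing maps (perfectly matched products with 1-based
  inclusive spans), miRNA/miRNA*-directed precursor self-cleavage,
  feedback-loop calls, and duplexes in which both strands are
  functional guides,
- category censuses (overall and per conservation class) and
  targets-per-miRNA tallies.

A synthetic-data generator with full ground truth (planted sites,
hairpin geometries, read-level provenance) makes every stage testable
without external data.

## The method in brief

For a miRNA of length *L* aligned ungapped and antiparallel to a
transcript window starting at *s* (1-based), miRNA position *i* pairs
with transcript position *s + L − i* and the penalty score is

S = Σᵢ wᵢ·p(i),  p = 0 (Watson–Crick), 0.5 (G:U), 1 (mismatch),  wᵢ = 2 for i ∈ [2,13], else 1.

Sites with S ≤ 4.5 (configurable) are candidates; the canonical slicing
coordinate is *s + L − 10*. A candidate becomes a call when the
transcript's 5'-end profile is occupied within ±1 nt (window
configurable) of that coordinate. With *m* = transcript-wide maximum
signature, *k* = number of positions attaining it, and *q* = median
over occupied positions, a supported position with count *c* is:

| category | rule |
|---|---|
| 4 | c = 1 (single raw read; tested first) |
| 0 | c = m and k = 1 (unique maximum) |
| 1 | c = m and k > 1 (tied maximum) |
| 2 | q < c < m |
| 3 | c ≤ q |

## Worked example

Simulate a study and run the whole pipeline from one config:

```
$ printf 'simulate: true\nseed: 1\n' > demo.yaml
$ degracall run --config demo.yaml --out demo_out
pipeline complete: demo_out
```

The call table (`demo_out/calls.tsv`) mirrors a degradome target table:

```
mirna_id     target_id  cleavage_position  category  raw_tags  score  offset
syn-miR1-3p  tx0014     727                0         19        4.0    0
syn-miR1-3p  tx0020     1035               0         17        2.0    0
syn-miR1-3p  tx0045     940                0         17        0.0    0
syn-miR1-3p  tx0050     223                4         1         0.0    0
syn-miR1-5p  tx0023     395                0         22        3.5    0
```

Each row is one degradome-supported cleavage site: `syn-miR1-3p` slices
`tx0045` at position 940 with 17 raw tags at the slicing coordinate
(`offset 0` = exactly opposite miRNA nt 10), the unique signature
maximum on that transcript (category 0, the highest confidence), on a
perfectly complementary site (score 0.0). The category-4 row is a site
supported by a single read — the lowest confidence class.

The census (`census.tsv`) aggregates categories with round-half-up
integer percentages, overall and per conservation class, reporting
both denominators (category sites and distinct targets):

```
stratum    n_sites  n_targets  cat0_n  cat0_pct  ...  cat4_n  cat4_pct  high_confidence_n  high_confidence_pct
all        46       46         40      87        ...  6       13        40                 87
conserved  18       18         16      89        ...  2       11        16                 89
```

and `star_pairs.tsv` lists duplexes whose 5p and 3p strands both direct
cleavage (here the five planted dual-functional duplexes, counting
transcript and precursor calls jointly):

```
duplex_id  fivep_id     threep_id    fivep_calls  threep_calls
syn-mir1   syn-miR1-5p  syn-miR1-3p  1            5
...
syn-mir5   syn-miR5-5p  syn-miR5-3p  5            1
```

`feedback_loops.tsv` records hairpins sliced by a mature strand of
their own family (e.g. `syn-MIR1` cut at position 29 by `syn-miR1-3p`,
a negative feedback loop buffering mature-strand abundance), and
`precursor_products.tsv` maps DCL1 products: tags perfectly matched
inside hairpins with 1-based inclusive spans, e.g. a 21-mer at
positions 18–38.

Stages can also be run separately (`degracall simulate / preprocess /
call / precursor-scan / report`); see `degracall --help`.

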