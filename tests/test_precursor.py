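"""Precursor products, self-targeting, feedback loops and star pairs."""

import warnings

import pytest

from degracall import precursor as pc
from degracall import preprocess as pp
from degracall._seq import MatureMiRNA
from degracall.align import TargetAlignment
from degracall.cleavage import CleavageCall


def naive_products(query, seq):
    return [
        (i + 1, i + len(query))
        for i in range(len(seq) - len(query) + 1)
        if seq[i: i + len(query)] == query
    ]


class TestLocateProducts:
    def test_span_arithmetic_20mer_at_38(self):
        mir = "TTGGCATTCTGTCCACCTCC"  # 20 nt
        pre = "A" * 37 + mir + "G" * 60
        products = pc.locate_products({"mir394a-5p": (mir, 2)}, {"pre1": pre})
        assert len(products) == 1
        p = products[0]
        assert (p.span_start, p.span_end, p.length, p.count) == (38, 57, 20, 2)
        assert p.span_end == p.span_start + p.length - 1

    def test_absent_query_empty(self):
        assert pc.locate_products({"q": ("T" * 20, 1)}, {"pre1": "A" * 100}) == []

    def test_query_in_two_precursors(self):
        q = "ACGTACGTACGTACGTACGT"
        products = pc.locate_products(
            {"q": (q, 3)}, {"pre1": "G" * 10 + q, "pre2": q + "C" * 5}
        )
        assert len(products) == 2
        assert {p.precursor_id for p in products} == {"pre1", "pre2"}

    def test_overlapping_occurrences_all_reported(self):
        products = pc.locate_products({"q": ("AAAA", 1)}, {"pre1": "AAAAAA"})
        assert [(p.span_start, p.span_end) for p in products] == [(1, 4), (2, 5), (3, 6)]

    def test_substring_identity_and_oracle(self, rng):
        pre = "".join(rng.choice(list("ACGT"), size=400))
        queries = {
            f"q{i}": ("".join(rng.choice(list("AC"), size=8)), i) for i in range(10)
        }
        products = pc.locate_products(queries, {"pre": pre})
        for p in products:
            assert pre[p.span_start - 1: p.span_end] == p.sequence
        for qid, (qseq, _) in queries.items():
            got = [(p.span_start, p.span_end) for p in products if p.query_id == qid]
            assert got == naive_products(qseq, pre)


def _call(mirna_id, tid, pos=50, category=2):
    aln = TargetAlignment(
        mirna_id=mirna_id,
        transcript_id=tid,
        site_start=pos - 11,
        site_end=pos + 9,
        pairing=("match",) * 21,
        score=1.0,
        canonical_cleavage=pos,
    )
    return CleavageCall(aln, pos, 5, category, 0)


def _catalog():
    return [
        MatureMiRNA("syn-miR1-5p", "A" * 21, "5p", "syn-mir1", "conserved", True),
        MatureMiRNA("syn-miR1-3p", "C" * 21, "3p", "syn-mir1", "conserved", False),
        MatureMiRNA("syn-miR2-5p", "G" * 21, "5p", "syn-mir2", "novel", True),
        MatureMiRNA("syn-miR2-3p", "T" * 21, "3p", "syn-mir2", "novel", False),
    ]


class TestFeedbackLoops:
    def test_same_family_call_is_a_loop(self):
        loops = pc.detect_feedback_loops([_call("syn-miR1-5p", "syn-MIR1")], _catalog())
        assert len(loops) == 1
        assert loops[0].partner_strand_id is None

    def test_unrelated_mirna_no_loop(self):
        loops = pc.detect_feedback_loops([_call("syn-miR2-5p", "syn-MIR1")], _catalog())
        assert loops == []

    def test_both_arms_mutually_partnered(self):
        calls = [
            _call("syn-miR1-5p", "syn-MIR1", pos=110),
            _call("syn-miR1-3p", "syn-MIR1", pos=22),
        ]
        loops = pc.detect_feedback_loops(calls, _catalog())
        assert len(loops) == 2
        by_strand = {l.cleaving_strand_id: l for l in loops}
        assert by_strand["syn-miR1-5p"].partner_strand_id == "syn-miR1-3p"
        assert by_strand["syn-miR1-3p"].partner_strand_id == "syn-miR1-5p"

    def test_explicit_family_map_used(self):
        loops = pc.detect_feedback_loops(
            [_call("syn-miR1-5p", "hairpinX")],
            _catalog(),
            precursor_families={"hairpinX": "syn-mir1"},
        )
        assert len(loops) == 1


class TestStarPairs:
    def test_one_arm_only_not_emitted(self):
        pairs = pc.functional_star_pairs(
            [_call("syn-miR1-3p", "t1"), _call("syn-miR1-3p", "t2")], _catalog()
        )
        assert pairs == []

    def test_one_call_each_arm_emitted(self):
        pairs = pc.functional_star_pairs(
            [_call("syn-miR1-5p", "t1"), _call("syn-miR1-3p", "syn-MIR1")], _catalog()
        )
        assert len(pairs) == 1
        assert (pairs[0].fivep_calls, pairs[0].threep_calls) == (1, 1)

    def test_missing_arm_annotation_warns_and_skips(self):
        catalog = _catalog() + [
            MatureMiRNA("oddball", "G" * 21, None, "oddfam", "novel", True)
        ]
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            pairs = pc.functional_star_pairs([_call("oddball", "t1")], catalog)
        assert pairs == []
        assert any("oddball" in str(w.message) for w in rec)


class TestSelfTargets:
    def test_self_target_hairpins_generate_own_family_calls(self, default_sim):
        reads = [seq for _, seq in default_sim.reads]
        tags, _ = pp.preprocess_reads(
            reads, default_sim.config.adapter, default_sim.ncrna
        )
        precursors = {hp.id: hp.sequence for hp in default_sim.hairpins}
        calls = pc.precursor_self_targets(default_sim.catalog, precursors, tags)
        loops = pc.detect_feedback_loops(calls, default_sim.catalog)
        looped = {l.precursor_id for l in loops}
        for hp in default_sim.hairpins:
            if hp.self_target:
                assert hp.id in looped

    def test_precursor_without_signature_has_no_calls(self, default_sim):
        precursors = {hp.id: hp.sequence for hp in default_sim.hairpins}
        calls = pc.precursor_self_targets(default_sim.catalog, precursors, [])
        assert calls == []

    def test_cleavage_position_matches_planted_register(self, default_sim):
        """Self-target calls land at star_start + L - 10 (the mid-duplex cut)."""
        reads = [seq for _, seq in default_sim.reads]
        tags, _ = pp.preprocess_reads(
            reads, default_sim.config.adapter, default_sim.ncrna
        )
        precursors = {hp.id: hp.sequence for hp in default_sim.hairpins}
        calls = pc.precursor_self_targets(default_sim.catalog, precursors, tags)
        L = default_sim.config.mirna_length
        for hp in default_sim.hairpins:
            if not hp.self_target:
                continue
            star_start, _ = hp.star_span()
            expected = star_start + L - 10
            own = [
                c for c in calls
                if c.transcript_id == hp.id and c.mirna_id == hp.guide_id
            ]
            assert any(abs(c.cleavage_position - expected) <= 1 for c in own)
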