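"""Generator contracts: determinism, geometry, and truth consistency."""

import numpy as np
import pytest

from degracall import align
from degracall._seq import revcomp
from degracall.synthetic import (
    SimConfig,
    generate_hairpins,
    generate_transcriptome,
    plant_site,
    plant_target_sites,
    simulate,
    simulate_reads,
)


def _tiny(**kw):
    base = dict(
        seed=5,
        n_transcripts=8,
        transcript_length_range=(400, 700),
        n_mirna_families=3,
        sites_per_mirna=1,
        n_dual_duplexes=1,
        n_self_target_hairpins=1,
        single_read_sites=1,
        n_ncrna=2,
    )
    base.update(kw)
    return SimConfig(**base)


class TestTranscriptome:
    def test_empty(self):
        assert generate_transcriptome(_tiny(n_transcripts=0)) == {}

    def test_count_and_length_bounds(self):
        cfg = _tiny(n_transcripts=50, transcript_length_range=(500, 2000))
        tx = generate_transcriptome(cfg)
        assert len(tx) == 50
        assert len(set(tx)) == 50
        assert all(500 <= len(s) <= 2000 for s in tx.values())

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            generate_transcriptome(_tiny(transcript_length_range=(900, 500)))

    def test_deterministic(self):
        cfg = _tiny()
        assert generate_transcriptome(cfg) == generate_transcriptome(cfg)


class TestHairpins:
    def test_arm_coordinates_span_their_length(self):
        catalog, hairpins = generate_hairpins(_tiny(n_mirna_families=6))
        L = 21
        for hp in hairpins:
            assert hp.arm5_end == hp.arm5_start + L - 1
            assert hp.arm3_end == hp.arm3_start + L - 1
            assert hp.sequence[hp.arm5_start - 1: hp.arm5_end] == next(
                m.sequence for m in catalog if m.id == hp.arm5_id
            )
            assert hp.sequence[hp.arm3_start - 1: hp.arm3_end] == next(
                m.sequence for m in catalog if m.id == hp.arm3_id
            )

    def test_zero_star_edits_gives_exact_revcomp(self):
        catalog, hairpins = generate_hairpins(_tiny(star_edit_range=(0, 0)))
        by_id = {m.id: m for m in catalog}
        for hp in hairpins:
            guide = by_id[hp.guide_id]
            star_id = hp.arm3_id if hp.guide_arm == "5p" else hp.arm5_id
            assert by_id[star_id].sequence == revcomp(guide.sequence)

    def test_arm_suffixes_follow_placement(self):
        catalog, _ = generate_hairpins(_tiny())
        for m in catalog:
            assert m.id.endswith(f"-{m.arm}")

    def test_deterministic_catalog(self):
        cfg = _tiny()
        a, _ = generate_hairpins(cfg)
        b, _ = generate_hairpins(cfg)
        assert a == b

    def test_guide_discovers_own_precursor_window(self):
        """By construction the star-arm window scores <= 4.5 for the guide."""
        catalog, hairpins = generate_hairpins(_tiny(n_mirna_families=8))
        by_id = {m.id: m for m in catalog}
        for hp in hairpins:
            star_start, _ = hp.star_span()
            aln = align.score_site(by_id[hp.guide_id].sequence, hp.sequence, star_start)
            assert aln.score <= 4.5


class TestPlantSite:
    MIR = "TGACAGAAGAGAGTGAGCACA"  # 21 nt

    def test_empty_edit_list_perfect_complement(self, rng):
        seq = "A" * 200
        new, score = plant_site(seq, self.MIR, 50, [], rng)
        assert score == 0.0
        assert new[49: 49 + 21] == revcomp(self.MIR)

    def test_single_mismatch_at_position_15(self, rng):
        _, score = plant_site("A" * 200, self.MIR, 50, [(15, align.MISMATCH)], rng)
        assert score == 1.0

    def test_gu_in_core_doubles(self, rng):
        # miRNA position 5 is A here; pick position 4 (C->no; G at pos 4?)
        # position 1-based: T G A C A G A...: G at position 2 supports G:U
        _, score = plant_site("A" * 200, self.MIR, 50, [(2, align.GU)], rng)
        assert score == 1.0  # 0.5 doubled inside positions 2-13

    def test_gu_outside_core_is_half(self, rng):
        # position 14 is T in this miRNA -> wobble allowed
        assert self.MIR[13] == "T"
        _, score = plant_site("A" * 200, self.MIR, 50, [(14, align.GU)], rng)
        assert score == 0.5

    def test_boundary_overlap_rejected(self, rng):
        with pytest.raises(ValueError, match="overlaps"):
            plant_site("A" * 30, self.MIR, 15, [], rng)


class TestTruthConsistency:
    def test_rescoring_reproduces_planted_score(self, default_sim):
        for site in default_sim.truth_sites:
            mir = next(m for m in default_sim.catalog if m.id == site.mirna_id)
            aln = align.score_site(
                mir.sequence,
                default_sim.transcripts[site.transcript_id],
                site.site_start,
            )
            assert aln.score == site.planted_score
            assert aln.canonical_cleavage == site.canonical_cleavage

    def test_canonical_cleavage_arithmetic(self, default_sim):
        L = default_sim.config.mirna_length
        for site in default_sim.truth_sites:
            assert site.canonical_cleavage == site.site_start + L - 10


class TestSimulateReads:
    def test_zero_rates_empty_library(self):
        cfg = _tiny(
            signal_mean=0,
            background_rate=0,
            contaminant_fraction=0,
            product_signal_mean=0,
            single_read_sites=0,
            n_self_target_hairpins=0,
        )
        res = simulate(cfg)
        assert res.reads == []

    def test_reads_carry_adapter_unless_corrupted(self, default_sim):
        adapter = default_sim.config.adapter
        for rid, seq in default_sim.reads:
            if "_corrupt" not in rid:
                assert seq.endswith(adapter)

    def test_forced_single_sites_have_signal_one(self, default_sim):
        forced = [s for s in default_sim.truth_sites if s.forced_single]
        assert forced and all(s.planted_signal == 1 for s in forced)

    def test_deterministic_read_count(self):
        cfg = _tiny()
        assert len(simulate(cfg).reads) == len(simulate(cfg).reads)


def test_seed_gives_byte_identical_outputs(tmp_path):
    cfg = _tiny()
    d1, d2 = tmp_path / "a", tmp_path / "b"
    simulate(cfg, d1)
    simulate(cfg, d2)
    names = sorted(p.name for p in d1.iterdir())
    assert names == sorted(p.name for p in d2.iterdir())
    for name in names:
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name


def test_negative_binomial_option_runs():
    cfg = _tiny(nb_dispersion=2.0)
    res = simulate(cfg)
    assert any(s.planted_signal > 0 for s in res.truth_sites)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimConfig(mirna_length=30).validate()
    with pytest.raises(ValueError):
        SimConfig(background_rate=-1).validate()
    with pytest.raises(ValueError):
        SimConfig(adapter="").validate()
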