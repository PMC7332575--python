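"""Dispersed-repeat finder, IR classification, excision, gene counting."""

import random

import pytest

from plastosv.model import GenomeRecord, revcomp
from plastosv.repeats import (
    DEFAULT_CRITERIA,
    RepeatCriteria,
    classify_ir,
    count_unique_genes,
    designate_irb,
    excise_irb,
    find_repeats,
)
from plastosv.simulate import (
    GeneLoss,
    IRLoss,
    InsertSIR,
    Pseudogenize,
    apply_events,
    intergenic_position,
)

from helpers_oracles import brute_force_repeats, hit_key_set, verify_hit_by_string


def _random_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestFindRepeats:
    def test_planted_forward_copy(self):
        rng = random.Random(1)
        seq = _random_dna(rng, 500)
        seg = seq[100:140]
        seq = seq[:300] + seg + seq[340:]
        hits = [
            h
            for h in find_repeats(seq, RepeatCriteria(30, 0, 1.0))
            if h.type == "forward"
        ]
        assert len(hits) == 1
        h = hits[0]
        assert h.length >= 40 and h.mismatches == 0
        assert h.pos1 <= 100 and h.pos2 <= 300

    def test_planted_palindromic_copy(self):
        rng = random.Random(2)
        seq = _random_dna(rng, 500)
        seg = seq[100:140]
        seq = seq[:300] + revcomp(seg) + seq[340:]
        hits = [
            h
            for h in find_repeats(seq, RepeatCriteria(30, 0, 1.0))
            if h.type == "palindromic"
        ]
        assert len(hits) == 1 and hits[0].mismatches == 0

    def test_planted_copy_with_two_substitutions(self):
        rng = random.Random(3)
        seq = _random_dna(rng, 500)
        seg = list(seq[100:140])
        for pos in (10, 25):
            seg[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seg[pos]]
        seq = seq[:300] + "".join(seg) + seq[340:]
        # with the budget equal to the planted mismatch count plus zero slack,
        # exactly one maximal window covers the whole plant
        hits = [
            h
            for h in find_repeats(seq, RepeatCriteria(30, 2, 0.90))
            if h.type == "forward"
            and h.pos1 <= 100
            and h.pos1 + h.length >= 140
        ]
        assert len(hits) == 1
        h = hits[0]
        assert h.mismatches == 2
        assert h.identity == pytest.approx((h.length - 2) / h.length)

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_brute_force_oracle(self, seed):
        rng = random.Random(seed)
        n = rng.randint(80, 400)
        bases = "ACGTN" if seed % 4 == 0 else "ACGT"
        seq = "".join(rng.choice(bases) for _ in range(n))
        crit = RepeatCriteria(10, rng.choice([0, 1, 2, 3]), 0.8)
        assert hit_key_set(find_repeats(seq, crit)) == brute_force_repeats(seq, crit)

    def test_every_hit_reverifies_by_string_comparison(self):
        rng = random.Random(42)
        seq = _random_dna(rng, 600)
        seq = seq[:450] + revcomp(seq[50:95]) + seq[495:]
        for h in find_repeats(seq, RepeatCriteria(10, 2, 0.8)):
            assert verify_hit_by_string(seq, h)

    def test_palindromic_symmetric_under_revcomp(self):
        rng = random.Random(6)
        seq = _random_dna(rng, 400)
        seq = seq[:300] + revcomp(seq[40:80]) + seq[340:]
        crit = RepeatCriteria(12, 1, 0.9)
        fwd = {
            (h.pos1, h.pos2, h.length, h.mismatches)
            for h in find_repeats(seq, crit, types=("palindromic",))
        }
        n = len(seq)
        rc = {
            (n - (h.pos2 + h.length), n - (h.pos1 + h.length), h.length, h.mismatches)
            for h in find_repeats(revcomp(seq), crit, types=("palindromic",))
        }
        assert fwd == rc

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            find_repeats("ACGT" * 20, DEFAULT_CRITERIA, types=("tandem",))


class TestClassifyIR:
    def test_planted_ir_recovered_exactly(self, compact_ancestor):
        genome, _ = compact_ancestor
        pairs = classify_ir(genome, min_ir_len=3000)
        assert [p.klass for p in pairs] == ["IR"]
        ir_feat = genome.feature_by_id("IR_A")
        assert pairs[0].length == ir_feat.length

    def test_ir_lost_genome_reports_sir_only(self, compact_ancestor):
        genome, _ = compact_ancestor
        p1 = intergenic_position(genome, 2000)
        p2 = intergenic_position(genome, 5000)
        evolved, _ = apply_events(
            genome, [IRLoss("B"), InsertSIR(271, (p1, p2))], seed=4
        )
        pairs = classify_ir(evolved, min_ir_len=3000)
        assert [(p.klass, p.length) for p in pairs] == [("sIR", 271)]

    def test_plain_sequence_has_no_pairs(self):
        rng = random.Random(9)
        genome = GenomeRecord(id="bare", sequence=_random_dna(rng, 5000))
        assert classify_ir(genome, min_ir_len=1000) == []


class TestExciseIRB:
    def test_length_drops_by_ir_len(self, compact_ancestor):
        genome, _ = compact_ancestor
        ir = classify_ir(genome, min_ir_len=3000)[0]
        out = excise_irb(genome, ir)
        assert out.length == genome.length - ir.length

    def test_duplicated_genes_become_single_copy(self, compact_ancestor):
        genome, _ = compact_ancestor
        ir = classify_ir(genome, min_ir_len=3000)[0]
        out = excise_irb(genome, ir)
        rrn = [f for f in out.features if f.kind == "gene" and f.name == "rrn16"]
        assert len(rrn) == 1

    def test_excised_genome_has_no_ir(self, compact_ancestor):
        genome, _ = compact_ancestor
        ir = classify_ir(genome, min_ir_len=3000)[0]
        out = excise_irb(genome, ir)
        assert all(p.klass != "IR" for p in classify_ir(out, min_ir_len=3000))

    def test_designation_prefers_copy_before_shorter_flank(self, compact_ancestor):
        genome, _ = compact_ancestor
        ir = classify_ir(genome, min_ir_len=3000)[0]
        b = designate_irb(genome, ir)
        assert b == (genome.feature_by_id("IR_B").start, genome.feature_by_id("IR_B").end)

    def test_rejects_sir_class(self, compact_ancestor):
        genome, _ = compact_ancestor
        ir = classify_ir(genome, min_ir_len=3000)[0]
        from dataclasses import replace

        with pytest.raises(ValueError):
            excise_irb(genome, replace(ir, klass="sIR"))


class TestCountUniqueGenes:
    def test_default_catalog_gives_published_outgroup_count(self, default_ancestor):
        genome, _ = default_ancestor
        assert count_unique_genes(genome) == 112

    def test_arithmetic_after_losses(self, default_ancestor):
        genome, _ = default_ancestor
        losses = ["accD", "rps16", "ycf1", "rpl32", "infA", "cemA"]
        evolved, _ = apply_events(genome, [GeneLoss(n) for n in losses])
        assert count_unique_genes(evolved) == 112 - 6

    def test_pseudogene_not_counted(self, default_ancestor):
        genome, _ = default_ancestor
        evolved, _ = apply_events(genome, [Pseudogenize("rpl20")])
        assert count_unique_genes(evolved) == 111
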