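"""Synthetic ancestor construction, scripted events, truth log, reads."""

import numpy as np
import pytest

from plastosv.io import write_fastq_pairs
from plastosv.model import revcomp
from plastosv.repeats import classify_ir, count_unique_genes
from plastosv.simulate import (
    AncestorConfig,
    CatalogGene,
    GeneLoss,
    Inversion,
    IRLoss,
    InsertSIR,
    IntronLoss,
    Pseudogenize,
    ReadSimConfig,
    ScriptedEventError,
    Translocate,
    apply_events,
    generate_ancestor,
    intergenic_position,
    replay_truth_log,
    simulate_reads,
)


class TestAncestor:
    def test_ir_copies_are_exact_reverse_complements(self, default_ancestor):
        genome, _ = default_ancestor
        a = genome.feature_by_id("IR_A")
        b = genome.feature_by_id("IR_B")
        assert revcomp(genome.sequence[a.start : a.end]) == genome.sequence[b.start : b.end]

    def test_copy_numbers(self, default_ancestor):
        genome, _ = default_ancestor
        from collections import Counter

        counts = Counter(f.name for f in genome.features if f.kind == "gene")
        ir_names = {
            f.name
            for f in genome.features
            if f.kind == "gene" and f.notes.get("ir_copy") == "B"
        }
        for name in ir_names:
            assert counts[name] >= 2
        catalog_dupes = {"trnG-UCC", "trnM-CAU", "rps19_fragment"}
        for name, c in counts.items():
            if name not in ir_names and name not in catalog_dupes:
                assert c == 1, name

    def test_truth_table_has_thirteen_blocks(self, default_ancestor):
        _, table = default_ancestor
        assert sorted(table.labels_for("ancestor")) == list(range(1, 14))

    def test_total_length_matches_config(self):
        cfg = AncestorConfig.compact(seed=5)
        genome, _ = cfg and generate_ancestor(cfg)
        assert genome.length == cfg.lsc_len + cfg.ssc_len + 2 * cfg.ir_len

    def test_deterministic_under_seed(self):
        g1, _ = generate_ancestor(AncestorConfig.compact(seed=8))
        g2, _ = generate_ancestor(AncestorConfig.compact(seed=8))
        assert g1.sequence == g2.sequence and g1.features == g2.features

    def test_catalog_too_large_rejected(self):
        cfg = AncestorConfig.compact(seed=1)
        with pytest.raises(ValueError, match="catalog too large"):
            generate_ancestor(
                AncestorConfig(
                    lsc_len=2000,
                    ssc_len=2000,
                    ir_len=5000,
                    gene_catalog=cfg.gene_catalog,
                    spacer_len_range=cfg.spacer_len_range,
                    seed=1,
                )
            )

    def test_ir_len_floor_enforced(self):
        with pytest.raises(ValueError):
            AncestorConfig(ir_len=500)


class TestEvents:
    def test_ir_loss_drops_exactly_ir_len(self, compact_ancestor):
        genome, _ = compact_ancestor
        cfg = AncestorConfig.compact(seed=1)
        evolved, _ = apply_events(genome, [IRLoss("B")])
        assert evolved.length == genome.length - cfg.ir_len
        rrn = [f for f in evolved.features if f.kind == "gene" and f.name == "rrn16"]
        assert len(rrn) == 1

    def test_inversion_is_involution(self, compact_ancestor):
        genome, _ = compact_ancestor
        s = intergenic_position(genome, 1500)
        e = intergenic_position(genome, 6000)
        once, _ = apply_events(genome, [Inversion(s, e)])
        twice, _ = apply_events(once, [Inversion(s, e)])
        assert twice.sequence == genome.sequence
        assert twice.features == genome.features

    def test_inversion_flips_contained_strands(self, compact_ancestor):
        genome, _ = compact_ancestor
        s = intergenic_position(genome, 1500)
        e = intergenic_position(genome, 6000)
        evolved, _ = apply_events(genome, [Inversion(s, e)])
        inside_before = {
            f.id: f.strand for f in genome.features if s <= f.start and f.end <= e
        }
        inside_after = {
            f.id: f.strand for f in evolved.features if f.id in inside_before
        }
        assert inside_before.keys() == inside_after.keys()
        assert all(inside_after[k] != inside_before[k] for k in inside_before)

    def test_pseudogenize_writes_internal_stop(self, compact_ancestor):
        genome, _ = compact_ancestor
        evolved, log = apply_events(genome, [Pseudogenize("psbA")])
        feat = next(f for f in evolved.features if f.name == "psbA")
        assert feat.kind == "pseudogene" and "lesion" in feat.notes
        sense = evolved.sequence[feat.start : feat.end]
        if feat.strand == "-":
            sense = revcomp(sense)
        codons = [sense[i : i + 3] for i in range(0, len(sense) - 3, 3)]
        assert "TAA" in codons[1:-1]
        assert evolved.length == genome.length

    def test_intron_loss_shrinks_gene(self, compact_ancestor):
        genome, _ = compact_ancestor
        evolved, _ = apply_events(genome, [IntronLoss("ndhA", 1)])
        assert evolved.length == genome.length - 300
        gene_before = next(f for f in genome.features if f.name == "ndhA" and f.kind == "gene")
        gene_after = next(f for f in evolved.features if f.name == "ndhA" and f.kind == "gene")
        assert gene_after.length == gene_before.length - 300

    def test_event_on_missing_feature_errors(self, compact_ancestor):
        genome, _ = compact_ancestor
        with pytest.raises(ScriptedEventError):
            apply_events(genome, [GeneLoss("nonexistent")])
        with pytest.raises(ScriptedEventError):
            apply_events(genome, [IntronLoss("psbA", 1)])

    def test_translocation_moves_segment(self, compact_ancestor):
        genome, _ = compact_ancestor
        s = intergenic_position(genome, 2000)
        e = intergenic_position(genome, 4000)
        dest = intergenic_position(genome, 9000) - (e - s)
        seg = genome.sequence[s:e]
        plain, _ = apply_events(genome, [Translocate(s, e, dest)])
        assert plain.length == genome.length
        assert plain.sequence[dest : dest + (e - s)] == seg
        assert sorted(plain.sequence) == sorted(genome.sequence)
        flipped, _ = apply_events(genome, [Translocate(s, e, dest, inverted=True)])
        assert flipped.sequence[dest : dest + (e - s)] == revcomp(seg)

    def test_truth_log_replay_is_exact(self, compact_ancestor):
        # coordinates are validated against the evolving state, so positions
        # for later events are measured on the intermediate genomes
        genome, _ = compact_ancestor
        head = [IRLoss("B"), GeneLoss("rps4"), Pseudogenize("psbA")]
        mid, _ = apply_events(genome, head)
        p1 = intergenic_position(mid, 2500)
        p2 = intergenic_position(mid, 5200)
        mid2, _ = apply_events(mid, [InsertSIR(271, (p1, p2))], seed=12)
        s = intergenic_position(mid2, 7000)
        e = intergenic_position(mid2, 8600)
        script = head + [InsertSIR(271, (p1, p2)), Inversion(s, e)]
        evolved, log = apply_events(genome, script, seed=12)
        replayed = replay_truth_log(genome, log)
        assert replayed.sequence == evolved.sequence
        assert replayed.features == evolved.features

    def test_scripted_inversions_bound_reversal_distance(self, compact_ancestor):
        # full recovery loop: inversions at block boundaries -> d <= k
        import random

        from plastosv.rearrange import reversal_distance
        from plastosv.repeats import excise_irb
        from plastosv.synteny import build_blocks, encode_permutation, gene_order

        genome, truth = compact_ancestor
        rng = random.Random(77)
        rows = {r.block_label: r for r in truth.rows_for("ancestor")}
        k = 4
        cur = genome
        for _ in range(k):
            b1, b2 = sorted(rng.sample(range(2, 11), 2))
            s = intergenic_position(cur, rows[b1].start - 1)
            e = intergenic_position(cur, rows[b2].end + 1)
            cur, _ = apply_events(cur, [Inversion(s, e)])
        ir = classify_ir(cur, min_ir_len=3000)[0]
        tgt = excise_irb(cur, ir)
        tgt.id = "evolved"
        ref = excise_irb(genome, classify_ir(genome, min_ir_len=3000)[0])
        ref.id = "ref"
        table = build_blocks(
            gene_order(ref, "trnH-GUG"), gene_order(tgt, "trnH-GUG")
        )
        perm = encode_permutation(table, "ref", "evolved")
        assert reversal_distance(perm).d <= k


class TestReads:
    def test_error_free_reads_are_exact_substrings(self, compact_ancestor):
        genome, _ = compact_ancestor
        reads = simulate_reads(genome, ReadSimConfig(n_pairs=200, seed=7))
        doubled = genome.sequence + genome.sequence
        for r in reads:
            assert r.seq1 in doubled
            assert revcomp(r.seq2) in doubled

    def test_same_seed_gives_identical_fastq(self, compact_ancestor, tmp_path):
        genome, _ = compact_ancestor
        for tag in ("x", "y"):
            reads = simulate_reads(genome, ReadSimConfig(n_pairs=150, seed=3))
            write_fastq_pairs(
                [(r.pair_id, r.seq1, r.seq2) for r in reads],
                tmp_path / f"{tag}_1.fq",
                tmp_path / f"{tag}_2.fq",
            )
        assert (tmp_path / "x_1.fq").read_bytes() == (tmp_path / "y_1.fq").read_bytes()
        assert (tmp_path / "x_2.fq").read_bytes() == (tmp_path / "y_2.fq").read_bytes()

    def test_insert_mean_within_three_standard_errors(self, compact_ancestor):
        genome, _ = compact_ancestor
        cfg = ReadSimConfig(n_pairs=2000, insert_mean=450, insert_sd=60, seed=19)
        reads = simulate_reads(genome, cfg)
        inserts = np.array([r.insert for r in reads])
        se = cfg.insert_sd / np.sqrt(len(inserts))
        assert abs(inserts.mean() - cfg.insert_mean) < 3 * se

    def test_error_rate_validated(self):
        with pytest.raises(ValueError):
            ReadSimConfig(error_rate=0.5)

    def test_mutated_reads_change_bases(self, compact_ancestor):
        genome, _ = compact_ancestor
        clean = simulate_reads(genome, ReadSimConfig(n_pairs=100, seed=5))
        noisy = simulate_reads(
            genome, ReadSimConfig(n_pairs=100, error_rate=0.05, seed=5)
        )
        assert any(c.seq1 != n.seq1 for c, n in zip(clean, noisy))
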