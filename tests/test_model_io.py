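"""Domain types, coordinate conventions, and write-read round trips."""

import random

import pytest

from plastosv import io as psv_io
from plastosv.model import (
    Feature,
    GenomeRecord,
    LossCharacterMatrix,
    SyntenyBlockRow,
    SyntenyBlockTable,
    complement,
    revcomp,
)


def test_revcomp_keeps_unknown_bases():
    assert revcomp("ACGTN") == "NACGT"
    assert complement("ACGTN") == "TGCAN"


class TestDomainValidation:
    def test_feature_interval_must_be_forward(self):
        with pytest.raises(ValueError):
            Feature(id="f", kind="gene", name="x", start=5, end=5, strand="+")

    def test_pseudogene_requires_lesion(self):
        with pytest.raises(ValueError):
            Feature(id="f", kind="pseudogene", name="x", start=0, end=3, strand="+")

    def test_feature_outside_sequence_rejected(self):
        f = Feature(id="g", kind="gene", name="x", start=2, end=20, strand="+")
        with pytest.raises(ValueError):
            GenomeRecord(id="g1", sequence="ACGTACGTAC", features=[f])

    def test_wrap_feature_needs_part_notes(self):
        parts = [
            Feature(id="w", kind="gene", name="x", start=8, end=10, strand="+",
                    notes={"part": "1"}),
            Feature(id="w", kind="gene", name="x", start=0, end=3, strand="+",
                    notes={"part": "2"}),
        ]
        GenomeRecord(id="ok", sequence="ACGTACGTAC", features=parts)
        bad = [p for p in parts]
        bad[1] = Feature(id="w", kind="gene", name="x", start=0, end=3, strand="+")
        with pytest.raises(ValueError):
            GenomeRecord(id="bad", sequence="ACGTACGTAC", features=bad)

    def test_block_table_rejects_overlap_and_duplicates(self):
        r1 = SyntenyBlockRow(1, "g", 0, 10, "+")
        with pytest.raises(ValueError):
            SyntenyBlockTable(rows=[r1, SyntenyBlockRow(1, "g", 20, 30, "+")])
        with pytest.raises(ValueError):
            SyntenyBlockTable(rows=[r1, SyntenyBlockRow(2, "g", 5, 15, "+")])

    def test_loss_matrix_states_checked(self):
        with pytest.raises(ValueError):
            LossCharacterMatrix(taxa=["a"], characters=["c"], states=[["2"]])


class TestGenomeIO:
    def test_gff3_one_based_conversion(self, tmp_path):
        fasta = tmp_path / "g.fasta"
        fasta.write_text(">g1 topology=linear\nACGTACGTAC\n")
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "g1\tx\tgene\t1\t6\t.\t+\t.\tID=f1;Name=demo;kind=gene\n"
        )
        rec = psv_io.read_genome(fasta)
        assert rec.features[0].start == 0 and rec.features[0].end == 6

    def test_feature_beyond_length_is_validation_error(self, tmp_path):
        fasta = tmp_path / "g.fasta"
        fasta.write_text(">g1\nACGTACGTAC\n")
        gff = tmp_path / "g.gff3"
        gff.write_text("g1\tx\tgene\t1\t60\t.\t+\t.\tID=f1;Name=n;kind=gene\n")
        with pytest.raises(psv_io.ParseError):
            psv_io.read_genome(fasta)

    def test_malformed_gff3_names_line(self, tmp_path):
        fasta = tmp_path / "g.fasta"
        fasta.write_text(">g1\nACGTACGTAC\n")
        (tmp_path / "g.gff3").write_text("g1\tonly-two-cols\n")
        with pytest.raises(psv_io.ParseError, match="g.gff3:1"):
            psv_io.read_genome(fasta)

    @pytest.mark.parametrize("format", ["fasta+gff3", "feature-table-tsv"])
    def test_round_trip_random_records(self, tmp_path, format):
        rng = random.Random(31)
        for i in range(20):
            n = rng.randint(50, 300)
            seq = "".join(rng.choice("ACGT") for _ in range(n))
            feats = []
            pos = 0
            for j in range(rng.randint(0, 5)):
                start = pos + rng.randint(0, 10)
                end = start + rng.randint(3, 20)
                if end >= n:
                    break
                feats.append(
                    Feature(
                        id=f"f{j}",
                        kind=rng.choice(["gene", "intron", "sIR"]),
                        name=f"name{j}",
                        start=start,
                        end=end,
                        strand=rng.choice("+-"),
                        notes={"k": "v w", "block": str(j)} if j % 2 else {},
                    )
                )
                pos = end
            rec = GenomeRecord(
                id=f"r{i}",
                sequence=seq,
                topology=rng.choice(["circular", "linear"]),
                features=feats,
            )
            path = tmp_path / f"r{i}.fasta"
            psv_io.write_genome(rec, path, format=format)
            back = psv_io.read_genome(path, format=format)
            assert back.id == rec.id
            assert back.sequence == rec.sequence
            assert back.topology == rec.topology
            assert back.features == rec.features

    def test_empty_feature_list_round_trips(self, tmp_path):
        rec = GenomeRecord(id="e", sequence="ACGT" * 10, features=[])
        psv_io.write_genome(rec, tmp_path / "e.fasta")
        assert psv_io.read_genome(tmp_path / "e.fasta").features == []

    def test_wrap_feature_round_trips_as_two_lines(self, tmp_path):
        rec = GenomeRecord(
            id="w",
            sequence="ACGTACGTAC",
            features=[
                Feature(id="w1", kind="gene", name="x", start=8, end=10,
                        strand="+", notes={"part": "1"}),
                Feature(id="w1", kind="gene", name="x", start=0, end=3,
                        strand="+", notes={"part": "2"}),
            ],
        )
        path = tmp_path / "w.fasta"
        psv_io.write_genome(rec, path)
        lines = [
            l for l in (tmp_path / "w.gff3").read_text().splitlines()
            if l and not l.startswith("#")
        ]
        assert len(lines) == 2
        assert psv_io.read_genome(path).features == rec.features


class TestTabularIO:
    def test_permutation_file_parses_printed_rows(self, tmp_path):
        p = tmp_path / "perms.txt"
        p.write_text(
            "Lophopyxis maingayi: 1, 2, 3, 4, -6, -5, 7, 8, 9, 10, -13, 11, 12\n"
        )
        perms = psv_io.read_permutations(p)
        assert perms["Lophopyxis maingayi"].labels == (
            1, 2, 3, 4, -6, -5, 7, 8, 9, 10, -13, 11, 12,
        )

    @pytest.mark.parametrize("body", ["a: 1, 1, 2", "a: 1, 3", "no-colon-line"])
    def test_permutation_file_rejects_bad_rows(self, tmp_path, body):
        p = tmp_path / "bad.txt"
        p.write_text(body + "\n")
        with pytest.raises(psv_io.ParseError):
            psv_io.read_permutations(p)

    def test_permutations_round_trip(self, tmp_path):
        from plastosv.rearrange import SignedPermutation

        perms = {
            "a": SignedPermutation((1, -3, 2)),
            "b": SignedPermutation.identity(4),
        }
        p = tmp_path / "p.txt"
        psv_io.write_permutations(perms, p)
        assert psv_io.read_permutations(p) == perms

    def test_block_table_round_trip(self, tmp_path):
        table = SyntenyBlockTable(
            rows=[
                SyntenyBlockRow(1, "g1", 0, 10, "+"),
                SyntenyBlockRow(2, "g1", 10, 30, "-"),
                SyntenyBlockRow(1, "g2", 5, 25, "-"),
            ]
        )
        p = tmp_path / "blocks.tsv"
        psv_io.write_block_table(table, p)
        assert psv_io.read_block_table(p).rows == table.rows

    def test_loss_matrix_round_trip(self, tmp_path):
        m = LossCharacterMatrix(
            taxa=["t1", "t2"],
            characters=["accD", "clpP_intron1"],
            states=[["1", "0"], ["?", "1"]],
        )
        p = tmp_path / "m.tsv"
        psv_io.write_loss_matrix(m, p)
        back = psv_io.read_loss_matrix(p)
        assert back.taxa == m.taxa
        assert back.characters == m.characters
        assert back.states == m.states

    def test_tree_round_trip(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("((A,B),(C,D));\n")
        tree = psv_io.read_tree(p)
        out = tmp_path / "t2.nwk"
        psv_io.write_tree(tree, out)
        labels = sorted(
            leaf.taxon.label for leaf in psv_io.read_tree(out).leaf_node_iter()
        )
        assert labels == ["A", "B", "C", "D"]

    def test_fastq_pairs_round_trip(self, tmp_path):
        pairs = [("p1", "ACGT", "TTAA"), ("p2", "GGGG", "CCCC")]
        psv_io.write_fastq_pairs(pairs, tmp_path / "r1.fq", tmp_path / "r2.fq")
        assert psv_io.read_fastq_pairs(tmp_path / "r1.fq", tmp_path / "r2.fq") == pairs
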