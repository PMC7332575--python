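"""Readers and writers for the formats the pipeline touches.

FASTA is read/written through Biopython; trees through dendropy; tabular
formats (block tables, loss-character matrices) are plain TSV.  The GFF3
dialect written here is 1-based inclusive with the feature kind and notes
kept in the attribute column, so write -> read is the identity on valid
:class:`~plastosv.model.GenomeRecord` objects.
"""

from __future__ import annotations

import os
import urllib.parse
from pathlib import Path

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    Feature,
    GenomeRecord,
    LossCharacterMatrix,
    SyntenyBlockRow,
    SyntenyBlockTable,
)
from .rearrange import SignedPermutation

__all__ = [
    "read_genome",
    "write_genome",
    "read_permutations",
    "write_permutations",
    "read_block_table",
    "write_block_table",
    "read_loss_matrix",
    "write_loss_matrix",
    "read_tree",
    "write_tree",
    "read_fastq_pairs",
    "write_fastq_pairs",
]


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# genomes: FASTA + GFF3, or a flat feature-table TSV
# ---------------------------------------------------------------------------

_FASTA_WIDTH = 70


def _gff3_path(fasta_path: str | Path) -> Path:
    return Path(fasta_path).with_suffix(".gff3")


def _table_path(fasta_path: str | Path) -> Path:
    return Path(fasta_path).with_suffix(".features.tsv")


def read_genome(
    path: str | Path,
    format: str = "fasta+gff3",
    features_path: str | Path | None = None,
) -> GenomeRecord:
    """Read a genome: FASTA sequence plus GFF3 or feature-table annotations.

    ``path`` names the FASTA file; the companion annotation file defaults to
    the same stem with ``.gff3`` (or ``.features.tsv``) unless given
    explicitly.  GFF3 coordinates (1-based inclusive) are converted to the
    internal 0-based half-open convention.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ParseError(f"{path}: expected exactly one FASTA record, got {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper()
    if not seq:
        raise ParseError(f"{path}: empty sequence")
    topology = "circular" if "topology=circular" in rec.description else "linear"

    if format == "fasta+gff3":
        fpath = Path(features_path) if features_path else _gff3_path(path)
        features, topo2 = _read_gff3(fpath, rec.id)
        if topo2 is not None:
            topology = topo2
    elif format == "feature-table-tsv":
        fpath = Path(features_path) if features_path else _table_path(path)
        features = _read_feature_table(fpath)
    else:
        raise ValueError(f"unknown genome format {format!r}")

    try:
        return GenomeRecord(id=rec.id, sequence=seq, topology=topology, features=features)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_genome(
    record: GenomeRecord, path: str | Path, format: str = "fasta+gff3"
) -> None:
    """Write FASTA (fixed wrap width) plus GFF3 or feature-table annotations."""
    path = Path(path)
    seqrec = SeqRecord(
        Seq(record.sequence),
        id=record.id,
        description=f"topology={record.topology}",
    )
    with open(path, "w") as fh:
        SeqIO.write([seqrec], fh, "fasta")
    if format == "fasta+gff3":
        _write_gff3(record, _gff3_path(path))
    elif format == "feature-table-tsv":
        _write_feature_table(record, _table_path(path))
    else:
        raise ValueError(f"unknown genome format {format!r}")


def _esc(value: str) -> str:
    return urllib.parse.quote(str(value), safe="")


def _unesc(value: str) -> str:
    return urllib.parse.unquote(value)


def _write_gff3(record: GenomeRecord, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {record.id} 1 {record.length}\n")
        fh.write(f"# topology={record.topology}\n")
        for f in record.features:
            attrs = [f"ID={_esc(f.id)}", f"Name={_esc(f.name)}", f"kind={_esc(f.kind)}"]
            for k in sorted(f.notes):
                attrs.append(f"note_{_esc(k)}={_esc(f.notes[k])}")
            fh.write(
                "\t".join(
                    [
                        record.id,
                        "plastosv",
                        f.kind,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def _read_gff3(path: Path, seqid: str) -> tuple[list[Feature], str | None]:
    features: list[Feature] = []
    topology: str | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "topology=" in line:
                    topology = line.split("topology=", 1)[1].strip()
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            _, _, ftype, start1, end1, _, strand, _, attr_col = cols
            try:
                start1i, end1i = int(start1), int(end1)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            attrs: dict[str, str] = {}
            for chunk in attr_col.split(";"):
                if not chunk:
                    continue
                if "=" not in chunk:
                    raise ParseError(f"{path}:{lineno}: malformed attribute {chunk!r}")
                k, v = chunk.split("=", 1)
                attrs[_unesc(k)] = _unesc(v)
            notes = {
                k[len("note_") :]: v for k, v in attrs.items() if k.startswith("note_")
            }
            try:
                features.append(
                    Feature(
                        id=attrs.get("ID", f"f{lineno}"),
                        kind=attrs.get("kind", ftype),
                        name=attrs.get("Name", ""),
                        start=start1i - 1,
                        end=end1i,
                        strand=strand,
                        notes=notes,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return features, topology


_TABLE_COLS = ["id", "kind", "name", "start", "end", "strand", "notes"]


def _write_feature_table(record: GenomeRecord, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TABLE_COLS) + "\n")
        for f in record.features:
            notes = ";".join(f"{_esc(k)}={_esc(v)}" for k, v in sorted(f.notes.items()))
            fh.write(
                "\t".join(
                    [f.id, f.kind, f.name, str(f.start + 1), str(f.end), f.strand, notes]
                )
                + "\n"
            )


def _read_feature_table(path: Path) -> list[Feature]:
    features: list[Feature] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TABLE_COLS:
            raise ParseError(f"{path}: unexpected feature-table header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != len(_TABLE_COLS):
                raise ParseError(f"{path}:{lineno}: expected {len(_TABLE_COLS)} columns")
            fid, kind, name, start1, end1, strand, notes_s = cols
            notes = {}
            if notes_s:
                for chunk in notes_s.split(";"):
                    k, v = chunk.split("=", 1)
                    notes[_unesc(k)] = _unesc(v)
            try:
                features.append(
                    Feature(
                        id=fid,
                        kind=kind,
                        name=name,
                        start=int(start1) - 1,
                        end=int(end1),
                        strand=strand,
                        notes=notes,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return features


# ---------------------------------------------------------------------------
# permutations, block tables, loss matrices, trees, reads
# ---------------------------------------------------------------------------


def read_permutations(path: str | Path) -> dict[str, SignedPermutation]:
    """Parse lines of the form ``name: s1, s2, ..., sn``."""
    out: dict[str, SignedPermutation] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ParseError(f"{path}:{lineno}: expected 'name: s1, s2, ...'")
            name, rest = line.split(":", 1)
            name = name.strip()
            if name in out:
                raise ParseError(f"{path}:{lineno}: duplicate genome id {name!r}")
            try:
                out[name] = SignedPermutation.from_text(rest)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_permutations(perms: dict[str, SignedPermutation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, perm in perms.items():
            fh.write(f"{name}: {perm}\n")


def read_block_table(path: str | Path) -> SyntenyBlockTable:
    """Block table TSV: block_label, genome_id, start, end (1-based incl), strand."""
    rows: list[SyntenyBlockRow] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["block_label", "genome_id", "start", "end", "strand"]:
            raise ParseError(f"{path}: unexpected block-table header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            try:
                rows.append(
                    SyntenyBlockRow(
                        block_label=int(cols[0]),
                        genome_id=cols[1],
                        start=int(cols[2]) - 1,
                        end=int(cols[3]),
                        strand=cols[4],
                    )
                )
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return SyntenyBlockTable(rows=rows)


def write_block_table(table: SyntenyBlockTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("block_label\tgenome_id\tstart\tend\tstrand\n")
        for r in table.rows:
            fh.write(
                f"{r.block_label}\t{r.genome_id}\t{r.start + 1}\t{r.end}\t{r.strand}\n"
            )


def read_loss_matrix(path: str | Path) -> LossCharacterMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "taxon":
            raise ParseError(f"{path}: first column must be 'taxon'")
        characters = header[1:]
        taxa: list[str] = []
        states: list[list[str]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != len(header):
                raise ParseError(f"{path}:{lineno}: column count mismatch")
            taxa.append(cols[0])
            states.append(cols[1:])
    try:
        return LossCharacterMatrix(taxa=taxa, characters=characters, states=states)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_loss_matrix(matrix: LossCharacterMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\t" + "\t".join(matrix.characters) + "\n")
        for taxon, row in zip(matrix.taxa, matrix.states):
            fh.write(taxon + "\t" + "\t".join(row) + "\n")


def read_tree(path: str | Path) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ParseError(f"{path}: duplicate leaf labels")
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick")


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> list[tuple[str, str, str]]:
    """Paired FASTQ -> list of (pair id, mate1 seq, mate2 seq)."""
    mates1 = list(SeqIO.parse(str(path1), "fastq"))
    mates2 = list(SeqIO.parse(str(path2), "fastq"))
    if len(mates1) != len(mates2):
        raise ParseError("mate files have unequal numbers of reads")
    out = []
    for r1, r2 in zip(mates1, mates2):
        pid = r1.id.removesuffix("/1")
        out.append((pid, str(r1.seq).upper(), str(r2.seq).upper()))
    return out


def write_fastq_pairs(
    pairs: list[tuple[str, str, str]], path1: str | Path, path2: str | Path
) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for pid, s1, s2 in pairs:
            f1.write(f"@{pid}/1\n{s1}\n+\n{'I' * len(s1)}\n")
            f2.write(f"@{pid}/2\n{s2}\n+\n{'I' * len(s2)}\n")
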