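"""Synteny blocks from shared gene anchors; signed-permutation encoding.

A desk-scale stand-in for whole-genome alignment: genes that are single-copy
in both genomes serve as signed anchors, maximal runs of anchors that are
consecutive in both genomes with a consistent relative orientation collapse
into one block, and blocks are numbered 1..n in reference order.  The target
genome is then encoded as a signed permutation — the label sequence in target
coordinate order, each label signed by the product of the block's strand in
target and reference ("strand orientation determines the sign").

Anchor-free stretches (intergenic blocks) cannot be recovered this way; they
are absorbed into the preceding block's span.  Reproducing a published block
segmentation that includes an intergenic-only block therefore requires
importing the block table rather than rebuilding it from gene anchors.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .model import GenomeRecord, SyntenyBlockRow, SyntenyBlockTable
from .rearrange import SignedPermutation

__all__ = ["GeneOrder", "gene_order", "build_blocks", "encode_permutation"]


@dataclass(frozen=True)
class GeneOrder:
    """Ordered (name, strand) gene list along a genome, with coordinates."""

    genome_id: str
    entries: tuple[tuple[str, str], ...]
    coords: tuple[tuple[int, int], ...] = ()
    genome_length: int | None = None

    def __post_init__(self) -> None:
        if not self.coords:
            object.__setattr__(
                self, "coords", tuple((i, i + 1) for i in range(len(self.entries)))
            )
        if len(self.coords) != len(self.entries):
            raise ValueError("coords and entries length mismatch")


def gene_order(genome: GenomeRecord, origin_gene: str | None = None) -> GeneOrder:
    """Intact genes sorted by start, optionally rotated/oriented at an origin.

    With ``origin_gene`` set, the (circular) order is rotated so that gene
    comes first; if it lies on the minus strand the whole reading direction is
    flipped first, so the origin block is always encoded as +1.
    """
    genes = sorted(
        (f for f in genome.features if f.kind == "gene"), key=lambda f: f.start
    )
    entries = [(f.name, f.strand) for f in genes]
    coords = [(f.start, f.end) for f in genes]
    if origin_gene is not None:
        matches = [i for i, (n, _) in enumerate(entries) if n == origin_gene]
        if len(matches) != 1:
            raise ValueError(
                f"origin gene {origin_gene!r} not unique in {genome.id}"
            )
        idx = matches[0]
        if entries[idx][1] == "-":
            length = genome.length
            entries = [
                (n, "+" if s == "-" else "-") for n, s in reversed(entries)
            ]
            coords = [(length - e, length - s) for s, e in reversed(coords)]
            idx = len(entries) - 1 - idx
        entries = entries[idx:] + entries[:idx]
        coords = coords[idx:] + coords[:idx]
    return GeneOrder(
        genome_id=genome.id,
        entries=tuple(entries),
        coords=tuple(coords),
        genome_length=genome.length,
    )


def build_blocks(ref: GeneOrder, target: GeneOrder) -> SyntenyBlockTable:
    """Collapse shared single-copy gene anchors into synteny blocks.

    Blocks are numbered 1..n by reference order; anchor-free sequence between
    blocks is absorbed into the preceding (lower-coordinate) block's span.
    """
    ref_counts = Counter(n for n, _ in ref.entries)
    tgt_counts = Counter(n for n, _ in target.entries)
    anchors = {
        n for n in ref_counts if ref_counts[n] == 1 and tgt_counts.get(n) == 1
    }
    if not anchors:
        raise ValueError(
            f"no shared single-copy gene anchors between {ref.genome_id} "
            f"and {target.genome_id}"
        )
    ref_anchors = [
        (n, s, ref.coords[i]) for i, (n, s) in enumerate(ref.entries) if n in anchors
    ]
    ref_index = {n: k + 1 for k, (n, _, _) in enumerate(ref_anchors)}
    ref_strand = {n: s for n, s, _ in ref_anchors}

    tgt_anchors = [
        (n, s, target.coords[i])
        for i, (n, s) in enumerate(target.entries)
        if n in anchors
    ]
    values = [
        ref_index[n] if s == ref_strand[n] else -ref_index[n]
        for n, s, _ in tgt_anchors
    ]

    # maximal runs consecutive in both genomes with consistent orientation
    runs: list[tuple[int, int]] = []  # [start, end) indices into tgt_anchors
    rs = 0
    for t in range(1, len(values) + 1):
        if t == len(values) or values[t] != values[t - 1] + 1:
            runs.append((rs, t))
            rs = t
    # label runs 1..n by reference position of their lowest anchor index
    keyed = sorted(runs, key=lambda r: min(abs(values[t]) for t in range(r[0], r[1])))
    labels = {run: lab + 1 for lab, run in enumerate(keyed)}

    rows: list[SyntenyBlockRow] = []
    for run in runs:
        lab = labels[run]
        vs = values[run[0] : run[1]]
        orient = "+" if vs[0] > 0 else "-"
        t_coords = [tgt_anchors[t][2] for t in range(run[0], run[1])]
        t_start = min(c[0] for c in t_coords)
        t_end = max(c[1] for c in t_coords)
        r_idx = sorted(abs(v) for v in vs)
        r_coords = [ref_anchors[k - 1][2] for k in r_idx]
        r_start = min(c[0] for c in r_coords)
        r_end = max(c[1] for c in r_coords)
        rows.append(
            SyntenyBlockRow(lab, ref.genome_id, r_start, r_end, "+")
        )
        rows.append(
            SyntenyBlockRow(lab, target.genome_id, t_start, t_end, orient)
        )

    # absorb anchor-free sequence into the preceding block per genome
    absorbed: list[SyntenyBlockRow] = []
    for gid in (ref.genome_id, target.genome_id):
        g_rows = sorted(
            (r for r in rows if r.genome_id == gid), key=lambda r: r.start
        )
        for i, r in enumerate(g_rows):
            end = g_rows[i + 1].start if i + 1 < len(g_rows) else r.end
            absorbed.append(
                SyntenyBlockRow(r.block_label, gid, r.start, max(r.end, end), r.strand)
            )
    return SyntenyBlockTable(rows=absorbed)


def encode_permutation(
    blocks: SyntenyBlockTable, reference_id: str, target_id: str
) -> SignedPermutation:
    """Signed permutation of the target's block order relative to reference."""
    ref_rows = blocks.rows_for(reference_id)
    tgt_rows = blocks.rows_for(target_id)
    if not ref_rows or not tgt_rows:
        raise ValueError("reference or target genome missing from block table")
    ref_labels = {r.block_label for r in ref_rows}
    tgt_labels = {r.block_label for r in tgt_rows}
    if ref_labels != tgt_labels:
        missing = sorted(ref_labels ^ tgt_labels)
        raise ValueError(f"block label sets differ; unmatched labels: {missing}")
    ref_strand = {r.block_label: r.strand for r in ref_rows}
    labels = []
    for r in sorted(tgt_rows, key=lambda r: r.start):
        sign = 1 if r.strand == ref_strand[r.block_label] else -1
        labels.append(sign * r.block_label)
    return SignedPermutation(tuple(labels))
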