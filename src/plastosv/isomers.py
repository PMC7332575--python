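"""sIR-mediated flip-flop isomers and read-pair spanning evidence.

A pair of short inverted repeats (sIRs) can mediate intramolecular homologous
recombination that inverts the segment between the copies, so a plastome
population carries two isomeric configurations.  Whether a given isomer
exists in the sequenced DNA is decided from paired-end reads: a read pair
that maps properly (inward-facing) to one isomer, with an insert length
inside the library window (the published filter kept 330-600 bp), and whose
mates bracket an entire sIR copy — one mate wholly before it, the other
wholly after — can only derive from that configuration.  An isomer with at
least ``min_support`` such spanning pairs is called supported.

The internal mapper places mates by exact substring match on the circular
sequence (both strands) and keeps pairs where both mates place uniquely and
inward-facing; precomputed alignments can be ingested from SAM instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .model import GenomeRecord, revcomp
from .repeats import IRPair
from .simulate import ReadPair, invert_segment

__all__ = [
    "ReadPairAlignment",
    "IsomerEvidence",
    "DEFAULT_INSERT_WINDOW",
    "flip_isomer",
    "map_pairs",
    "filter_by_insert",
    "spanning_support",
    "evaluate_isomers",
    "read_sam_pairs",
]

DEFAULT_INSERT_WINDOW = (330, 600)


@dataclass(frozen=True)
class ReadPairAlignment:
    pair_id: str
    mate1_start: int
    mate1_end: int
    mate2_start: int
    mate2_end: int
    proper_orientation: bool
    insert: int

    def __post_init__(self) -> None:
        if self.insert <= 0:
            raise ValueError("insert must be positive")


@dataclass(frozen=True)
class IsomerEvidence:
    isomer: str
    mapped_pairs: int
    filtered_pairs: int
    spanning_pairs: dict[str, int] = field(hash=False)
    supported: bool = False


def flip_isomer(genome: GenomeRecord, sir: IRPair) -> GenomeRecord:
    """The alternative configuration: segment between the sIR copies inverted.

    The repeat copies themselves are left untouched (flip-flop recombination
    is invariant on the repeats); length and base composition are preserved,
    and applying the flip twice restores the original genome.
    """
    if sir.a_end > sir.b_start:
        raise ValueError("sIR copies overlap; no segment to flip")
    if sir.b_end > genome.length:
        raise ValueError("origin-wrapping sIR flips are not supported; rotate first")
    return invert_segment(genome, sir.a_end, sir.b_start)


def _occurrences(needle: str, haystack: str, limit: int) -> list[int]:
    """Start positions of needle in haystack with start < limit."""
    out: list[int] = []
    idx = haystack.find(needle)
    while idx != -1 and idx < limit:
        out.append(idx)
        idx = haystack.find(needle, idx + 1)
    return out


def map_pairs(
    reads: list[ReadPair] | list[tuple[str, str, str]],
    genome: GenomeRecord,
) -> list[ReadPairAlignment]:
    """Exact-match placement of read pairs on the (circular) genome.

    A pair is reported when exactly one proper inward-facing placement
    exists: one mate forward, the other reverse-complemented downstream
    within one genome circumference.  Ambiguous or unplaced pairs drop out.
    """
    n = genome.length
    doubled = (
        genome.sequence + genome.sequence
        if genome.topology == "circular"
        else genome.sequence
    )
    out: list[ReadPairAlignment] = []
    for read in reads:
        if isinstance(read, ReadPair):
            pid, s1, s2 = read.pair_id, read.seq1, read.seq2
        else:
            pid, s1, s2 = read
        candidates: list[tuple[int, int, int, int, bool]] = []
        # (left_start, left_end, right_start, right_end, mate1_is_left)
        for left, right, m1_left in ((s1, s2, True), (s2, s1, False)):
            fwd = _occurrences(left, doubled, n)
            rev = _occurrences(revcomp(right), doubled, 2 * n)
            for p in fwd:
                for q in rev:
                    if q < p or q + len(right) - p > n:
                        continue
                    if q + len(right) < p + len(left):
                        continue
                    candidates.append((p, p + len(left), q, q + len(right), m1_left))
        if len(candidates) != 1:
            continue
        p, pe, q, qe, m1_left = candidates[0]
        insert = qe - p
        if m1_left:
            aln = ReadPairAlignment(pid, p, pe, q, qe, True, insert)
        else:
            aln = ReadPairAlignment(pid, q, qe, p, pe, True, insert)
        out.append(aln)
    return out


def filter_by_insert(
    pairs: list[ReadPairAlignment],
    window: tuple[int, int] = DEFAULT_INSERT_WINDOW,
) -> list[ReadPairAlignment]:
    """Keep properly oriented pairs with lo <= insert <= hi (inclusive)."""
    lo, hi = window
    if lo >= hi:
        raise ValueError("insert window must satisfy lo < hi")
    return [p for p in pairs if p.proper_orientation and lo <= p.insert <= hi]


def spanning_support(
    pairs: list[ReadPairAlignment],
    sir: IRPair,
    min_support: int = 1,
    isomer: str = "A",
) -> IsomerEvidence:
    """Count pairs whose inner gap contains an entire sIR copy.

    A pair spans a copy X when the leftmost mate ends at or before X.start
    and the rightmost mate starts at or after X.end.  Counting is per copy;
    the isomer is supported when any copy reaches ``min_support``.
    """
    counts = {"A": 0, "B": 0}
    copies = {"A": (sir.a_start, sir.a_end), "B": (sir.b_start, sir.b_end)}
    for p in pairs:
        if p.mate1_start <= p.mate2_start:
            left_end, right_start = p.mate1_end, p.mate2_start
        else:
            left_end, right_start = p.mate2_end, p.mate1_start
        for label, (xs, xe) in copies.items():
            if left_end <= xs and right_start >= xe:
                counts[label] += 1
    supported = any(c >= min_support for c in counts.values())
    return IsomerEvidence(
        isomer=isomer,
        mapped_pairs=len(pairs),
        filtered_pairs=len(pairs),
        spanning_pairs=counts,
        supported=supported,
    )


def evaluate_isomers(
    genome: GenomeRecord,
    sir: IRPair,
    reads: list[ReadPair] | list[tuple[str, str, str]],
    window: tuple[int, int] = DEFAULT_INSERT_WINDOW,
    min_support: int = 1,
) -> dict[str, IsomerEvidence]:
    """Map reads to both isomer configurations and score spanning support."""
    flipped = flip_isomer(genome, sir)
    flipped.id = genome.id + "_isomerB"
    out: dict[str, IsomerEvidence] = {}
    for label, g in (("A", genome), ("B", flipped)):
        mapped = map_pairs(reads, g)
        filtered = filter_by_insert(mapped, window)
        ev = spanning_support(filtered, sir, min_support, isomer=label)
        out[label] = IsomerEvidence(
            isomer=label,
            mapped_pairs=len(mapped),
            filtered_pairs=len(filtered),
            spanning_pairs=ev.spanning_pairs,
            supported=ev.supported,
        )
    return out


def read_sam_pairs(path: str | Path) -> list[ReadPairAlignment]:
    """Ingest precomputed alignments (SAM) as read-pair records."""
    import pysam

    out: list[ReadPairAlignment] = []
    seen: dict[str, object] = {}
    with pysam.AlignmentFile(str(path), "r") as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if not rec.is_paired:
                continue
            if rec.query_name in seen:
                other = seen.pop(rec.query_name)
                first, second = (other, rec) if other.is_read1 else (rec, other)
                insert = abs(first.template_length) or abs(second.template_length)
                if insert <= 0:
                    continue
                out.append(
                    ReadPairAlignment(
                        pair_id=first.query_name,
                        mate1_start=first.reference_start,
                        mate1_end=first.reference_end,
                        mate2_start=second.reference_start,
                        mate2_end=second.reference_end,
                        proper_orientation=bool(first.is_proper_pair),
                        insert=insert,
                    )
                )
            else:
                seen[rec.query_name] = rec
    return out
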