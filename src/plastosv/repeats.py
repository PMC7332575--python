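"""Dispersed-repeat enumeration and inverted-repeat classification.

Four repeat classes are recognized, following the usual organellar-genomics
vocabulary: *forward* (second copy as-is), *palindromic* (second copy reverse
complemented, i.e. an inverted repeat), *reverse* (second copy reversed) and
*complement* (second copy complemented in place).  A hit is a MAXIMAL pair of
same-length windows whose Hamming distance does not exceed ``max_hamming``:
extending one base left or right (where the sequence allows) would exceed the
mismatch budget.  Bases outside {A, C, G, T} never match anything, themselves
included.

The default criteria mirror the two published settings for plastome repeat
surveys: minimum length 30 bp with Hamming distance 3 and >= 90% identity,
and minimum length 30 bp with zero mismatches.

Detection is exact: every qualifying maximal window contains an exact run of
length >= ceil((min_len - max_hamming) / (max_hamming + 1)) by pigeonhole, so
seeding with exact k-mers of that length and extending across up to
``max_hamming + 1`` mismatches on each side cannot miss a hit.  A brute-force
all-pairs scan exists only in the test suite as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import Feature, GenomeRecord, complement, revcomp

__all__ = [
    "RepeatCriteria",
    "RepeatHit",
    "IRPair",
    "REPEAT_TYPES",
    "DEFAULT_CRITERIA",
    "EXACT_CRITERIA",
    "find_repeats",
    "classify_ir",
    "excise_irb",
    "count_unique_genes",
]

REPEAT_TYPES = ("forward", "palindromic", "reverse", "complement")

_ACGT = frozenset(b"ACGT")


@dataclass(frozen=True)
class RepeatCriteria:
    min_len: int
    max_hamming: int
    min_identity: float

    def __post_init__(self) -> None:
        if self.min_len < 2:
            raise ValueError("min_len must be >= 2")
        if self.max_hamming < 0:
            raise ValueError("max_hamming must be >= 0")
        if not (0.0 < self.min_identity <= 1.0):
            raise ValueError("min_identity must be in (0, 1]")


DEFAULT_CRITERIA = RepeatCriteria(min_len=30, max_hamming=3, min_identity=0.90)
EXACT_CRITERIA = RepeatCriteria(min_len=30, max_hamming=0, min_identity=1.0)


@dataclass(frozen=True)
class RepeatHit:
    type: str
    pos1: int
    pos2: int
    length: int
    mismatches: int

    def __post_init__(self) -> None:
        if self.pos1 > self.pos2 or (self.pos1 == self.pos2 and self.type == "forward"):
            raise ValueError("hits are reported with pos1 <= pos2 (strict for forward)")

    @property
    def identity(self) -> float:
        return (self.length - self.mismatches) / self.length


@dataclass(frozen=True)
class IRPair:
    """One pair of exactly inverted copies; the large IR or a short sIR."""

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    length: int
    klass: str  # "IR" | "sIR"


def _transformed(seq: str, rtype: str) -> str:
    if rtype == "forward":
        return seq
    if rtype == "palindromic":
        return revcomp(seq)
    if rtype == "reverse":
        return seq[::-1]
    if rtype == "complement":
        return complement(seq)
    raise ValueError(f"unknown repeat type {rtype!r}")


def seed_length(criteria: RepeatCriteria) -> int:
    """Exact-seed length guaranteeing completeness by pigeonhole."""
    k = criteria.max_hamming
    return max(1, -(-(criteria.min_len - k) // (k + 1)))


def _exact_runs(sb: bytes, tb: bytes, w: int, diag_filter) -> dict[int, list[tuple[int, int]]]:
    """Maximal exact runs (length >= w) per diagonal, from chained seed hits.

    A run (s, e) on diagonal d means sb[s:e] == tb[s+d:e+d] exactly, with all
    bases in ACGT, and the run cannot be extended.
    """
    index: dict[bytes, list[int]] = {}
    n = len(sb)
    for i in range(n - w + 1):
        kmer = sb[i : i + w]
        if any(ch not in _ACGT for ch in kmer):
            continue
        index.setdefault(kmer, []).append(i)
    m = len(tb)
    seeds: dict[int, list[int]] = {}
    for j in range(m - w + 1):
        hits = index.get(tb[j : j + w])
        if not hits:
            continue
        for i in hits:
            d = j - i
            if diag_filter(d):
                seeds.setdefault(d, []).append(i)
    runs: dict[int, list[tuple[int, int]]] = {}
    for d, cols in seeds.items():
        cols.sort()
        merged: list[tuple[int, int]] = []
        rs, re = cols[0], cols[0] + w
        for c in cols[1:]:
            if c <= re - w + 1:
                re = max(re, c + w)
            else:
                merged.append((rs, re))
                rs, re = c, c + w
        merged.append((rs, re))
        runs[d] = merged
    return runs


def _match(a: int, b: int) -> bool:
    return a == b and a in _ACGT


def find_repeats(
    seq: str,
    criteria: RepeatCriteria = DEFAULT_CRITERIA,
    types: tuple[str, ...] = REPEAT_TYPES,
) -> list[RepeatHit]:
    """All maximal repeat pairs of the requested types under the criteria.

    Each unordered occurrence pair is reported once, with ``pos1 <= pos2``
    (strictly for forward repeats).  Hits shorter than ``min_len`` or below
    ``min_identity`` are filtered out.
    """
    for t in types:
        if t not in REPEAT_TYPES:
            raise ValueError(f"unknown repeat type {t!r}")
    n = len(seq)
    if n < criteria.min_len:
        raise ValueError("sequence shorter than min_len")
    k = criteria.max_hamming
    w = seed_length(criteria)
    sb = seq.upper().encode()
    hits: list[RepeatHit] = []
    for rtype in types:
        tb = _transformed(seq.upper(), rtype).encode()
        pair_like = rtype in ("forward", "complement")
        diag_filter = (lambda d: d > 0) if pair_like else (lambda d: True)
        runs = _exact_runs(sb, tb, w, diag_filter)
        seen: set[tuple[int, int, int]] = set()
        for d, run_list in runs.items():
            lo = max(0, -d)
            hi = min(n, len(tb) - d)
            for rs, re in run_list:
                left_mm: list[int] = []
                t = rs - 1
                while t >= lo and len(left_mm) < k + 1:
                    if not _match(sb[t], tb[t + d]):
                        left_mm.append(t)
                    t -= 1
                right_mm: list[int] = []
                t = re
                while t < hi and len(right_mm) < k + 1:
                    if not _match(sb[t], tb[t + d]):
                        right_mm.append(t)
                    t += 1
                for a in range(k + 1):
                    b = k - a
                    ws = left_mm[a] + 1 if a < len(left_mm) else lo
                    we = right_mm[b] if b < len(right_mm) else hi
                    mm = min(a, len(left_mm)) + min(b, len(right_mm))
                    left_blocked = ws == lo or mm + 1 > k
                    right_blocked = we == hi or mm + 1 > k
                    if not (left_blocked and right_blocked):
                        continue
                    length = we - ws
                    if length < criteria.min_len:
                        continue
                    if (length - mm) / length < criteria.min_identity:
                        continue
                    if (d, ws, we) in seen:
                        continue
                    seen.add((d, ws, we))
                    if pair_like:
                        p1, p2 = ws, ws + d
                    else:
                        p1 = ws
                        p2 = n - (ws + d) - length
                        if p2 < p1:
                            continue  # mirror of a window reported elsewhere
                    hits.append(
                        RepeatHit(
                            type=rtype, pos1=p1, pos2=p2, length=length, mismatches=mm
                        )
                    )
    hits.sort(key=lambda h: (h.type, h.pos1, h.pos2, -h.length))
    return hits


# ---------------------------------------------------------------------------
# IR / sIR classification and IR_B excision
# ---------------------------------------------------------------------------


def _circular_arcs_disjoint(a: int, la: int, b: int, lb: int, n: int) -> bool:
    """Are circular arcs [a, a+la) and [b, b+lb) (mod n) disjoint?"""
    for s1, l1, s2, l2 in ((a, la, b, lb), (b, lb, a, la)):
        gap = (s2 - s1) % n
        if gap < l1:
            return False
    return True


def classify_ir(
    genome: GenomeRecord,
    min_ir_len: int = 10_000,
    min_sir_len: int = 30,
) -> list[IRPair]:
    """Detect the large IR pair and short inverted repeats (sIRs).

    Exact (0-mismatch) inverted repeat pairs with disjoint spans are ranked by
    length; the longest pair >= ``min_ir_len`` is the IR, remaining pairs
    >= ``min_sir_len`` are sIRs (longest first).  Circular genomes are scanned
    across the origin; an origin-wrapping copy is reported with its end beyond
    the genome length.
    """
    n = genome.length
    if genome.topology == "circular":
        scan = genome.sequence + genome.sequence
    else:
        scan = genome.sequence
    if len(scan) < min_sir_len:
        return []
    crit = RepeatCriteria(min_len=min_sir_len, max_hamming=0, min_identity=1.0)
    raw = find_repeats(scan, crit, types=("palindromic",))
    candidates: dict[frozenset, tuple[int, int, int]] = {}
    for h in raw:
        if h.length > n:
            continue
        a = h.pos1 % n
        b = h.pos2 % n
        if a == b and h.pos1 != h.pos2:
            continue  # the same physical copy seen twice through doubling
        key = frozenset(((a, h.length), (b, h.length)))
        prev = candidates.get(key)
        if prev is None or h.length > prev[2]:
            lo, hi = min(a, b), max(a, b)
            candidates[key] = (lo, hi, h.length)
    pairs = sorted(candidates.values(), key=lambda t: (-t[2], t[0], t[1]))
    out: list[IRPair] = []
    have_ir = False
    for a, b, length in pairs:
        if not _circular_arcs_disjoint(a, length, b, length, n):
            continue
        if not have_ir and length >= min_ir_len:
            klass = "IR"
            have_ir = True
        elif length >= min_sir_len:
            klass = "sIR"
        else:
            continue
        out.append(
            IRPair(
                a_start=a,
                a_end=a + length,
                b_start=b,
                b_end=b + length,
                length=length,
                klass=klass,
            )
        )
    return out


def designate_irb(genome: GenomeRecord, ir: IRPair) -> tuple[int, int]:
    """Pick which IR copy is "B": the copy followed by the shorter SC gap.

    The two single-copy stretches separating the IR copies differ in length
    (SSC-like vs LSC-like); the copy immediately upstream of the shorter
    (SSC-like) stretch is designated B, so excising it leaves the genome
    reading LSC, SSC, IR in reference order.  Returns (start, end) of B.
    """
    n = genome.length
    gap_a_to_b = (ir.b_start - ir.a_end) % n
    gap_b_to_a = (ir.a_start - ir.b_end) % n
    if gap_a_to_b <= gap_b_to_a:
        return ir.a_start, ir.a_end
    return ir.b_start, ir.b_end


def excise_irb(genome: GenomeRecord, ir: IRPair) -> GenomeRecord:
    """Remove the B copy of the IR; drop its features, shift the rest."""
    if ir.klass != "IR":
        raise ValueError("excise_irb expects an IR-class pair")
    b_start, b_end = designate_irb(genome, ir)
    n = genome.length
    if b_end > n:
        raise ValueError("cannot excise an origin-wrapping IR copy; rotate first")
    if (b_start, b_end) == (ir.a_start, ir.a_end):
        o_start, o_end = ir.b_start, ir.b_end
    else:
        o_start, o_end = ir.a_start, ir.a_end
    if revcomp(genome.subsequence(b_start, b_end)) != genome.subsequence(o_start, o_end):
        raise ValueError("IR pair does not match the genome sequence")
    length = b_end - b_start
    new_seq = genome.sequence[:b_start] + genome.sequence[b_end:]
    new_features: list[Feature] = []
    for f in genome.features:
        if f.start >= b_start and f.end <= b_end:
            continue  # inside B: dropped
        if f.end <= b_start:
            new_features.append(f)
        elif f.start >= b_end:
            new_features.append(f.shifted(-length))
        else:
            raise ValueError(
                f"feature {f.id} straddles the IR_B boundary; cannot excise"
            )
    return GenomeRecord(
        id=genome.id,
        sequence=new_seq,
        topology=genome.topology,
        features=new_features,
    )


def count_unique_genes(genome: GenomeRecord) -> int:
    """Distinct intact gene names; IR duplicates once, pseudogenes excluded."""
    return len({f.name for f in genome.features if f.kind == "gene"})
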