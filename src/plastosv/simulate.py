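"""Synthetic quadripartite plastomes, scripted evolution, and read pairs.

The generator emulates the canonical photosynthetic-angiosperm plastome: a
circular molecule with a Large Single Copy region (~85 kb), a Small Single
Copy region (~15 kb) and two identical inverted-repeat copies (~25 kb each),
laid out as LSC | IR_B | SSC | IR_A.  Genes come from a built-in catalog that
mirrors the locally-collinear-block gene content published for the
putranjivoid clade comparison (13 blocks; 112 distinct gene names, the count
reported for the IR-bearing outgroup *Balanops*): blocks 1-10 sit in the LSC,
block 11 spans the SSC and the head of the IR, blocks 12-13 complete the IR.
Block 7 is a gene-free intergenic block, as published.

Intergenic spacers are i.i.d. uniform random DNA and genes are random DNA
(protein genes get an enforced ATG...stop frame free of internal stops), so
the only repeats in a synthetic genome are the ones scripted into it; planted
repeat tests are exact.  The single base flanking each planted inverted-repeat
copy is pinned to break chance extensions, so maximal-repeat detection
recovers planted lengths exactly.

Scripted events (inversion, IR loss, gene/intron loss, pseudogenization by an
internal stop codon, sIR insertion, translocation) are applied left to right
with coordinates re-validated against the evolving genome; a truth log records
every resolved event so that replaying it on the ancestor reproduces the
evolved genome byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import Feature, GenomeRecord, SyntenyBlockRow, SyntenyBlockTable, revcomp

__all__ = [
    "CatalogGene",
    "AncestorConfig",
    "EventScript",
    "TruthLog",
    "ReadSimConfig",
    "ReadPair",
    "Inversion",
    "IRLoss",
    "GeneLoss",
    "IntronLoss",
    "Pseudogenize",
    "InsertSIR",
    "Translocate",
    "default_catalog",
    "compact_catalog",
    "generate_ancestor",
    "invert_segment",
    "intergenic_position",
    "apply_events",
    "replay_truth_log",
    "simulate_reads",
]


@dataclass(frozen=True)
class CatalogGene:
    name: str
    length: int  # full feature span, introns included
    strand: str
    compartment: str  # LSC | SSC | IR
    block: int
    introns: int = 0


# Published per-block gene lists for the 13 locally collinear blocks, plus the
# genes the IR-bearing outgroup retains but the IR-lost clade dropped
# (rps16, infA, ycf1, rps7): 112 distinct names in total.
_TRNA_LEN = 74
_RRN = {"rrn5": 121, "rrn4.5": 103, "rrn23": 2810, "rrn16": 1491}
_PROTEIN_LEN = {
    "psbA": 1062, "matK": 1530, "atpA": 1524, "rpoC2": 4140, "rpoC1": 2052,
    "rpoB": 3213, "psbD": 1062, "psbC": 1386, "psaA": 2253, "psaB": 2205,
    "rbcL": 1428, "accD": 1500, "petA": 963, "ycf4": 555, "ycf3": 507,
    "ycf2": 6837, "ycf1": 4200, "ndhF": 2220, "ndhB": 2211, "ndhD": 1503,
    "ndhA": 1392, "ndhH": 1182, "ccsA": 963, "clpP": 1191, "atpF": 1110,
    "rps16": 1161, "rpl2": 822, "rpl32": 174, "psaC": 246, "ndhE": 306,
    "ndhG": 531, "ndhI": 501, "rps15": 273, "rpl23": 282, "rps2": 711,
}
_FRAGMENT_LEN = {"rps19_fragment": 120, "rps12_5exon": 450, "rps12_3exon": 840}
_INTRONS = {"clpP": 2, "atpF": 1, "rps16": 1, "ndhA": 1, "rps12_3exon": 1}
_INTRON_LEN = 300

_BLOCK_GENES: dict[int, list[str]] = {
    1: ["trnH-GUG", "psbA", "trnK-UUU", "matK"],
    2: ["psbI", "psbK", "trnQ-UUG", "rps16"],
    3: [
        "trnS-GCU", "trnG-UCC", "trnR-UCU", "atpA", "atpF", "atpH", "atpI",
        "rps2", "rpoC2", "rpoC1", "rpoB", "trnC-GCA", "petN", "psbM",
        "trnD-GUC", "trnY-GUA", "trnE-UUC", "trnT-GGU", "psbD", "psbC",
        "trnS-UGA", "psbZ", "trnG-UCC", "trnM-CAU", "rps14", "psaB", "psaA",
        "ycf3", "trnS-GGA",
    ],
    4: ["trnT-UGU", "rps4"],
    5: ["ndhC", "ndhK", "ndhJ", "trnF-GAA", "trnL-UAA"],
    6: ["trnV-UAC", "trnM-CAU", "atpE", "atpB"],
    7: [],  # intergenic block
    8: ["petL", "psbE", "psbF", "psbL", "psbJ", "petA", "cemA", "ycf4",
        "psaI", "accD", "rbcL"],
    9: ["petG", "trnW-CCA", "trnP-UGG", "psaJ", "rpl33", "rps18", "rpl20",
        "rps12_5exon", "clpP"],
    10: ["rps19_fragment", "rpl22", "rps3", "rpl16", "rpl14", "rps8", "infA",
         "rpl36", "rps11", "rpoA", "petD", "petB", "psbH", "psbN", "psbT",
         "psbB"],
    # block 11: SSC genes, then the IR genes that open the repeat
    11: ["ndhF", "rpl32", "trnL-UAG", "ccsA", "ndhD", "psaC", "ndhE", "ndhG",
         "ndhI", "ndhA", "ndhH", "rps15", "ycf1",
         "trnN-GUU", "trnR-ACG", "rrn5", "rrn4.5", "rrn23", "trnA-UGC",
         "trnI-GAU", "rrn16", "trnV-GAC", "rps12_3exon", "rps7", "ndhB",
         "trnL-CAA", "ycf2"],
    12: ["trnI-CAU"],
    13: ["rpl23", "rpl2", "rps19_fragment"],
}
_SSC_GENES = {
    "ndhF", "rpl32", "trnL-UAG", "ccsA", "ndhD", "psaC", "ndhE", "ndhG",
    "ndhI", "ndhA", "ndhH", "rps15", "ycf1",
}
_MINUS_STRAND = {
    "psbA", "matK", "rps16", "rpoC2", "rpoC1", "rpoB", "ndhF", "ndhB",
    "ycf1", "rpl23", "rpl2", "clpP", "petN", "rpl20", "rrn16", "rrn23",
}


def _gene_length(name: str) -> int:
    if name.startswith("trn"):
        return _TRNA_LEN
    if name in _RRN:
        return _RRN[name]
    if name in _FRAGMENT_LEN:
        return _FRAGMENT_LEN[name]
    base = _PROTEIN_LEN.get(name, 600)
    return base + _INTRONS.get(name, 0) * _INTRON_LEN


def _is_protein(name: str) -> bool:
    return not (name.startswith("trn") or name in _RRN or name in _FRAGMENT_LEN)


def default_catalog() -> list[CatalogGene]:
    """The full 13-block catalog (112 distinct gene names)."""
    out: list[CatalogGene] = []
    for block in range(1, 14):
        for name in _BLOCK_GENES[block]:
            if block <= 10:
                compartment = "LSC"
            elif block == 11:
                compartment = "SSC" if name in _SSC_GENES else "IR"
            else:
                compartment = "IR"
            out.append(
                CatalogGene(
                    name=name,
                    length=_gene_length(name),
                    strand="-" if name in _MINUS_STRAND else "+",
                    compartment=compartment,
                    block=block,
                    introns=_INTRONS.get(name, 0),
                )
            )
    return out


def compact_catalog() -> list[CatalogGene]:
    """A small 13-block catalog for fast simulation-heavy testing."""
    keep_lsc = {b: _BLOCK_GENES[b][:2] for b in range(1, 11)}
    out: list[CatalogGene] = []
    for block in range(1, 11):
        for name in keep_lsc[block]:
            out.append(
                CatalogGene(
                    name=name,
                    length=_gene_length(name),
                    strand="-" if name in _MINUS_STRAND else "+",
                    compartment="LSC",
                    block=block,
                    introns=_INTRONS.get(name, 0),
                )
            )
    for name, compartment, block in [
        ("ndhF", "SSC", 11), ("rpl32", "SSC", 11), ("ndhA", "SSC", 11),
        ("rps15", "SSC", 11),
        ("trnN-GUU", "IR", 11), ("rrn16", "IR", 11), ("ndhB", "IR", 11),
        ("trnI-CAU", "IR", 12), ("rpl23", "IR", 13), ("rpl2", "IR", 13),
    ]:
        out.append(
            CatalogGene(
                name=name,
                length=_gene_length(name),
                strand="-" if name in _MINUS_STRAND else "+",
                compartment=compartment,
                block=block,
                introns=_INTRONS.get(name, 0),
            )
        )
    return out


@dataclass(frozen=True)
class AncestorConfig:
    lsc_len: int = 85_000
    ssc_len: int = 15_000
    ir_len: int = 25_000
    gene_catalog: tuple[CatalogGene, ...] = ()
    spacer_len_range: tuple[int, int] = (100, 600)
    seed: int = 1

    def __post_init__(self) -> None:
        if not self.gene_catalog:
            object.__setattr__(self, "gene_catalog", tuple(default_catalog()))
        if self.ir_len < 1000:
            raise ValueError("ir_len must be >= 1000")
        total = self.lsc_len + self.ssc_len + 2 * self.ir_len
        if total > 200_000:
            raise ValueError("total configured length exceeds 200 kb")
        comps = [g.compartment for g in self.gene_catalog]
        if any(c not in {"LSC", "SSC", "IR"} for c in comps):
            raise ValueError("compartments must be LSC, SSC or IR")
        order = {"LSC": 0, "SSC": 1, "IR": 2}
        if [order[c] for c in comps] != sorted(order[c] for c in comps):
            raise ValueError("catalog must list LSC genes, then SSC, then IR")
        if self.spacer_len_range[0] < 1 or self.spacer_len_range[0] > self.spacer_len_range[1]:
            raise ValueError("invalid spacer_len_range")

    @classmethod
    def compact(cls, seed: int = 1) -> "AncestorConfig":
        """Scaled-down config with the compact catalog, spacer average 150."""
        catalog = tuple(compact_catalog())
        spacer = (80, 220)
        avg = sum(spacer) // 2
        sums = {"LSC": 0, "SSC": 0, "IR": 0}
        counts = {"LSC": 0, "SSC": 0, "IR": 0}
        for g in catalog:
            sums[g.compartment] += g.length
            counts[g.compartment] += 1
        return cls(
            lsc_len=sums["LSC"] + avg * (counts["LSC"] + 1),
            ssc_len=sums["SSC"] + avg * (counts["SSC"] + 1),
            ir_len=sums["IR"] + avg * (counts["IR"] + 1),
            gene_catalog=catalog,
            spacer_len_range=spacer,
            seed=seed,
        )


_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """ATG ... stop, internally stop-free, length a multiple of 3."""
    if length % 3 != 0 or length < 9:
        raise ValueError(f"protein gene length {length} not a multiple of 3 (>= 9)")
    ncod = length // 3 - 2
    body = "".join(rng.choice(_SENSE_CODONS) for _ in range(ncod))
    return "ATG" + body + "TAA"


def _spacer_lengths(
    rng: np.random.Generator, count: int, total: int, lo: int, hi: int
) -> list[int]:
    if count == 0:
        if total != 0:
            raise ValueError("spacer budget with no spacers")
        return []
    if total < count:
        raise ValueError(
            f"catalog too large for configured length: only {total} spacer bases "
            f"left for {count} spacers"
        )
    draws = rng.integers(lo, hi + 1, size=count).astype(float)
    scaled = np.floor(draws * (total / draws.sum())).astype(int)
    scaled = np.maximum(scaled, 1)
    scaled[-1] += total - int(scaled.sum())
    if scaled[-1] < 1:
        raise ValueError("catalog too large for configured length")
    return [int(x) for x in scaled]


def _build_compartment(
    rng: np.random.Generator,
    genes: list[CatalogGene],
    target_len: int,
    lo: int,
    hi: int,
    id_prefix: str,
) -> tuple[str, list[Feature]]:
    """spacer + gene + spacer + ... + spacer summing to target_len."""
    gene_total = sum(g.length for g in genes)
    spacers = _spacer_lengths(rng, len(genes) + 1, target_len - gene_total, lo, hi)
    chunks: list[str] = []
    features: list[Feature] = []
    pos = 0
    for idx, g in enumerate(genes):
        chunks.append(_random_dna(rng, spacers[idx]))
        pos += spacers[idx]
        intron_feats: list[tuple[int, int]] = []
        if _is_protein(g.name):
            exonic = g.length - g.introns * _INTRON_LEN
            sense = _random_cds(rng, exonic)
            if g.introns:
                pieces = np.array_split(np.frombuffer(sense.encode(), "S1"), g.introns + 1)
                parts = []
                off = 0
                for pi, piece in enumerate(pieces):
                    txt = piece.tobytes().decode()
                    parts.append(txt)
                    off += len(txt)
                    if pi < g.introns:
                        intron_feats.append((off, off + _INTRON_LEN))
                        parts.append(_random_dna(rng, _INTRON_LEN))
                        off += _INTRON_LEN
                sense = "".join(parts)
        else:
            exonic = g.length - g.introns * _INTRON_LEN
            sense = _random_dna(rng, exonic)
            off = exonic // 2
            for _ in range(g.introns):
                sense = sense[:off] + _random_dna(rng, _INTRON_LEN) + sense[off:]
                intron_feats.append((off, off + _INTRON_LEN))
                off += _INTRON_LEN
        genomic = sense if g.strand == "+" else revcomp(sense)
        chunks.append(genomic)
        fid = f"{id_prefix}{idx}_{g.name}"
        features.append(
            Feature(
                id=fid,
                kind="gene",
                name=g.name,
                start=pos,
                end=pos + g.length,
                strand=g.strand,
                notes={"block": str(g.block)},
            )
        )
        for k, (s, e) in enumerate(intron_feats, start=1):
            # intron offsets are in sense orientation; map to genomic coords
            if g.strand == "+":
                gs, ge = pos + s, pos + e
            else:
                gs, ge = pos + g.length - e, pos + g.length - s
            features.append(
                Feature(
                    id=f"{fid}_intron{k}",
                    kind="intron",
                    name=g.name,
                    start=gs,
                    end=ge,
                    strand=g.strand,
                    notes={"gene": fid, "index": str(k)},
                )
            )
        pos += g.length
    chunks.append(_random_dna(rng, spacers[-1]))
    return "".join(chunks), features


def generate_ancestor(
    config: AncestorConfig,
) -> tuple[GenomeRecord, SyntenyBlockTable]:
    """Build the circular ancestor and its 13-block truth table.

    Layout: LSC | IR_B | SSC | IR_A, so that removing IR_B leaves the blocks
    reading 1..n in order.  IR_B is the exact reverse complement of IR_A;
    bases flanking the repeat copies are pinned so the pair is maximal at
    exactly ``ir_len``.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.spacer_len_range
    lsc_genes = [g for g in config.gene_catalog if g.compartment == "LSC"]
    ssc_genes = [g for g in config.gene_catalog if g.compartment == "SSC"]
    ir_genes = [g for g in config.gene_catalog if g.compartment == "IR"]

    lsc_seq, lsc_feats = _build_compartment(rng, lsc_genes, config.lsc_len, lo, hi, "L")
    ssc_seq, ssc_feats = _build_compartment(rng, ssc_genes, config.ssc_len, lo, hi, "S")
    ira_seq, ira_feats = _build_compartment(rng, ir_genes, config.ir_len, lo, hi, "R")

    lsc_len, ssc_len, ir_len = len(lsc_seq), len(ssc_seq), len(ira_seq)
    assert (lsc_len, ssc_len, ir_len) == (config.lsc_len, config.ssc_len, config.ir_len)
    irb_seq = revcomp(ira_seq)
    seq = list(lsc_seq + irb_seq + ssc_seq + ira_seq)
    n = len(seq)
    irb_start = lsc_len
    ssc_start = irb_start + ir_len
    ira_start = ssc_start + ssc_len

    # pin flanks so the planted IR pair cannot be extended by chance matches
    def _pin(idx: int, partner: int) -> None:
        forbidden = {"A": "T", "C": "G", "G": "C", "T": "A"}[seq[partner % n]]
        if seq[idx % n] == forbidden:
            seq[idx % n] = "A" if forbidden != "A" else "C"

    _pin(irb_start - 1, ira_start + ir_len)  # left of B vs right of A (wraps)
    _pin(irb_start + ir_len, ira_start - 1)  # right of B vs left of A

    features: list[Feature] = list(lsc_feats)
    for f in ssc_feats:
        features.append(f.shifted(ssc_start))
    for f in ira_feats:
        features.append(f.shifted(ira_start))
    # mirrored feature copies inside IR_B
    for f in ira_feats:
        b_end = irb_start + (ir_len - f.start)
        b_start = irb_start + (ir_len - f.end)
        features.append(
            replace(
                f,
                id=f.id + "__B",
                start=b_start,
                end=b_end,
                strand="-" if f.strand == "+" else "+",
                notes={**f.notes, "ir_copy": "B"},
            )
        )
    features.append(
        Feature(
            id="IR_B", kind="IR", name="IR", start=irb_start,
            end=irb_start + ir_len, strand="-", notes={"pair": "IR_A", "copy": "B"},
        )
    )
    features.append(
        Feature(
            id="IR_A", kind="IR", name="IR", start=ira_start,
            end=ira_start + ir_len, strand="+", notes={"pair": "IR_B", "copy": "A"},
        )
    )
    features.sort(key=lambda f: (f.start, f.end))
    genome = GenomeRecord(
        id="ancestor", sequence="".join(seq), topology="circular", features=features
    )

    # truth blocks: gene extents (outside IR_B) grouped by catalog block label.
    # A gene-free block (the intergenic block 7) gets the spacer between its
    # neighbours' gene extents, so all 13 labels appear in the table.
    blocks = list(range(1, max(g.block for g in config.gene_catalog) + 1))
    spans: dict[int, tuple[int, int]] = {}
    for f in genome.features:
        if f.kind != "gene" or f.notes.get("ir_copy") == "B":
            continue
        b = int(f.notes["block"])
        s, e = spans.get(b, (f.start, f.end))
        spans[b] = (min(s, f.start), max(e, f.end))
    for i, b in enumerate(blocks):
        if b in spans:
            continue
        prev_end = spans[blocks[i - 1]][1] if i > 0 else 0
        next_start = (
            spans[blocks[i + 1]][0] if i + 1 < len(blocks) else genome.length
        )
        spans[b] = (prev_end + 1, next_start - 1)
    rows = [
        SyntenyBlockRow(
            block_label=b,
            genome_id=genome.id,
            start=spans[b][0],
            end=spans[b][1],
            strand="+",
        )
        for b in blocks
    ]
    table = SyntenyBlockTable(rows=rows)
    return genome, table


# ---------------------------------------------------------------------------
# scripted events
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Inversion:
    start: int
    end: int


@dataclass(frozen=True)
class IRLoss:
    copy: str  # "A" | "B"


@dataclass(frozen=True)
class GeneLoss:
    name: str


@dataclass(frozen=True)
class IntronLoss:
    gene: str
    intron_index: int = 1


@dataclass(frozen=True)
class Pseudogenize:
    name: str


@dataclass(frozen=True)
class InsertSIR:
    length: int
    positions: tuple[int, int]


@dataclass(frozen=True)
class Translocate:
    start: int
    end: int
    dest: int  # position in the genome after the segment is cut out
    inverted: bool = False


Event = Inversion | IRLoss | GeneLoss | IntronLoss | Pseudogenize | InsertSIR | Translocate
EventScript = list  # ordered list of Event


class ScriptedEventError(ValueError):
    pass


@dataclass
class TruthLog:
    """Resolved record of applied events; replayable on the ancestor."""

    entries: list[dict] = field(default_factory=list)


def _check_span(genome: GenomeRecord, start: int, end: int, what: str) -> None:
    if not (0 <= start < end <= genome.length):
        raise ScriptedEventError(f"{what}: span [{start}, {end}) outside genome")


def _partition_features(
    genome: GenomeRecord, start: int, end: int, what: str
) -> tuple[list[Feature], list[Feature], list[Feature]]:
    """(before, inside, after); error if a feature straddles a boundary."""
    before, inside, after = [], [], []
    for f in genome.features:
        if f.end <= start:
            before.append(f)
        elif f.start >= end:
            after.append(f)
        elif f.start >= start and f.end <= end:
            inside.append(f)
        else:
            raise ScriptedEventError(
                f"{what}: feature {f.id} straddles span boundary [{start}, {end})"
            )
    return before, inside, after


def invert_segment(genome: GenomeRecord, start: int, end: int) -> GenomeRecord:
    _check_span(genome, start, end, "inversion")
    before, inside, after = _partition_features(genome, start, end, "inversion")
    seg = revcomp(genome.sequence[start:end])
    new_inside = [
        replace(
            f,
            start=start + (end - f.end),
            end=start + (end - f.start),
            strand="-" if f.strand == "+" else "+",
        )
        for f in inside
    ]
    feats = sorted(before + new_inside + after, key=lambda f: (f.start, f.end))
    return GenomeRecord(
        id=genome.id,
        sequence=genome.sequence[:start] + seg + genome.sequence[end:],
        topology=genome.topology,
        features=feats,
    )


def _delete(genome: GenomeRecord, start: int, end: int, what: str) -> GenomeRecord:
    """Delete [start, end); drop contained features, shrink containing ones."""
    _check_span(genome, start, end, what)
    length = end - start
    feats: list[Feature] = []
    for f in genome.features:
        if f.end <= start:
            feats.append(f)
        elif f.start >= end:
            feats.append(f.shifted(-length))
        elif f.start >= start and f.end <= end:
            continue
        elif f.start < start and f.end > end:  # deletion strictly inside feature
            feats.append(replace(f, end=f.end - length))
        else:
            raise ScriptedEventError(f"{what}: feature {f.id} straddles deletion")
    return GenomeRecord(
        id=genome.id,
        sequence=genome.sequence[:start] + genome.sequence[end:],
        topology=genome.topology,
        features=feats,
    )


def _in_spacer(genome: GenomeRecord, pos: int) -> bool:
    return all(not (f.start < pos < f.end) for f in genome.features)


def intergenic_position(genome: GenomeRecord, near: int) -> int:
    """The closest position to ``near`` not inside any feature."""
    for delta in range(genome.length):
        for pos in (near + delta, near - delta):
            if 0 <= pos <= genome.length and _in_spacer(genome, pos):
                return pos
    raise ValueError("no intergenic position found")


def _apply_one(
    genome: GenomeRecord, event: Event, rng: np.random.Generator
) -> tuple[GenomeRecord, dict]:
    pre_len = genome.length
    if isinstance(event, Inversion):
        out = invert_segment(genome, event.start, event.end)
        entry = {"op": "inversion", "start": event.start, "end": event.end}
    elif isinstance(event, IRLoss):
        targets = [f for f in genome.features if f.kind == "IR" and f.notes.get("copy") == event.copy]
        if not targets:
            raise ScriptedEventError(f"ir_loss: no IR copy {event.copy!r} in genome")
        ir = targets[0]
        out = _delete(genome, ir.start, ir.end, "ir_loss")
        # the surviving sequence is single-copy now; drop the IR annotations
        out.features = [f for f in out.features if f.kind != "IR"]
        entry = {"op": "ir_loss", "copy": event.copy, "start": ir.start, "end": ir.end}
    elif isinstance(event, GeneLoss):
        spans = sorted(
            [
                (f.start, f.end)
                for f in genome.features
                if f.kind == "gene" and f.name == event.name
            ],
            reverse=True,
        )
        if not spans:
            raise ScriptedEventError(f"gene_loss: no intact gene {event.name!r}")
        out = genome
        for s, e in spans:
            out = _delete(out, s, e, "gene_loss")
        entry = {"op": "gene_loss", "name": event.name, "spans": spans}
    elif isinstance(event, IntronLoss):
        introns = [
            f
            for f in genome.features
            if f.kind == "intron"
            and f.name == event.gene
            and f.notes.get("index") == str(event.intron_index)
        ]
        if not introns:
            raise ScriptedEventError(
                f"intron_loss: gene {event.gene!r} has no intron {event.intron_index}"
            )
        out = genome
        for f in sorted(introns, key=lambda f: -f.start):
            out = _delete(out, f.start, f.end, "intron_loss")
        entry = {
            "op": "intron_loss",
            "gene": event.gene,
            "intron_index": event.intron_index,
            "spans": [(f.start, f.end) for f in introns],
        }
    elif isinstance(event, Pseudogenize):
        genes = [
            f for f in genome.features if f.kind == "gene" and f.name == event.name
        ]
        if not genes:
            raise ScriptedEventError(f"pseudogenize: no intact gene {event.name!r}")
        if not _is_protein(event.name):
            raise ScriptedEventError(
                f"pseudogenize: {event.name!r} is not a protein-coding gene"
            )
        seq = list(genome.sequence)
        edits: list[tuple[int, str]] = []
        feats: list[Feature] = []
        for f in genome.features:
            if f.kind == "gene" and f.name == event.name:
                introns = sorted(
                    (
                        (g.start, g.end)
                        for g in genome.features
                        if g.kind == "intron" and g.notes.get("gene") == f.id
                    )
                )
                exonic = f.length - sum(e - s for s, e in introns)
                codon = (exonic // 3) // 2  # middle codon, sense orientation
                offset = codon * 3
                # map sense offset to genomic position, skipping introns
                if f.strand == "+":
                    pos = f.start
                    remaining = offset
                    for s, e in introns:
                        gap = s - pos
                        if remaining < gap:
                            break
                        remaining -= gap
                        pos = e
                    pos += remaining
                    stop = "TAA"
                    for k, ch in enumerate(stop):
                        edits.append((pos + k, ch))
                else:
                    pos = f.end
                    remaining = offset
                    for s, e in sorted(introns, reverse=True):
                        gap = pos - e
                        if remaining < gap:
                            break
                        remaining -= gap
                        pos = s
                    pos -= remaining
                    stop_rc = "TTA"  # revcomp of TAA
                    for k, ch in enumerate(stop_rc):
                        edits.append((pos - 3 + k, ch))
                feats.append(
                    replace(
                        f,
                        kind="pseudogene",
                        notes={**f.notes, "lesion": f"internal_stop@codon{codon}"},
                    )
                )
            else:
                feats.append(f)
        for pos, ch in edits:
            seq[pos] = ch
        out = GenomeRecord(
            id=genome.id,
            sequence="".join(seq),
            topology=genome.topology,
            features=feats,
        )
        entry = {"op": "pseudogenize", "name": event.name, "edits": edits}
    elif isinstance(event, InsertSIR):
        p1, p2 = sorted(event.positions)
        if p2 - p1 < event.length:
            raise ScriptedEventError("insert_sir: copies would overlap")
        for p in (p1, p2):
            if not (0 <= p <= genome.length) or not _in_spacer(genome, p):
                raise ScriptedEventError(
                    f"insert_sir: position {p} not in intergenic sequence"
                )
        x = _random_dna(rng, event.length)
        out, entry = _insert_sir_resolved(genome, p1, p2, x)
    elif isinstance(event, Translocate):
        out, entry = _translocate(genome, event.start, event.end, event.dest, event.inverted)
    else:
        raise ScriptedEventError(f"unknown event {event!r}")
    entry["pre_length"] = pre_len
    entry["post_length"] = out.length
    return out, entry


def _insert_sir_resolved(
    genome: GenomeRecord, p1: int, p2: int, x: str
) -> tuple[GenomeRecord, dict]:
    length = len(x)
    xrc = revcomp(x)
    seq = genome.sequence[:p1] + x + genome.sequence[p1:p2] + xrc + genome.sequence[p2:]
    seq = list(seq)
    n = len(seq)
    a_start, b_start = p1, p2 + length
    # pin flanks: extensions pair left-of-A with right-of-B and vice versa
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def _pin(idx: int, partner: int) -> None:
        forbidden = comp[seq[partner % n]]
        if seq[idx % n] == forbidden:
            seq[idx % n] = "A" if forbidden != "A" else "C"

    _pin(a_start - 1, b_start + length)
    _pin(a_start + length, b_start - 1)
    feats: list[Feature] = []
    for f in genome.features:
        if f.start >= p2:
            feats.append(f.shifted(2 * length))
        elif f.start >= p1:
            feats.append(f.shifted(length))
        else:
            feats.append(f)
    sid = f"sIR{sum(1 for f in genome.features if f.kind == 'sIR') // 2 + 1}"
    feats.append(
        Feature(
            id=f"{sid}_A", kind="sIR", name=sid, start=a_start,
            end=a_start + length, strand="+", notes={"pair": f"{sid}_B"},
        )
    )
    feats.append(
        Feature(
            id=f"{sid}_B", kind="sIR", name=sid, start=b_start,
            end=b_start + length, strand="-", notes={"pair": f"{sid}_A"},
        )
    )
    feats.sort(key=lambda f: (f.start, f.end))
    out = GenomeRecord(
        id=genome.id, sequence="".join(seq), topology=genome.topology, features=feats
    )
    entry = {"op": "insert_sir", "p1": p1, "p2": p2, "sequence": x}
    return out, entry


def _translocate(
    genome: GenomeRecord, start: int, end: int, dest: int, inverted: bool
) -> tuple[GenomeRecord, dict]:
    _check_span(genome, start, end, "translocate")
    before, inside, after = _partition_features(genome, start, end, "translocate")
    seg = genome.sequence[start:end]
    length = end - start
    rest_seq = genome.sequence[:start] + genome.sequence[end:]
    if not (0 <= dest <= len(rest_seq)):
        raise ScriptedEventError("translocate: dest outside post-cut genome")
    rest_feats = before + [f.shifted(-length) for f in after]
    for f in rest_feats:
        if f.start < dest < f.end:
            raise ScriptedEventError(f"translocate: dest inside feature {f.id}")
    if inverted:
        seg = revcomp(seg)
        moved = [
            replace(
                f,
                start=dest + (end - f.end),
                end=dest + (end - f.start),
                strand="-" if f.strand == "+" else "+",
            )
            for f in inside
        ]
    else:
        moved = [f.shifted(dest - start) for f in inside]
    feats = [f if f.end <= dest else f.shifted(length) for f in rest_feats] + moved
    feats.sort(key=lambda f: (f.start, f.end))
    out = GenomeRecord(
        id=genome.id,
        sequence=rest_seq[:dest] + seg + rest_seq[dest:],
        topology=genome.topology,
        features=feats,
    )
    entry = {
        "op": "translocate", "start": start, "end": end, "dest": dest,
        "inverted": inverted,
    }
    return out, entry


def apply_events(
    genome: GenomeRecord, script: EventScript, seed: int = 0
) -> tuple[GenomeRecord, TruthLog]:
    """Apply scripted events left to right, logging resolved parameters."""
    rng = np.random.default_rng(seed)
    log = TruthLog()
    cur = genome
    for event in script:
        cur, entry = _apply_one(cur, event, rng)
        log.entries.append(entry)
    return cur, log


def replay_truth_log(genome: GenomeRecord, log: TruthLog) -> GenomeRecord:
    """Re-apply a truth log; reproduces the evolved genome exactly."""
    cur = genome
    for e in log.entries:
        op = e["op"]
        if op == "inversion":
            cur = invert_segment(cur, e["start"], e["end"])
        elif op == "ir_loss":
            cur, _ = _apply_one(cur, IRLoss(copy=e["copy"]), np.random.default_rng(0))
        elif op == "gene_loss":
            cur, _ = _apply_one(cur, GeneLoss(name=e["name"]), np.random.default_rng(0))
        elif op == "intron_loss":
            cur, _ = _apply_one(
                cur,
                IntronLoss(gene=e["gene"], intron_index=e["intron_index"]),
                np.random.default_rng(0),
            )
        elif op == "pseudogenize":
            cur, _ = _apply_one(cur, Pseudogenize(name=e["name"]), np.random.default_rng(0))
        elif op == "insert_sir":
            cur, _ = _insert_sir_resolved(cur, e["p1"], e["p2"], e["sequence"])
        elif op == "translocate":
            cur, _ = _translocate(cur, e["start"], e["end"], e["dest"], e["inverted"])
        else:
            raise ValueError(f"unknown log entry {op!r}")
    return cur


# ---------------------------------------------------------------------------
# paired-end read simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadSimConfig:
    n_pairs: int = 1000
    read_len: int = 100
    insert_mean: float = 450.0
    insert_sd: float = 80.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.insert_mean < 2 * self.read_len:
            raise ValueError("insert_mean must be >= 2 * read_len")
        if not (0.0 <= self.error_rate <= 0.05):
            raise ValueError("error_rate must be in [0, 0.05]")


@dataclass(frozen=True)
class ReadPair:
    pair_id: str
    seq1: str
    seq2: str
    frag_start: int  # truth: fragment start on the source genome
    insert: int  # truth: outer fragment length


def simulate_reads(genome: GenomeRecord, config: ReadSimConfig) -> list[ReadPair]:
    """FR (inward-facing) read pairs from uniform circular fragment starts.

    Insert lengths are normal(insert_mean, insert_sd) truncated to
    [2*read_len, genome length]; mate 2 is the reverse complement of the
    fragment end.  Fully deterministic under the config seed.
    """
    n = genome.length
    if n <= config.insert_mean + 6 * config.insert_sd:
        raise ValueError("genome too short for the configured insert distribution")
    rng = np.random.default_rng(config.seed)
    lo, hi = 2 * config.read_len, n
    inserts = np.empty(config.n_pairs, dtype=int)
    filled = 0
    while filled < config.n_pairs:
        draw = np.rint(
            rng.normal(config.insert_mean, config.insert_sd, config.n_pairs - filled)
        ).astype(int)
        ok = draw[(draw >= lo) & (draw <= hi)]
        inserts[filled : filled + len(ok)] = ok
        filled += len(ok)
    starts = rng.integers(0, n, size=config.n_pairs)
    doubled = genome.sequence + genome.sequence
    pairs: list[ReadPair] = []
    for i in range(config.n_pairs):
        s, ins = int(starts[i]), int(inserts[i])
        frag = doubled[s : s + ins]
        m1 = frag[: config.read_len]
        m2 = revcomp(frag[-config.read_len :])
        if config.error_rate > 0:
            m1 = _mutate(rng, m1, config.error_rate)
            m2 = _mutate(rng, m2, config.error_rate)
        pairs.append(ReadPair(f"pair{i}", m1, m2, s, ins))
    return pairs


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for idx in hits:
        cur = arr[idx]
        choices = [b for b in (b"A", b"C", b"G", b"T") if b != cur]
        arr[idx] = choices[int(rng.integers(0, 3))]
    return arr.tobytes().decode()
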