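"""Core domain types for plastome structural-variation analysis.

Coordinates are 0-based half-open everywhere inside the package; the GFF3
serialization in :mod:`plastosv.io` converts to 1-based inclusive on disk.
Circular features that wrap the origin are represented as two sub-interval
:class:`Feature` entries sharing one id (``notes["part"]`` = "1"/"2").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "Feature",
    "GenomeRecord",
    "SyntenyBlockRow",
    "SyntenyBlockTable",
    "LossCharacterMatrix",
    "complement",
    "revcomp",
    "FEATURE_KINDS",
]

FEATURE_KINDS = {"gene", "exon", "intron", "IR", "sIR", "pseudogene"}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def complement(seq: str) -> str:
    """Base-wise complement (A<->T, C<->G; N and unknowns kept verbatim)."""
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Feature:
    """A typed annotation interval on a genome."""

    id: str
    kind: str
    name: str
    start: int
    end: int
    strand: str
    notes: dict = field(default_factory=dict, compare=True)

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"feature {self.id}: strand must be + or -")
        if self.kind == "pseudogene" and "lesion" not in self.notes:
            raise ValueError(
                f"pseudogene {self.id} must record its inactivating lesion in notes"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def shifted(self, offset: int) -> "Feature":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass
class GenomeRecord:
    """A circular or linear DNA sequence with typed features."""

    id: str
    sequence: str
    topology: str = "circular"
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.id}: empty sequence")
        if self.topology not in {"circular", "linear"}:
            raise ValueError(f"genome {self.id}: topology must be circular|linear")
        self.validate()

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        n = self.length
        seen: dict[str, int] = {}
        for f in self.features:
            if f.end > n:
                raise ValueError(
                    f"genome {self.id}: feature {f.id} [{f.start}, {f.end}) "
                    f"outside sequence of length {n}"
                )
            seen[f.id] = seen.get(f.id, 0) + 1
        for fid, count in seen.items():
            if count > 2:
                raise ValueError(f"genome {self.id}: feature id {fid} used {count}x")
            if count == 2:
                parts = {f.notes.get("part") for f in self.features if f.id == fid}
                if parts != {"1", "2"}:
                    raise ValueError(
                        f"genome {self.id}: duplicate feature id {fid} without "
                        "wrap-around part annotation"
                    )

    def feature_by_id(self, fid: str) -> Feature:
        for f in self.features:
            if f.id == fid:
                return f
        raise KeyError(f"genome {self.id}: no feature {fid}")

    def genes(self, include_pseudo: bool = False) -> list[Feature]:
        kinds = {"gene", "pseudogene"} if include_pseudo else {"gene"}
        return [f for f in self.features if f.kind in kinds]

    def subsequence(self, start: int, end: int) -> str:
        """Sequence of [start, end); wraps the origin on circular genomes."""
        n = self.length
        if 0 <= start <= end <= n:
            return self.sequence[start:end]
        if self.topology != "circular":
            raise ValueError(f"interval [{start}, {end}) outside linear genome")
        start %= n
        end %= n
        if start < end:
            return self.sequence[start:end]
        return self.sequence[start:] + self.sequence[:end]


@dataclass(frozen=True)
class SyntenyBlockRow:
    block_label: int
    genome_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.block_label < 1:
            raise ValueError("block labels are positive integers")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"block {self.block_label}@{self.genome_id}: invalid interval"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError("block strand must be + or -")


@dataclass
class SyntenyBlockTable:
    """Locally collinear blocks: one row per (block, genome)."""

    rows: list[SyntenyBlockRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen = set()
        for r in self.rows:
            key = (r.block_label, r.genome_id)
            if key in seen:
                raise ValueError(f"duplicate block row {key}")
            seen.add(key)
        for gid in self.genome_ids():
            rows = sorted(self.rows_for(gid), key=lambda r: r.start)
            for a, b in zip(rows, rows[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping blocks {a.block_label} and {b.block_label} "
                        f"in genome {gid}"
                    )

    def genome_ids(self) -> list[str]:
        out: list[str] = []
        for r in self.rows:
            if r.genome_id not in out:
                out.append(r.genome_id)
        return out

    def rows_for(self, genome_id: str) -> list[SyntenyBlockRow]:
        return [r for r in self.rows if r.genome_id == genome_id]

    def labels_for(self, genome_id: str) -> set[int]:
        return {r.block_label for r in self.rows_for(genome_id)}


@dataclass
class LossCharacterMatrix:
    """Binary presence(1)/loss(0) states with '?' for missing evidence."""

    taxa: list[str]
    characters: list[str]
    states: list[list[str]]

    def __post_init__(self) -> None:
        if len(self.states) != len(self.taxa):
            raise ValueError("state matrix row count != number of taxa")
        for taxon, row in zip(self.taxa, self.states):
            if len(row) != len(self.characters):
                raise ValueError(f"taxon {taxon}: state row length mismatch")
            for s in row:
                if s not in {"0", "1", "?"}:
                    raise ValueError(f"taxon {taxon}: invalid state {s!r}")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxa")
        if len(set(self.characters)) != len(self.characters):
            raise ValueError("duplicate characters")

    def state(self, taxon: str, character: str) -> str:
        return self.states[self.taxa.index(taxon)][self.characters.index(character)]
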