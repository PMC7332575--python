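"""Full comparison pipeline: genomes in, tables out.

Stage order follows the published workflow: classify the inverted repeats,
excise IR_B where a full IR pair is present ("optimal homology assessment"),
build synteny blocks and encode signed permutations against the reference,
compute exact reversal distances, enumerate dispersed repeats on the
IR_B-excised sequences, map irreversible losses on a supplied tree, and
optionally score sIR isomer evidence from read pairs.  Every stage emits one
structured log line with its parameters, and identical inputs plus seed give
byte-identical reports.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

from .dollo import LossMapping, characters_from_genomes, dollo_losses
from .isomers import DEFAULT_INSERT_WINDOW, IsomerEvidence, evaluate_isomers
from .model import GenomeRecord
from .rearrange import DistanceResult, SignedPermutation, reversal_distance
from .repeats import (
    DEFAULT_CRITERIA,
    IRPair,
    RepeatCriteria,
    RepeatHit,
    classify_ir,
    count_unique_genes,
    excise_irb,
    find_repeats,
)
from .simulate import ReadPair
from .synteny import build_blocks, encode_permutation, gene_order

__all__ = [
    "PipelineConfig",
    "ComparisonReport",
    "PipelineStageError",
    "run_comparison",
    "bin_repeats",
    "distance_table",
    "REPEAT_BINS",
]

logger = logging.getLogger("plastosv.pipeline")

# the published size bins leave the 500-1000 bp range unbinned; it is kept as
# an explicit extra column rather than silently merged
REPEAT_BINS = ("30-60bp", "60-100bp", "100-500bp", "500-1000bp", ">1000bp")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, input_id: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed on input {input_id!r}: {cause}")
        self.stage = stage
        self.input_id = input_id


@dataclass
class PipelineConfig:
    genomes: list[GenomeRecord]
    reference_id: str
    repeat_criteria: RepeatCriteria = DEFAULT_CRITERIA
    min_ir_len: int = 10_000
    min_sir_len: int = 30
    insert_window: tuple[int, int] = DEFAULT_INSERT_WINDOW
    origin_gene: str | None = "trnH-GUG"
    tree: dendropy.Tree | None = None
    watch_list: list[tuple[str, object]] | None = None
    reads: dict[str, list[ReadPair]] | None = None
    min_support: int = 1
    out_dir: Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [g.id for g in self.genomes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate genome ids")
        if self.reference_id not in ids:
            raise ValueError(f"reference {self.reference_id!r} not among inputs")
        for value, name in (
            (self.min_ir_len, "min_ir_len"),
            (self.min_sir_len, "min_sir_len"),
        ):
            if value <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ComparisonReport:
    rows: list[dict] = field(default_factory=list)
    permutations: dict[str, SignedPermutation] = field(default_factory=dict)
    distances: dict[str, DistanceResult] = field(default_factory=dict)
    repeat_hits: dict[str, list[RepeatHit]] = field(default_factory=dict)
    repeat_bins: dict[str, dict[str, int]] = field(default_factory=dict)
    ir_pairs: dict[str, list[IRPair]] = field(default_factory=dict)
    loss_mapping: LossMapping | None = None
    isomer_evidence: dict[str, dict[str, IsomerEvidence]] = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def repeat_frame(self) -> pd.DataFrame:
        recs = []
        for gid, bins in self.repeat_bins.items():
            recs.append({"genome_id": gid, "total": sum(bins.values()), **bins})
        return pd.DataFrame(recs)

    def write(self, out_dir: Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.summary_frame().to_csv(out_dir / "summary.tsv", sep="\t", index=False)
        self.repeat_frame().to_csv(out_dir / "repeats.tsv", sep="\t", index=False)
        if self.loss_mapping is not None:
            recs = [
                {
                    "character": c,
                    "event_count": self.loss_mapping.event_count(c),
                    "branches": "; ".join(
                        ",".join(clade) for clade in self.loss_mapping.event_branches[c]
                    ),
                }
                for c in self.loss_mapping.characters
            ]
            pd.DataFrame(recs).to_csv(out_dir / "losses.tsv", sep="\t", index=False)
        if self.isomer_evidence:
            recs = []
            for gid, evs in self.isomer_evidence.items():
                for label, ev in evs.items():
                    recs.append(
                        {
                            "genome_id": gid,
                            "isomer": label,
                            "mapped": ev.mapped_pairs,
                            "filtered": ev.filtered_pairs,
                            "spanning_A": ev.spanning_pairs["A"],
                            "spanning_B": ev.spanning_pairs["B"],
                            "supported": ev.supported,
                        }
                    )
            pd.DataFrame(recs).to_csv(out_dir / "isomers.tsv", sep="\t", index=False)


def bin_repeats(hits: list[RepeatHit]) -> dict[str, int]:
    """Counts per published length bin, plus the explicit 500-1000 bp gap bin."""
    bins = dict.fromkeys(REPEAT_BINS, 0)
    for h in hits:
        if 30 <= h.length < 60:
            bins["30-60bp"] += 1
        elif 60 <= h.length < 100:
            bins["60-100bp"] += 1
        elif 100 <= h.length < 500:
            bins["100-500bp"] += 1
        elif 500 <= h.length < 1000:
            bins["500-1000bp"] += 1
        elif h.length >= 1000:
            bins[">1000bp"] += 1
    return bins


def distance_table(perms: dict[str, SignedPermutation]) -> pd.DataFrame:
    """Breakpoint-graph statistics and exact distance per permutation."""
    recs = []
    for gid, perm in perms.items():
        res = reversal_distance(perm)
        g = res.graph
        recs.append(
            {
                "genome_id": gid,
                "n": g.n,
                "b": g.breakpoints,
                "c": g.cycles,
                "h": g.hurdles,
                "f": g.fortress,
                "d": res.d,
            }
        )
    return pd.DataFrame(recs)


def _stage(stage: str, input_id: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            elapsed = time.perf_counter() - self.t0
            if exc is None:
                logger.info(
                    "stage=%s input=%s elapsed=%.3fs", stage, input_id, elapsed
                )
                return False
            raise PipelineStageError(stage, input_id, exc) from exc

    return _Ctx()


def run_comparison(config: PipelineConfig) -> ComparisonReport:
    """Run the full comparative analysis against the configured reference."""
    logger.info(
        "stage=start reference=%s genomes=%d seed=%d criteria=(%d,%d,%.2f)",
        config.reference_id,
        len(config.genomes),
        config.seed,
        config.repeat_criteria.min_len,
        config.repeat_criteria.max_hamming,
        config.repeat_criteria.min_identity,
    )
    report = ComparisonReport()
    working: dict[str, GenomeRecord] = {}

    for genome in config.genomes:
        with _stage("classify_ir", genome.id):
            pairs = classify_ir(genome, config.min_ir_len, config.min_sir_len)
            report.ir_pairs[genome.id] = pairs
            ir = next((p for p in pairs if p.klass == "IR"), None)
        with _stage("excise_irb", genome.id):
            working[genome.id] = excise_irb(genome, ir) if ir else genome

    ref_work = working[config.reference_id]
    with _stage("gene_order", config.reference_id):
        ref_order = gene_order(ref_work, origin_gene=config.origin_gene)

    for genome in config.genomes:
        gid = genome.id
        if gid == config.reference_id:
            perm = None
            dist = None
        else:
            with _stage("blocks_encode", gid):
                tgt_order = gene_order(working[gid], origin_gene=config.origin_gene)
                table = build_blocks(ref_order, tgt_order)
                perm = encode_permutation(table, config.reference_id, gid)
            with _stage("distance", gid):
                dist = reversal_distance(perm)
                report.permutations[gid] = perm
                report.distances[gid] = dist
        with _stage("repeats", gid):
            hits = find_repeats(working[gid].sequence, config.repeat_criteria)
            report.repeat_hits[gid] = hits
            report.repeat_bins[gid] = bin_repeats(hits)
        ir = next((p for p in report.ir_pairs[gid] if p.klass == "IR"), None)
        sirs = [p for p in report.ir_pairs[gid] if p.klass == "sIR"]
        report.rows.append(
            {
                "genome_id": gid,
                "size_bp": genome.length,
                "ir_bp": ir.length if ir else "n.a.",
                "unique_genes": count_unique_genes(genome),
                "sir_bp": ",".join(str(s.length) for s in sirs) if sirs else "np",
                "permutation": str(perm) if perm is not None else "reference",
                "distance": dist.d if dist is not None else "-",
            }
        )

    if config.tree is not None and config.watch_list:
        with _stage("loss_mapping", "all"):
            matrix = characters_from_genomes(config.genomes, config.watch_list)
            report.loss_mapping = dollo_losses(config.tree, matrix)

    if config.reads:
        by_id = {g.id: g for g in config.genomes}
        for gid, reads in config.reads.items():
            sirs = [p for p in report.ir_pairs[gid] if p.klass == "sIR"]
            if not sirs:
                continue
            with _stage("isomer_evidence", gid):
                # sIR coordinates refer to the un-excised molecule the reads
                # were sequenced from
                report.isomer_evidence[gid] = evaluate_isomers(
                    by_id[gid],
                    sirs[0],
                    reads,
                    window=config.insert_window,
                    min_support=config.min_support,
                )

    if config.out_dir is not None:
        with _stage("write", "all"):
            report.write(config.out_dir)
    logger.info("stage=done genomes=%d", len(config.genomes))
    return report
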