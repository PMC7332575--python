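"""Irreversible-loss (Dollo) mapping of binary characters on a rooted tree.

Gene losses, intron losses, pseudogenizations and IR loss are treated as
irreversible: once a lineage loses the feature it never regains it.  Under
that assumption the minimum-event explanation of the tip states places one
loss on the stem branch of each maximal clade whose sampled leaves all lack
the feature.  The root state is fixed to "present" (the outgroup retains all
features); leaves scored "?" carry no evidence and never create or forbid an
event on their own.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

from .model import GenomeRecord, LossCharacterMatrix

__all__ = [
    "LossMapping",
    "dollo_losses",
    "characters_from_genomes",
    "gene_present",
    "intron_present",
    "ir_present",
]


@dataclass(frozen=True)
class LossMapping:
    """Per character: loss branches, each identified by its child clade."""

    characters: tuple[str, ...]
    event_branches: dict[str, tuple[tuple[str, ...], ...]]

    def event_count(self, character: str) -> int:
        return len(self.event_branches[character])


def dollo_losses(tree: dendropy.Tree, matrix: LossCharacterMatrix) -> LossMapping:
    """Minimal irreversible-loss events explaining each binary character.

    Event branches are the stems of the maximal clades whose leaves are all
    0 or ? and include at least one 0.  Leaves absent from the matrix are
    treated as "?".  If every leaf lacks the character the single event sits
    on the branch subtending the whole tree (identified by the full leaf
    set).  Raises if the matrix names a taxon not present in the tree.
    """
    leaf_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = set(matrix.taxa) - leaf_labels
    if missing:
        raise ValueError(f"matrix taxa absent from tree: {sorted(missing)}")

    branches: dict[str, tuple[tuple[str, ...], ...]] = {}
    for character in matrix.characters:
        states = {
            taxon: matrix.state(taxon, character) for taxon in matrix.taxa
        }
        has_zero: dict[int, bool] = {}
        has_one: dict[int, bool] = {}
        clade: dict[int, list[str]] = {}
        for node in tree.postorder_node_iter():
            nid = id(node)
            if node.is_leaf():
                label = node.taxon.label
                s = states.get(label, "?")
                has_zero[nid] = s == "0"
                has_one[nid] = s == "1"
                clade[nid] = [label]
            else:
                kids = [id(c) for c in node.child_nodes()]
                has_zero[nid] = any(has_zero[k] for k in kids)
                has_one[nid] = any(has_one[k] for k in kids)
                clade[nid] = [x for k in kids for x in clade[k]]
        events: list[tuple[str, ...]] = []
        for node in tree.preorder_node_iter():
            nid = id(node)
            if has_one[nid] or not has_zero[nid]:
                continue
            parent = node.parent_node
            if parent is None or has_one[id(parent)]:
                events.append(tuple(sorted(clade[nid])))
        branches[character] = tuple(sorted(events))
    return LossMapping(
        characters=tuple(matrix.characters), event_branches=branches
    )


# ---------------------------------------------------------------------------
# scoring characters from annotated genomes
# ---------------------------------------------------------------------------


def gene_present(name: str):
    """Predicate: an intact (non-pseudo) gene with this name exists."""

    def _pred(genome: GenomeRecord) -> bool:
        return any(f.kind == "gene" and f.name == name for f in genome.features)

    return _pred


def intron_present(gene: str, index: int = 1):
    """Predicate: the gene still carries its ``index``-th intron."""

    def _pred(genome: GenomeRecord) -> bool:
        return any(
            f.kind == "intron"
            and f.name == gene
            and f.notes.get("index") == str(index)
            for f in genome.features
        )

    return _pred


def ir_present():
    """Predicate: a paired large inverted repeat is annotated."""

    def _pred(genome: GenomeRecord) -> bool:
        return any(
            f.kind == "IR" and "pair" in f.notes for f in genome.features
        )

    return _pred


def characters_from_genomes(
    genomes: list[GenomeRecord],
    watch_list: list[tuple[str, object]],
) -> LossCharacterMatrix:
    """Score genomes against (character name, predicate) pairs: 1 intact, 0 lost."""
    taxa = [g.id for g in genomes]
    characters = [name for name, _ in watch_list]
    states = [
        ["1" if pred(g) else "0" for _, pred in watch_list] for g in genomes
    ]
    return LossCharacterMatrix(taxa=taxa, characters=characters, states=states)
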