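"""Irreversible-loss mapping on a putranjivoid-style tree.

Scores loss characters on a ten-taxon tree shaped like the study system (two
IR-bearing outgroup species, one Lophopyxis-like lineage, seven Drypetes-like
species) and maps each character's minimal set of loss events.
"""

import dendropy

from plastosv.dollo import dollo_losses
from plastosv.model import LossCharacterMatrix

newick = "((Bb,Bp),(Lm,(D1,(D2,(D3,(D4,(D5,(D6,D7))))))));"
tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)

ingroup = ["Lm"] + [f"D{i}" for i in range(1, 8)]
taxa = ["Bb", "Bp"] + ingroup


def states(zeros):
    return [["0" if t in zeros else "1"] for t in taxa]


characters = {
    # the whole ingroup lost the IR: one event on the clade stem
    "IR": set(ingroup),
    # a gene lost in three scattered species: three independent events
    "rpl32": {"D1", "D3", "D5"},
    # a gene lost only in the Drypetes clade: one event
    "ycf2": {f"D{i}" for i in range(1, 8)},
}

for name, zeros in characters.items():
    matrix = LossCharacterMatrix(taxa=taxa, characters=[name], states=states(zeros))
    lm = dollo_losses(tree, matrix)
    branches = [",".join(clade) for clade in lm.event_branches[name]]
    print(f"{name}: {lm.event_count(name)} loss event(s) on: {branches}")

print()
print("Each event branch is named by the clade below it; under irreversibility")
print("the minimum explanation is one loss per maximal all-lost clade.")
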