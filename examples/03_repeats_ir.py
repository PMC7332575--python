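"""Dispersed repeats and IR/sIR classification on planted sequence.

Plants transformed copies of one 45 bp segment into random DNA (as-is,
reverse-complemented, reversed, complemented), runs the maximal repeat finder
with exact matching (30 bp floor, zero mismatches), and classifies the
inverted-repeat structure of a synthetic plastome before and after IR_B
excision.  Every unordered pair among the five copies is reported, each under
the repeat class that relates its two members — e.g. the reversed copy versus
the complemented copy form a palindromic (inverted) pair.
"""

import random

from plastosv.model import complement, revcomp
from plastosv.pipeline import bin_repeats
from plastosv.repeats import RepeatCriteria, classify_ir, excise_irb, find_repeats
from plastosv.simulate import AncestorConfig, generate_ancestor

rng = random.Random(5)
seq = "".join(rng.choice("ACGT") for _ in range(2000))
plant = seq[100:145]
seq = (
    seq[:400] + plant + seq[445:900]
    + revcomp(plant) + seq[945:1400]
    + plant[::-1] + seq[1445:1800]
    + complement(plant) + seq[1845:]
)

hits = find_repeats(seq, RepeatCriteria(30, 0, 1.0))
print("type         pos1  pos2  len  mm  identity")
for h in hits:
    print(f"{h.type:<12} {h.pos1:>5} {h.pos2:>5} {h.length:>4} {h.mismatches:>3}"
          f"  {h.identity:.3f}")
print("bins:", bin_repeats(hits))
print()

genome, _ = generate_ancestor(AncestorConfig.compact(seed=5))
pairs = classify_ir(genome, min_ir_len=3000)
print(f"ancestor ({genome.length} bp):",
      [(p.klass, p.length) for p in pairs])
excised = excise_irb(genome, pairs[0])
print(f"after IR_B excision ({excised.length} bp):",
      [(p.klass, p.length) for p in classify_ir(excised, min_ir_len=3000)] or "no IR")
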