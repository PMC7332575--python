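"""Exact reversal distances for the published block orders.

Feeds the locally-collinear-block permutations of the IR-lost plastomes
(encoded against the conserved outgroup order 1..13) to the breakpoint-graph
engine and prints an optimal inversion scenario for the most rearranged one.
"""

from plastosv.pipeline import distance_table
from plastosv.rearrange import SignedPermutation, optimal_scenario

perms = {
    "Balanops (reference)": SignedPermutation.identity(13),
    "Lophopyxis maingayi": SignedPermutation.from_text(
        "1, 2, 3, 4, -6, -5, 7, 8, 9, 10, -13, 11, 12"
    ),
    "Drypetes (all seven species)": SignedPermutation.from_text(
        "1, 13, -10, 9, -8, 6, 7, -5, -4, 3, -2, 11, -12"
    ),
}

print(distance_table(perms).to_string(index=False))
print()
print("d is the minimum number of inversions back to the reference order;")
print("b/c/h/f are breakpoints, cycles, hurdles, fortress of the breakpoint graph.")
print()

sc = optimal_scenario(perms["Drypetes (all seven species)"])
print(f"One optimal scenario for Drypetes ({len(sc.steps)} inversions):")
for (i, j), state in zip(sc.steps, sc.replay()[1:]):
    print(f"  invert blocks {i + 1}..{j + 1}  ->  {state}")
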