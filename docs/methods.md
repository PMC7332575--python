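# Methods

This note records the models, conventions and numerical choices behind
`plastosv`, in the order the pipeline applies them.

## Reversal distance (the GRIMM-stage reimplementation)

Signed permutations are treated as **linear**, framed by 0 and n+1.  The
framed permutation is doubled (+x → (2x−1, 2x); −x → (2x, 2x−1)); black
edges join consecutive framed positions, gray edges join consecutive values.
The distance is the Hannenhalli–Pevzner formula d = (n+1) − c + h + f with:

- *c*: number of cycles (union-find over black+gray edges);
- component structure: non-trivial gray edges grouped by shared cycle and by
  interval crossing; a gray edge with endpoint positions p, q is *oriented*
  iff p + q is even; a component is unoriented when none of its gray edges
  is oriented;
- *h* (hurdles): unoriented components whose positions are contiguous on the
  circle of framed positions restricted to unoriented-component positions;
- superhurdle: a hurdle whose removal turns another unoriented component
  into a hurdle; *f* = 1 iff the number of hurdles is odd and all of them
  are superhurdles.

The linear convention is adopted because it reproduces the published
distances (3 and 7) from the published block orders; the circular-genome
reading of the same permutations is out of scope and would be a different
model choice.  Correctness is not argued from the formula alone: the
suite checks d against an independent exhaustive search on **all** 4,272
signed permutations with n ≤ 5 and 500 random permutations with n ∈ {6,7,8}.
The oracle uses breadth-first enumeration of the full reversal group for
n ≤ 5 and iterative-deepening search pruned only by the two elementary
admissible bounds ⌈b/2⌉ and (n+1)−c for larger n, so it does not share the
hurdle/fortress machinery with the code it checks.  Fortress configurations
are too large to fall inside the oracle's range; they are covered by the
formula-consistency invariants only.

**Optimal scenarios** apply, at each step, the lexicographically smallest
(i, j) reversal that reduces d by exactly one.  Optimal scenarios are highly
non-unique; the fixed tie-break makes output reproducible, and every emitted
scenario is replayed and re-verified step by step (monotone certificate).

## Synteny blocks and encoding

Blocks are built from **shared single-copy gene anchors**: genes occurring
exactly once in both genomes.  Maximal runs of anchors consecutive in both
genomes with consistent relative orientation collapse into one block; blocks
are numbered 1..n in reference order; anchor-free sequence is absorbed into
the preceding (lower-coordinate) block.  IR-duplicated and otherwise
multi-copy genes never anchor (one copy may survive IR loss, breaking the
1:1 mapping).  Genomes are linearized for encoding at a configurable origin
gene (default *trnH-GUG*, the first gene of reference block 1); if the
origin gene lies on the minus strand the reading direction is flipped first,
so the origin block is always +1.

Limit: a block that contains no genes (the published segmentation has one
purely intergenic block) cannot be recovered from gene anchors and is
absorbed into its left neighbour; reproducing a published segmentation that
includes such a block requires importing the block table (supported) rather
than rebuilding it.

## Repeat finding

A hit is a **maximal** window pair under a Hamming budget: extending one
base left or right (where defined) would exceed `max_hamming`.  The second
copy is compared as-is (forward), reverse-complemented (palindromic),
reversed (reverse) or complemented in place (complement); each unordered
occurrence pair is reported once with pos1 ≤ pos2 (strictly for forward).
Bases outside {A,C,G,T} never match, themselves included.  Defaults follow
the two published survey settings: (min 30 bp, Hamming 3, identity ≥ 0.90)
and (min 30 bp, exact).

Detection seeds on exact k-mers of length ⌈(min_len − k)/(k + 1)⌉ — the
pigeonhole bound including the mismatch correction, without which a window
of `min_len` whose longest exact run is one shorter than `min_len/(k+1)`
could be missed — merges seed chains into maximal exact runs, and extends
each run across up to k+1 mismatches per side, enumerating every mismatch
allocation.  This is exact, not heuristic; the test suite proves hit-set
equality against a full per-diagonal brute-force scan on random and planted
sequences, and re-verifies every reported hit by direct string comparison.

Counting convention: maximal hits, one record per unordered pair.  Published
repeat **counts** from nested-repeat-prone tools are tool-dependent and are
not a target; only the criteria semantics are.  Report bins follow the
published length classes (30–60, 60–100, 100–500, >1000 bp) plus an explicit
`500-1000bp` column for the range the published bins omit, so totals always
conserve.

## IR classification and IR_B excision

IR copies in real plastomes are identical, so IR/sIR classification demands
**exact** inverted-repeat pairs with disjoint spans (scanning across the
origin on circular genomes): the longest pair ≥ `min_ir_len` (default
10,000 bp) is the IR; remaining pairs ≥ `min_sir_len` (default 30 bp,
lowerable to 11) are sIRs.  Which copy is "B" is positional in the
literature; the pinned convention here is *the copy followed by the shorter
single-copy stretch* (the SSC-like gap), so that excision leaves the genome
reading LSC, SSC, IR — the reference block order.  Excision drops features
inside B and shifts downstream coordinates; a feature straddling the
boundary is an error rather than a silent truncation.

## The synthetic-data generator

The generator emulates the canonical quadripartite plastome at the study's
scale: LSC 85 kb, SSC 15 kb, IR 25 kb (150 kb total), with a built-in gene
catalog that mirrors the published 13-block gene content — blocks 1–10 in
the LSC, block 11 spanning SSC plus the head of the IR, blocks 12–13 inside
the IR, block 7 gene-free — and 112 distinct gene names, the unique-gene
count reported for the IR-bearing outgroup.  Genes use approximate real
lengths where they matter (rRNAs, the large open reading frames) and 600 bp
otherwise; five genes carry introns (300 bp each).  Layout is
LSC | IR_B | SSC | IR_A with IR_B the exact reverse complement of IR_A, so
the IR_B-excised genome reads blocks 1..13 in order.

Spacers and gene bodies are i.i.d. uniform random DNA (protein genes get an
enforced ATG…stop frame free of internal stops), so *the only repeats are
scripted ones* and planted-repeat tests are exact.  The single base flanking
each planted IR/sIR copy is pinned to break chance extensions, making
maximal-hit lengths equal planted lengths deterministically.  Spacer lengths
are drawn from the configured range and then scaled to meet the compartment
budget exactly (so tight gene-dense compartments may compress spacers below
the nominal minimum).

What the generator does **not** emulate: nucleotide substitution along
branches, codon usage, indel sequencing error, real intergenic repeat
content.  Passing tests therefore demonstrate correctness of the method's
logic on clean signals, not robustness to alignment ambiguity in real data.

Scripted events apply left to right with coordinates validated against the
evolving genome; inversions and translocations must cut intergenic sequence
(a scripted cut through a feature is an error).  `ir_loss` removes the named
copy's full span and drops the IR annotations (the survivor is single-copy
sequence).  `pseudogenize` writes TAA over the middle codon, strand-aware,
and records the lesion.  Every applied event is logged with resolved
parameters (including the generated sIR sequence), and replaying the log on
the ancestor reproduces the evolved genome byte for byte.

Read simulation is FR (inward-facing): fragment starts uniform on the
circle, insert length normal(μ, σ) truncated to [2·read_len, genome length],
mate 2 the reverse complement of the fragment end.  Defaults
(read_len 100, μ 450, σ 80, error 0) are chosen so the published 330–600 bp
insert filter retains most pairs while leaving room for pairs to bracket a
271 bp repeat; the study's own libraries are described only as short-insert,
so these are generator conventions, not estimates of the real libraries.

## Isomer evidence

"Read pairs spanning the entire sIR" is formalized as an interval predicate:
one mate ends at or before the copy's start, the other starts at or after
its end, the pair properly oriented with insert inside the window (both ends
inclusive — "between 330 and 600" is read inclusively and the boundary
semantics are pinned by test).  The internal mapper is exact-match only and
requires a unique inward-facing placement; reads landing entirely inside an
sIR copy are ambiguous between the copies and drop out, which is the
behaviour a real mapper's uniqueness filter approximates.  `min_support`
defaults to 1: the published claim is existence, not abundance.  Noisy real
data should enter through the SAM ingest path instead of the internal
mapper.

## Dollo loss mapping

The root state is fixed to "present" (the outgroup retains all features).
For each binary character the event branches are the stems of the maximal
clades whose sampled leaves are all 0 or ? and include at least one 0 — the
minimum set of irreversible losses explaining the tips.  "?" carries no
evidence: it joins a loss clade for free and never creates an event.  Two
degenerate cases are pinned: an all-0 character yields one event on the
branch subtending the whole tree (identified by the full leaf set), and
pseudogenes score 0 alongside physical losses (the published event map
groups "gene losses or pseudogenes"; callers who want them separate can
score their own watch list).  Minimality is tested against brute-force
enumeration of branch subsets on random 8-leaf trees.

## Problem sizes used in testing

Simulation-heavy properties run on a scaled-down ancestor (compact 13-block
catalog, ~27 kb, IR ≈ 6 kb) — the properties checked (distance bounds,
classification truth, count arithmetic) are scale-free, and the full-size
150 kb default is exercised directly where the quantity depends on the full
catalog (the 112 unique genes, IR classification at 25 kb).  The pipeline
recovery property runs 100 seeded scenarios of up to 6 boundary inversions
with optional IR loss, gene losses and pseudogenization; the repeat-finder
oracle runs on 50 random sequences up to ~1.2 kb plus planted fixtures at
the published criteria; the Dollo oracle covers 200 random 8-leaf cases.

## Known limitations

- Linear (not circular) permutation model, as discussed above.
- Fortress detection follows the standard classification but is outside the
  exhaustive oracle's reach; no natural plastome data set is expected to
  produce one.
- The repeat finder indexes every k-mer; highly repetitive (low-complexity)
  real sequence would inflate seed lists.  Synthetic inputs are uniform
  random, where expected seed density is n²/4^k.
- The internal read mapper is exact-match; sequencing error above zero
  reduces mappable pairs rather than placing them approximately.
- `excise_irb` and `flip_isomer` require the relevant copies not to wrap the
  origin; rotate the genome first if they do.
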