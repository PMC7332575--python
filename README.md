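# plastosv

Comparative structural-variation analysis of plastid genomes (plastomes),
built for the study design where a clade that has **lost one copy of the
large Inverted Repeat (IR)** is compared against IR-bearing relatives:
detect and excise the IR, encode each genome's synteny-block order as a
signed permutation, compute **exact genome rearrangement distances**,
enumerate dispersed repeats, confirm short-inverted-repeat (sIR) flip-flop
isomers from paired-end reads, and map irreversible losses onto a phylogeny.

The intended users are organellar-genomics researchers who today chain
together progressiveMauve, GRIMM, REPuter, Bowtie2/SAMtools and manual event
mapping; `plastosv` reimplements the analytical core of that chain as one
tested, scriptable Python library, exercised end to end on synthetic
plastomes with known ground truth.

## The model at the core

A plastome is compared to a reference through its locally collinear blocks
(LCBs): blocks are numbered 1..n along the reference, and the target genome
is written as a signed permutation π, the block labels in target order with
sign given by strand ("strand orientation determines the sign").  The
minimum number of inversions transforming π into the identity is computed
exactly by Hannenhalli–Pevzner breakpoint-graph theory:

    d(π) = (n + 1) − c(π) + h(π) + f(π)

where *c* counts cycles of the breakpoint graph of π framed by 0 and n+1,
*h* counts hurdles (unoriented components that are circularly contiguous
among unoriented-component positions) and *f* flags a fortress.  An optimal
scenario is built greedily: at each step the lexicographically smallest
reversal that lowers *d* by one is applied — HP theory guarantees one
exists.  The engine is verified against an exhaustive search oracle on every
signed permutation with n ≤ 5 and hundreds of random larger ones.

Around that core the package implements, as separate modules:

| module      | what it does |
|-------------|--------------|
| `model`/`io`| genome/feature/block/matrix types; FASTA+GFF3, TSV, Newick, FASTQ |
| `simulate`  | synthetic quadripartite ancestors (LSC/SSC/IR, 13-block, 112-gene catalog), scripted inversions/losses/pseudogenizations/sIR insertions with a replayable truth log, paired-end read simulation |
| `repeats`   | maximal dispersed repeats (forward/palindromic/reverse/complement, Hamming tolerance), IR/sIR classification, IR_B excision, unique-gene counting |
| `synteny`   | synteny blocks from shared single-copy gene anchors; signed-permutation encoding |
| `rearrange` | breakpoint graph, exact distance, optimal scenarios, exhaustive oracle |
| `isomers`   | sIR flip-flop isomer construction; read-pair spanning evidence with the 330–600 bp insert filter |
| `dollo`     | irreversible-loss (Dollo) event mapping on rooted trees |
| `pipeline`  | orchestration, Table-style reports, repeat-length binning |

## Worked example

```bash
python examples/01_reversal_distance.py
```

prints (abridged):

```
                   genome_id  n  b  c  h  f  d
        Balanops (reference) 13  0 14  0  0  0
         Lophopyxis maingayi 13  5 11  0  0  3
Drypetes (all seven species) 13 11  7  0  0  7

One optimal scenario for Drypetes (7 inversions):
  invert blocks 2..11  ->  1, 2, -3, 4, 5, -7, -6, 8, -9, 10, -13, 11, -12
  ...
  invert blocks 11..12  ->  1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13
```

Reading it: the conserved outgroup order is the identity (no breakpoints, 14
cycles, distance 0); the Lophopyxis-like block order is 3 inversions away;
the block order shared by all seven *Drypetes* species needs a minimum of 7
inversions, and the printed scenario is one verified optimal route back to
the reference order.  The other examples cover the synthetic end-to-end
pipeline (`02`), repeat finding and IR excision (`03`), isomer read-pair
evidence (`04`) and Dollo loss mapping (`05`).

A thin CLI wraps the same functions:

```bash
plastosv distance perms.txt          # TSV: genome_id, n, b, c, h, f, d
plastosv scenario perms.txt Drypetes
plastosv simulate --compact --seed 1 --out ancestor.fasta
plastosv run ancestor.fasta evolved.fasta --reference ancestor --out-dir out/
```

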