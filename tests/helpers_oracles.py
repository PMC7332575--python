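"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives the quantity a library routine computes, by a
different (slow, obviously-correct) route, so agreement is evidence the fast
path is right.
"""

from __future__ import annotations

import itertools
import random

from plastosv.model import complement, revcomp

ACGT = set("ACGT")


def brute_force_repeats(seq: str, crit, types=("forward", "palindromic", "reverse", "complement")):
    """All maximal repeat pairs by full per-diagonal scanning (no seeding)."""
    seq = seq.upper()
    n = len(seq)
    k = crit.max_hamming
    out = set()
    for rtype in types:
        if rtype == "forward":
            other = seq
        elif rtype == "palindromic":
            other = revcomp(seq)
        elif rtype == "reverse":
            other = seq[::-1]
        else:
            other = complement(seq)
        m = len(other)
        pair_like = rtype in ("forward", "complement")
        diagonals = range(1, m) if pair_like else range(-(n - 1), m)
        for d in diagonals:
            lo, hi = max(0, -d), min(n, m - d)
            if hi - lo < crit.min_len:
                continue
            mismatches = [
                t
                for t in range(lo, hi)
                if not (seq[t] == other[t + d] and seq[t] in ACGT)
            ]
            r = len(mismatches)
            fenced = [lo - 1] + mismatches + [hi]
            windows = set()
            for t in range(0, max(0, r - k) + 1):
                ws = fenced[t] + 1
                we = fenced[t + k + 1] if t + k + 1 <= r else hi
                windows.add((ws, we, min(k, r - t)))
            for ws, we, mm in windows:
                length = we - ws
                if length < crit.min_len:
                    continue
                if (length - mm) / length < crit.min_identity:
                    continue
                if pair_like:
                    p1, p2 = ws, ws + d
                else:
                    p1 = ws
                    p2 = n - (ws + d) - length
                    if p2 < p1:
                        continue
                out.add((rtype, p1, p2, length, mm))
    return out


def hit_key_set(hits):
    return {(h.type, h.pos1, h.pos2, h.length, h.mismatches) for h in hits}


def verify_hit_by_string(seq: str, hit) -> bool:
    """Re-check a reported hit by direct string comparison."""
    seq = seq.upper()
    a = seq[hit.pos1 : hit.pos1 + hit.length]
    b = seq[hit.pos2 : hit.pos2 + hit.length]
    if hit.type == "forward":
        pass
    elif hit.type == "palindromic":
        b = revcomp(b)
    elif hit.type == "reverse":
        b = b[::-1]
    else:
        b = complement(b)
    mm = sum(
        1 for x, y in zip(a, b) if not (x == y and x in ACGT)
    )
    return mm == hit.mismatches


def random_signed_permutation(rng: random.Random, n: int):
    labels = list(range(1, n + 1))
    rng.shuffle(labels)
    return tuple(x if rng.random() < 0.5 else -x for x in labels)


# ---------------------------------------------------------------------------
# Dollo brute force
# ---------------------------------------------------------------------------


def brute_force_dollo(tree, states: dict[str, str]) -> int:
    """Minimum number of irreversible-loss branches explaining the tips.

    Enumerates every subset of branches (including the root stem), keeping
    subsets under which each 0-leaf lies below exactly one loss branch, no
    1-leaf lies below any, and ?-leaves are unconstrained.
    """
    nodes = list(tree.preorder_node_iter())
    below: list[set[str]] = []
    for node in nodes:
        below.append({leaf.taxon.label for leaf in node.leaf_iter()})
    zero = {t for t, s in states.items() if s == "0"}
    one = {t for t, s in states.items() if s == "1"}

    def valid(chosen: list[set[str]]) -> bool:
        for t in one:
            if any(t in c for c in chosen):
                return False
        for t in zero:
            if sum(1 for c in chosen if t in c) != 1:
                return False
        return True

    # enumerate branch subsets by increasing size; never need more branches
    # than there are 0-leaves
    for size in range(0, len(zero) + 1):
        for combo in itertools.combinations(range(len(nodes)), size):
            if valid([below[i] for i in combo]):
                return size
    raise AssertionError("no consistent loss assignment found")


def random_tree(rng: random.Random, leaves: list[str]):
    """A random rooted binary tree over the given leaf labels (newick text)."""
    items = [f"{name}" for name in leaves]
    rng.shuffle(items)
    while len(items) > 1:
        i = rng.randrange(len(items))
        a = items.pop(i)
        j = rng.randrange(len(items))
        b = items.pop(j)
        items.append(f"({a},{b})")
    return items[0] + ";"
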