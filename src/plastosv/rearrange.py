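"""Exact sorting-by-reversals machinery for signed permutations.

Locally collinear blocks of two plastomes, encoded as a signed permutation
relative to a reference, are compared here with the classical
Hannenhalli-Pevzner breakpoint-graph theory: the minimum number of reversals
(inversions) transforming the permutation into the identity is

    d = (n + 1) - c + h + f

where ``c`` counts cycles of the breakpoint graph of the permutation framed by
0 and n+1, ``h`` counts hurdles (unoriented components that are circularly
contiguous among unoriented-component positions), and ``f`` flags a fortress
(an odd number of hurdles, all of them superhurdles).  Permutations are
treated as linear, framed by 0 and n+1; this is the convention under which the
block orders printed for IR-lost plastomes reproduce their published
rearrangement distances.

An independent exhaustive search (:func:`exhaustive_distance`) is provided as
a test oracle for small ``n``; it never consults the hurdle/fortress logic
beyond two elementary admissible lower bounds.
"""

from __future__ import annotations

import functools
from collections import deque
from dataclasses import dataclass, field

__all__ = [
    "SignedPermutation",
    "BreakpointGraph",
    "DistanceResult",
    "ReversalScenario",
    "apply_reversal",
    "build_breakpoint_graph",
    "reversal_distance",
    "optimal_scenario",
    "exhaustive_distance",
]


@dataclass(frozen=True)
class SignedPermutation:
    """An ordering of the block labels 1..n with signs encoding strand."""

    labels: tuple[int, ...]

    def __post_init__(self) -> None:
        labels = tuple(int(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        n = len(labels)
        if n == 0:
            raise ValueError("empty permutation")
        seen = set()
        for x in labels:
            if x == 0:
                raise ValueError("0 is not a valid signed block label")
            if abs(x) in seen:
                raise ValueError(f"duplicate block label |{x}|")
            seen.add(abs(x))
        missing = set(range(1, n + 1)) - seen
        if missing:
            raise ValueError(
                "labels must cover 1..n exactly; missing "
                + ", ".join(str(m) for m in sorted(missing))
            )

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def is_identity(self) -> bool:
        return self.labels == tuple(range(1, self.n + 1))

    @classmethod
    def identity(cls, n: int) -> "SignedPermutation":
        return cls(tuple(range(1, n + 1)))

    @classmethod
    def from_text(cls, text: str) -> "SignedPermutation":
        """Parse the printed comma-separated form, e.g. ``"1, -3, 2"``."""
        parts = [p for p in text.replace(",", " ").split() if p]
        try:
            labels = tuple(int(p) for p in parts)
        except ValueError as exc:
            raise ValueError(f"malformed permutation text: {text!r}") from exc
        return cls(labels)

    def __str__(self) -> str:
        return ", ".join(str(x) for x in self.labels)

    def __iter__(self):
        return iter(self.labels)


def apply_reversal(perm: SignedPermutation, i: int, j: int) -> SignedPermutation:
    """Reverse the segment ``i..j`` (inclusive) and flip its signs."""
    if not (0 <= i <= j < perm.n):
        raise IndexError(f"reversal indices ({i}, {j}) out of range for n={perm.n}")
    return SignedPermutation(_reverse(perm.labels, i, j))


def _reverse(labels: tuple[int, ...], i: int, j: int) -> tuple[int, ...]:
    seg = tuple(-x for x in labels[i : j + 1][::-1])
    return labels[:i] + seg + labels[j + 1 :]


# ---------------------------------------------------------------------------
# breakpoint graph
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BreakpointGraph:
    """Summary statistics of the framed, doubled breakpoint graph."""

    n: int
    breakpoints: int
    cycles: int
    oriented_components: int
    unoriented_components: int
    hurdles: int
    fortress: int
    framed_doubled: tuple[int, ...] = field(repr=False)


def _framed_doubled(labels: tuple[int, ...]) -> list[int]:
    """0, L(x1), R(x1), ..., L(xn), R(xn), 2n+1 with +x -> (2x-1, 2x)."""
    u = [0]
    for x in labels:
        if x > 0:
            u.append(2 * x - 1)
            u.append(2 * x)
        else:
            u.append(-2 * x)
            u.append(-2 * x - 1)
    u.append(2 * len(labels) + 1)
    return u


class _UnionFind:
    def __init__(self, size: int) -> None:
        self.parent = list(range(size))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _cycles_breakpoints(labels: tuple[int, ...]) -> tuple[int, int]:
    """(c, b): cycle count of the breakpoint graph and breakpoint count."""
    n = len(labels)
    u = _framed_doubled(labels)
    uf = _UnionFind(2 * n + 2)
    b = 0
    for i in range(n + 1):
        a, z = u[2 * i], u[2 * i + 1]  # black edge
        uf.union(a, z)
        lo, hi = (a, z) if a < z else (z, a)
        if not (lo % 2 == 0 and hi == lo + 1):
            b += 1
    for v in range(n + 1):  # gray edges join values 2v and 2v+1
        uf.union(2 * v, 2 * v + 1)
    c = len({uf.find(v) for v in range(2 * n + 2)})
    return c, b


def _circularly_contiguous(labels_seq: list[int], target: int) -> bool:
    """True if all occurrences of target form one circular run of labels_seq."""
    m = len(labels_seq)
    transitions = 0
    for k in range(m):
        if labels_seq[k] == target and labels_seq[(k + 1) % m] != target:
            transitions += 1
    return transitions <= 1


def build_breakpoint_graph(perm: SignedPermutation) -> BreakpointGraph:
    labels = perm.labels
    n = len(labels)
    u = _framed_doubled(labels)
    pos = [0] * (2 * n + 2)
    for idx, v in enumerate(u):
        pos[v] = idx

    c, b = _cycles_breakpoints(labels)

    # Cycle identity per value via black+gray union-find (recomputed small).
    uf = _UnionFind(2 * n + 2)
    for i in range(n + 1):
        uf.union(u[2 * i], u[2 * i + 1])
    for v in range(n + 1):
        uf.union(2 * v, 2 * v + 1)

    # Non-trivial gray edges: (interval on positions, orientation, cycle id).
    gray = []
    for v in range(n + 1):
        p, q = pos[2 * v], pos[2 * v + 1]
        lo, hi = (p, q) if p < q else (q, p)
        trivial = hi == lo + 1 and lo % 2 == 0  # gray parallel to a black edge
        if trivial:
            continue
        oriented = (p + q) % 2 == 0
        gray.append((lo, hi, oriented, uf.find(2 * v)))

    # Components: gray edges of one cycle together; crossing intervals merge.
    m = len(gray)
    comp_uf = _UnionFind(m)
    cycle_first: dict[int, int] = {}
    for e in range(m):
        cyc = gray[e][3]
        if cyc in cycle_first:
            comp_uf.union(cycle_first[cyc], e)
        else:
            cycle_first[cyc] = e
    for e1 in range(m):
        lo1, hi1 = gray[e1][0], gray[e1][1]
        for e2 in range(e1 + 1, m):
            lo2, hi2 = gray[e2][0], gray[e2][1]
            if lo1 < lo2 < hi1 < hi2 or lo2 < lo1 < hi2 < hi1:
                comp_uf.union(e1, e2)

    comp_oriented: dict[int, bool] = {}
    comp_positions: dict[int, list[int]] = {}
    for e in range(m):
        root = comp_uf.find(e)
        comp_oriented[root] = comp_oriented.get(root, False) or gray[e][2]
        comp_positions.setdefault(root, []).extend((gray[e][0], gray[e][1]))

    oriented_components = sum(1 for o in comp_oriented.values() if o)
    unoriented = [r for r, o in comp_oriented.items() if not o]

    # Hurdles: project positions of unoriented components on the circle of
    # framed positions; a component whose entries form one circular block is a
    # hurdle.  A hurdle is a superhurdle when deleting it turns some other
    # unoriented component into a hurdle.
    tagged = sorted(
        (p, r) for r in unoriented for p in comp_positions[r]
    )
    seq = [r for _, r in tagged]
    hurdles = [r for r in unoriented if _circularly_contiguous(seq, r)]
    hurdle_set = set(hurdles)
    fortress = 0
    if hurdles and len(hurdles) % 2 == 1 and len(unoriented) > len(hurdles):
        all_super = True
        for hrd in hurdles:
            reduced = [r for r in seq if r != hrd]
            protects = any(
                _circularly_contiguous(reduced, r)
                for r in unoriented
                if r not in hurdle_set
            )
            if not protects:
                all_super = False
                break
        fortress = 1 if all_super else 0

    return BreakpointGraph(
        n=n,
        breakpoints=b,
        cycles=c,
        oriented_components=oriented_components,
        unoriented_components=len(unoriented),
        hurdles=len(hurdles),
        fortress=fortress,
        framed_doubled=tuple(u),
    )


@dataclass(frozen=True)
class DistanceResult:
    d: int
    graph: BreakpointGraph


def reversal_distance(perm: SignedPermutation) -> DistanceResult:
    """Exact minimum number of reversals sorting ``perm`` to the identity."""
    g = build_breakpoint_graph(perm)
    d = (g.n + 1) - g.cycles + g.hurdles + g.fortress
    return DistanceResult(d=d, graph=g)


def _distance_labels(labels: tuple[int, ...]) -> int:
    return reversal_distance(SignedPermutation(labels)).d


# ---------------------------------------------------------------------------
# optimal scenario
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReversalScenario:
    """An ordered list of (i, j) reversals sorting a permutation."""

    source: SignedPermutation
    steps: tuple[tuple[int, int], ...]

    def replay(self) -> list[SignedPermutation]:
        """All intermediate permutations, ending at the identity."""
        out = [self.source]
        cur = self.source
        for i, j in self.steps:
            cur = apply_reversal(cur, i, j)
            out.append(cur)
        return out


def optimal_scenario(perm: SignedPermutation) -> ReversalScenario:
    """A minimum-length reversal scenario sorting ``perm`` to the identity.

    Greedy certificate construction: at each step the lexicographically
    smallest reversal (i, j) that lowers the exact distance by one is applied;
    Hannenhalli-Pevzner theory guarantees such a reversal exists whenever
    d > 0, so the loop terminates after exactly d steps.
    """
    steps: list[tuple[int, int]] = []
    cur = perm
    d = reversal_distance(cur).d
    while d > 0:
        found = False
        for i in range(cur.n):
            for j in range(i, cur.n):
                nxt = apply_reversal(cur, i, j)
                if reversal_distance(nxt).d == d - 1:
                    steps.append((i, j))
                    cur = nxt
                    d -= 1
                    found = True
                    break
            if found:
                break
        if not found:  # pragma: no cover - impossible by HP theory
            raise RuntimeError("no distance-reducing reversal found")
    return ReversalScenario(source=perm, steps=tuple(steps))


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------

_MAX_ORACLE_N = 8
_BFS_MAX_N = 5


@functools.lru_cache(maxsize=None)
def _bfs_table(n: int) -> dict[tuple[int, ...], int]:
    """Distance from the identity to every signed permutation (n small)."""
    ident = tuple(range(1, n + 1))
    dist = {ident: 0}
    frontier = deque([ident])
    moves = [(i, j) for i in range(n) for j in range(i, n)]
    while frontier:
        cur = frontier.popleft()
        d = dist[cur]
        for i, j in moves:
            nxt = _reverse(cur, i, j)
            if nxt not in dist:
                dist[nxt] = d + 1
                frontier.append(nxt)
    return dist


def _elementary_lower_bound(labels: tuple[int, ...]) -> int:
    """max(ceil(b/2), (n+1)-c): admissible, independent of hurdle theory."""
    n = len(labels)
    c, b = _cycles_breakpoints(labels)
    return max((b + 1) // 2, (n + 1) - c)


def exhaustive_distance(perm: SignedPermutation) -> int:
    """True reversal distance by exhaustive search (test oracle, n <= 8).

    Breadth-first enumeration of the whole reversal group for n <= 5;
    iterative-deepening depth-first search for 6 <= n <= 8, pruned only by the
    two elementary lower bounds ceil(b/2) and (n+1)-c (each reversal removes
    at most two breakpoints and raises the cycle count by at most one).
    """
    n = perm.n
    if n > _MAX_ORACLE_N:
        raise ValueError(f"exhaustive oracle limited to n <= {_MAX_ORACLE_N}")
    labels = perm.labels
    if n <= _BFS_MAX_N:
        return _bfs_table(n)[labels]

    ident = tuple(range(1, n + 1))
    moves = [(i, j) for i in range(n) for j in range(i, n)]
    lb0 = _elementary_lower_bound(labels)

    def dfs(cur: tuple[int, ...], remaining: int, memo: dict) -> bool:
        if cur == ident:
            return True
        if remaining <= 0:
            return False
        if memo.get(cur, -1) >= remaining:
            return False
        children = []
        for i, j in moves:
            nxt = _reverse(cur, i, j)
            lb = _elementary_lower_bound(nxt)
            if lb <= remaining - 1:
                children.append((lb, nxt))
        children.sort(key=lambda t: t[0])
        for _, nxt in children:
            if dfs(nxt, remaining - 1, memo):
                return True
        memo[cur] = remaining
        return False

    depth = lb0
    while True:
        if dfs(labels, depth, {}):
            return depth
        depth += 1
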