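"""Exhaustive census of short loops (simple cycles of length 3-6).

A loop is a closed path without repeating nodes or edges, treated as an
unoriented, unrooted subgraph.  The census uses a depth-first search bounded
by loop length: paths are rooted at their lexicographically smallest node,
extended only through larger identifiers, and a cycle is recorded exactly
once by fixing the traversal direction (second node smaller than last).
Neighbours are visited in sorted order, so the enumeration is deterministic.

Loop lengths are capped at six by design: beyond that the counts in real
interaction networks explode combinatorially (length-6 counts already reach
1e9 in dense networks) and the biological reading as a small functional
motif is lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .network import InteractionNetwork

__all__ = [
    "Loop",
    "LoopCensus",
    "canonical_form",
    "count_loops",
    "enumerate_loops",
    "brute_force_census",
    "MIN_LOOP_LEN",
    "MAX_LOOP_LEN",
]

Loop = tuple[str, ...]

MIN_LOOP_LEN = 3
MAX_LOOP_LEN = 6

#: above this many retained loops per length the census keeps counts only
DEFAULT_ENUMERATION_CAP = 10_000_000


@dataclass
class LoopCensus:
    """Loop counts per length, optionally with the enumerated loops.

    ``loops[L]`` is None when enumeration was not requested or exceeded the
    retention cap for that length; ``counts`` is always exact.
    """

    counts: dict[int, int]
    loops: dict[int, Optional[set[Loop]]] = field(default_factory=dict)

    def total(self) -> int:
        return sum(self.counts.values())


def canonical_form(sequence: Sequence[str]) -> Loop:
    """Canonicalise a cycle node sequence up to rotation and reflection.

    The canonical sequence starts at the lexicographically smallest member
    and proceeds toward its smaller neighbour within the cycle, so all
    2L symmetric writings of the same cycle map to one tuple.  Idempotent.
    """
    seq = tuple(sequence)
    if len(seq) < 3:
        raise ValueError("a loop needs at least 3 nodes")
    if len(set(seq)) != len(seq):
        raise ValueError("not a simple cycle: repeated node")
    i = seq.index(min(seq))
    n = len(seq)
    nxt = seq[(i + 1) % n]
    prv = seq[(i - 1) % n]
    if nxt <= prv:
        return tuple(seq[(i + j) % n] for j in range(n))
    return tuple(seq[(i - j) % n] for j in range(n))


def _validate_bounds(lmin: int, lmax: int) -> None:
    if lmax > MAX_LOOP_LEN:
        raise ValueError(f"lmax > {MAX_LOOP_LEN}: census is bounded by design")
    if lmin < MIN_LOOP_LEN:
        raise ValueError(f"lmin < {MIN_LOOP_LEN}: shortest loop is a triangle")
    if lmin > lmax:
        raise ValueError("lmin > lmax")


def count_loops(
    net: InteractionNetwork,
    lmin: int = MIN_LOOP_LEN,
    lmax: int = MAX_LOOP_LEN,
    *,
    keep_loops: bool = False,
    cap: int = DEFAULT_ENUMERATION_CAP,
) -> LoopCensus:
    """Count (and optionally enumerate) all simple cycles of length lmin..lmax.

    Each distinct cycle-as-subgraph is counted exactly once.  With
    ``keep_loops`` the canonical loop tuples are retained per length until
    ``cap`` is exceeded for that length, after which only counts remain.
    """
    _validate_bounds(lmin, lmax)
    order = sorted(net.nodes)
    adj_sorted = {v: sorted(net.neighbors(v)) for v in order}
    adj = {v: net.neighbors(v) for v in order}
    counts: dict[int, int] = {length: 0 for length in range(lmin, lmax + 1)}
    retain: dict[int, Optional[set[Loop]]] = (
        {length: set() for length in range(lmin, lmax + 1)} if keep_loops else {}
    )

    def record(path: list[str]) -> None:
        length = len(path)
        counts[length] += 1
        if keep_loops and retain[length] is not None:
            retain[length].add(tuple(path))
            if len(retain[length]) > cap:
                retain[length] = None

    def extend(path: list[str], on_path: set[str]) -> None:
        s = path[0]
        u = path[-1]
        depth = len(path)
        for w in adj_sorted[u]:
            if w <= s or w in on_path:
                continue
            length = depth + 1
            # closing edge back to the root; fixed direction avoids the mirror
            if length >= lmin and s in adj[w] and path[1] < w:
                path.append(w)
                record(path)
                path.pop()
            if length < lmax:
                path.append(w)
                on_path.add(w)
                extend(path, on_path)
                on_path.remove(w)
                path.pop()

    for s in order:
        for n1 in adj_sorted[s]:
            if n1 <= s:
                continue
            extend([s, n1], {s, n1})

    return LoopCensus(counts=counts, loops=retain)


def enumerate_loops(net: InteractionNetwork, length: int) -> set[Loop]:
    """All loops of exactly ``length`` nodes, in canonical form."""
    census = count_loops(net, length, length, keep_loops=True)
    loops = census.loops[length]
    if loops is None:
        raise MemoryError(
            f"loop enumeration at length {length} exceeded the retention cap"
        )
    return loops


def brute_force_census(
    net: InteractionNetwork, lmax: int = MAX_LOOP_LEN, *, guard: int = 40
) -> LoopCensus:
    """Independent oracle: count cycles by exhaustive rooted path search.

    Enumerates every rooted, directed simple path of up to ``lmax`` nodes and
    counts closures back to the root; each L-cycle is found 2L times (L roots
    x 2 directions), so the raw tallies are divided by 2L.  No pruning is
    shared with :func:`count_loops`.  Guarded to small networks.
    """
    if net.n_proteins > guard:
        raise ValueError(f"brute force guarded to NP <= {guard}")
    _validate_bounds(MIN_LOOP_LEN, lmax)
    adj = {v: net.neighbors(v) for v in net}
    raw = {length: 0 for length in range(MIN_LOOP_LEN, lmax + 1)}

    def walk(root: str, u: str, visited: set[str], depth: int) -> None:
        for w in adj[u]:
            if w == root and depth >= MIN_LOOP_LEN:
                raw[depth] += 1
            if w not in visited and depth < lmax:
                visited.add(w)
                walk(root, w, visited, depth + 1)
                visited.remove(w)

    for root in net:
        walk(root, root, {root}, 1)

    return LoopCensus(
        counts={length: raw[length] // (2 * length) for length in raw}
    )
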