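"""Trend classification of loop counts under randomisation, and the
resilient loop core.

Comparing the loop census of a network with the equilibrium census of its
randomised ensembles (degree-constrained and degree-degree-constrained)
yields a small taxonomy of recurring patterns:

* ``purple`` — counts increase under both constraints;
* ``pink``   — increase under the degree constraint, decrease under the
  degree-degree constraint;
* ``cyan``   — decrease under both, steeper under the degree-degree
  constraint;
* ``green``  — decrease under both, steeper under the degree constraint
  (the signature of high-quality networks, whose loop wiring is partly
  encoded in the degree-degree correlation);
* ``irregular`` — any flat change, or decrease-then-increase combinations.

The resilient core is the set of loops present in the original network and
in *every* replica of the degree-degree-constrained ensemble at the end of
the chain: loops that the tightest null model cannot rewire away.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .loops import Loop, LoopCensus, enumerate_loops
from .mcgd import RandomisedEnsemble
from .network import InteractionNetwork

__all__ = [
    "TrendPattern",
    "ResilientCore",
    "classify_trend",
    "resilient_core",
    "loop_edges",
]

DEFAULT_FLAT_TOL = 0.01


@dataclass(frozen=True)
class TrendPattern:
    sign_k: str  # up | down | flat
    sign_kk: str
    steeper: str  # k | kk | n/a
    label: str  # purple | pink | cyan | green | irregular


def _sign(orig: int, mean_final: float, flat_tol: float) -> str:
    rel = (mean_final - orig) / orig
    if abs(rel) < flat_tol:
        return "flat"
    return "up" if rel > 0 else "down"


def classify_trend(
    orig: LoopCensus,
    ens_k: RandomisedEnsemble,
    ens_kk: RandomisedEnsemble,
    length: int,
    flat_tol: float = DEFAULT_FLAT_TOL,
) -> TrendPattern:
    """Label the pattern of loop-count change at one loop length.

    Signs compare the mean final replica count with the original count; a
    relative change below ``flat_tol`` counts as flat.  For joint decreases,
    ``steeper`` names the mode with the lower mean final count (the larger
    decrease); it is ``n/a`` otherwise.
    """
    if length not in orig.counts:
        raise ValueError(f"length {length} not in the original census")
    n0 = orig.counts[length]
    if n0 == 0:
        raise ValueError("undefined relative change: original count is 0")
    mean_k = ens_k.mean_final(length)
    mean_kk = ens_kk.mean_final(length)
    sign_k = _sign(n0, mean_k, flat_tol)
    sign_kk = _sign(n0, mean_kk, flat_tol)

    steeper = "n/a"
    if (sign_k, sign_kk) == ("up", "up"):
        label = "purple"
    elif (sign_k, sign_kk) == ("up", "down"):
        label = "pink"
    elif (sign_k, sign_kk) == ("down", "down"):
        steeper = "kk" if mean_kk < mean_k else "k"
        label = "cyan" if steeper == "kk" else "green"
    else:
        label = "irregular"
    return TrendPattern(
        sign_k=sign_k, sign_kk=sign_kk, steeper=steeper, label=label
    )


def loop_edges(loop: Loop) -> set[tuple[str, str]]:
    """The undirected edges traversed by a loop (cyclically consecutive pairs)."""
    n = len(loop)
    return {
        tuple(sorted((loop[i], loop[(i + 1) % n]))) for i in range(n)
    }


@dataclass
class ResilientCore:
    """Loops preserved across every replica of a randomised ensemble."""

    loops: dict[int, set[Loop]]
    proteins: set[str]
    subnetwork: InteractionNetwork
    retention_fraction: dict[int, Optional[float]]

    def total_loops(self) -> int:
        return sum(len(s) for s in self.loops.values())


def resilient_core(
    net: InteractionNetwork,
    ensemble: RandomisedEnsemble,
    lengths: Sequence[int] = (3, 4),
) -> ResilientCore:
    """Extract the loops retained by every replica of ``ensemble``.

    For each requested length, the core is the intersection of the original
    network's loop set with the loop sets of all replica final networks
    (loop identity is by canonical node sequence; labels persist through
    rewiring).  ``retention_fraction[L]`` is core/original, or None when the
    original has no loop of that length.  The induced subnetwork contains
    exactly the nodes and edges participating in core loops.
    """
    if ensemble.n_replicas < 1:
        raise ValueError("ensemble has no replicas")
    core: dict[int, set[Loop]] = {}
    retention: dict[int, Optional[float]] = {}
    replica_loops: dict[int, list[set[Loop]]] = {
        length: [
            enumerate_loops(rep.final, length) for rep in ensemble.replicas
        ]
        for length in lengths
    }
    for length in lengths:
        orig_loops = enumerate_loops(net, length)
        kept = set(orig_loops)
        for rep_set in replica_loops[length]:
            kept &= rep_set
        core[length] = kept
        retention[length] = (
            len(kept) / len(orig_loops) if orig_loops else None
        )

    proteins: set[str] = set()
    edges: set[tuple[str, str]] = set()
    for loops in core.values():
        for loop in loops:
            proteins.update(loop)
            edges.update(loop_edges(loop))
    sub = InteractionNetwork(edges=edges, nodes=proteins)
    return ResilientCore(
        loops=core,
        proteins=proteins,
        subnetwork=sub,
        retention_fraction=retention,
    )


def verify_core(
    core: ResilientCore,
    net: InteractionNetwork,
    finals: Iterable[InteractionNetwork],
) -> bool:
    """Independently re-check that every core loop is a loop of every network."""
    nets = [net, *finals]
    for length, loops in core.loops.items():
        for loop in loops:
            for g in nets:
                for u, v in loop_edges(loop):
                    if not g.has_edge(u, v):
                        return False
    return True
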