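"""Undirected protein-protein interaction networks: container and edge-list I/O.

A PPIN is modelled as a simple undirected graph over opaque, case-sensitive
protein identifiers.  Self-interactions and duplicate records are removed on
load, matching the cleaning applied to published interaction datasets before
any loop or randomisation analysis.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator

log = logging.getLogger(__name__)

__all__ = ["InteractionNetwork", "load_network", "write_network", "edge_key"]


def edge_key(u: str, v: str) -> tuple[str, str]:
    """Canonical (sorted) representation of an undirected edge."""
    return (u, v) if u <= v else (v, u)


class InteractionNetwork:
    """Simple undirected graph of protein identifiers.

    Invariants maintained by construction: no self-edges, each unordered pair
    stored once, symmetric adjacency.  ``NP = n_proteins`` counts nodes,
    ``NI = n_interactions`` counts edges, and the handshake identity
    ``sum(deg) = 2 * NI`` always holds.

    Isolated nodes are allowed in memory (e.g. scaffolds for planted motifs)
    but are never produced by :func:`load_network`.
    """

    __slots__ = ("_adj",)

    def __init__(
        self,
        edges: Iterable[tuple[str, str]] = (),
        nodes: Iterable[str] = (),
    ) -> None:
        self._adj: dict[str, set[str]] = {}
        for n in nodes:
            self.add_node(n)
        for u, v in edges:
            self.add_edge(u, v)

    # -- construction -------------------------------------------------

    def add_node(self, n: str) -> None:
        self._adj.setdefault(n, set())

    def add_edge(self, u: str, v: str) -> None:
        """Add an undirected edge; self-edges are rejected, duplicates ignored."""
        if u == v:
            raise ValueError(f"self-interaction not allowed: {u!r}")
        self._adj.setdefault(u, set()).add(v)
        self._adj.setdefault(v, set()).add(u)

    def remove_edge(self, u: str, v: str) -> None:
        if not self.has_edge(u, v):
            raise KeyError(f"no such edge: ({u!r}, {v!r})")
        self._adj[u].discard(v)
        self._adj[v].discard(u)

    # -- queries ------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self._adj)

    @property
    def n_proteins(self) -> int:
        """NP: number of proteins (nodes)."""
        return len(self._adj)

    @property
    def n_interactions(self) -> int:
        """NI: number of interactions (edges)."""
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def has_node(self, n: str) -> bool:
        return n in self._adj

    def has_edge(self, u: str, v: str) -> bool:
        return u in self._adj and v in self._adj[u]

    def neighbors(self, n: str) -> set[str]:
        return set(self._adj[n])

    def degree(self, n: str) -> int:
        return len(self._adj[n])

    def degrees(self) -> dict[str, int]:
        return {n: len(nbrs) for n, nbrs in self._adj.items()}

    def edges(self) -> Iterator[tuple[str, str]]:
        """Iterate undirected edges once each, as sorted tuples."""
        for u, nbrs in self._adj.items():
            for v in nbrs:
                if u <= v:
                    yield (u, v)

    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.edges())

    def __contains__(self, n: str) -> bool:
        return n in self._adj

    def __iter__(self) -> Iterator[str]:
        return iter(self._adj)

    def __len__(self) -> int:
        return len(self._adj)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edge_set() == other.edge_set()

    def __repr__(self) -> str:
        return (
            f"<InteractionNetwork NP={self.n_proteins} "
            f"NI={self.n_interactions}>"
        )

    def copy(self) -> "InteractionNetwork":
        new = InteractionNetwork()
        new._adj = {n: set(nbrs) for n, nbrs in self._adj.items()}
        return new

    # -- interop ------------------------------------------------------

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self._adj)
        g.add_edges_from(self.edges())
        return g

    @classmethod
    def from_networkx(cls, g) -> "InteractionNetwork":
        net = cls()
        for n in g.nodes:
            net.add_node(str(n))
        for u, v in g.edges:
            if u != v:
                net.add_edge(str(u), str(v))
        return net


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("tsv", "sif"):
            raise ValueError(f"unknown format {fmt!r} (expected 'tsv' or 'sif')")
        return fmt
    return "sif" if path.suffix.lower() == ".sif" else "tsv"


def load_network(path: str | Path, fmt: str | None = None) -> InteractionNetwork:
    """Load an edge list, silently dropping self- and duplicate interactions.

    Parameters
    ----------
    path:
        TSV (two whitespace-separated identifier columns; extra columns
        ignored; ``#`` comment lines skipped) or SIF
        (``node relation node [node ...]``) file.
    fmt:
        ``"tsv"`` or ``"sif"``; inferred from the ``.sif`` suffix when None.

    Raises
    ------
    ValueError
        On malformed records (with line number) or when no interactions
        survive cleaning.
    """
    path = Path(path)
    fmt = _detect_format(path, fmt)
    net = InteractionNetwork()
    n_self = n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if fmt == "tsv":
                if len(cols) < 2:
                    raise ValueError(
                        f"{path}:{lineno}: malformed record "
                        f"(expected 2 identifier columns, got {len(cols)})"
                    )
                pairs = [(cols[0], cols[1])]
            else:  # sif
                if len(cols) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: malformed SIF record "
                        "(expected 'node relation node')"
                    )
                pairs = [(cols[0], t) for t in cols[2:]]
            for u, v in pairs:
                if u == v:
                    n_self += 1
                elif net.has_edge(u, v):
                    n_dup += 1
                else:
                    net.add_edge(u, v)
    if net.n_interactions == 0:
        raise ValueError(f"{path}: no interactions")
    if n_self or n_dup:
        log.info(
            "%s: dropped %d self-interactions and %d duplicate records",
            path,
            n_self,
            n_dup,
        )
    return net


def write_network(
    net: InteractionNetwork, path: str | Path, fmt: str = "tsv"
) -> None:
    """Write the edge list (sorted, deterministic); round-trips with load."""
    if fmt not in ("tsv", "sif"):
        raise ValueError(f"unknown format {fmt!r}")
    if net.n_proteins == 0:
        raise ValueError("refusing to write empty network")
    with open(path, "w") as fh:
        for u, v in sorted(net.edges()):
            if fmt == "tsv":
                fh.write(f"{u}\t{v}\n")
            else:
                fh.write(f"{u} pp {v}\n")
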