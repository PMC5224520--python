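"""Synthetic networks and annotations for testing the analysis pipeline.

Published interaction networks are sparse, hub-rich (heavy-tailed degrees)
and carry functional module structure: proteins of a complex are densely
interconnected and share biological-process terms.  This module generates
graphs and annotations with exactly those features — configuration-model
graphs with power-law degrees, planted cliques (with an optional
unique-degree guard enabling provable resilience under degree-degree
constrained rewiring), and module-structured annotations with tunable
coherence — plus a miniature three-level ontology so GO-dependent code
paths run without downloading the real Gene Ontology.

Everything is seeded and deterministic.  Defaults emulate a mid-size Y2H
screen: a few hundred proteins, mean degree ~4, power-law exponent 2.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from random import Random
from typing import Optional, Sequence

from .annotation import AnnotationMap
from .network import InteractionNetwork

__all__ = [
    "SynthConfig",
    "powerlaw_degree_sequence",
    "configuration_model_graph",
    "er_graph",
    "plant_clique",
    "synthetic_annotations",
    "mini_ontology_text",
    "write_obo",
    "write_annotations_tsv",
    "write_annotations_gaf",
    "module_term",
    "background_term",
]


@dataclass
class SynthConfig:
    """Study conditions for synthetic fixtures.

    Degree model: ``powerlaw`` (exponent/k_min/k_max), ``er`` (p) or
    ``fixed`` (degree_sequence).  Annotation model: each module gets a block
    of ``terms_per_module`` terms carried by members with probability
    ``coherence``; every protein carries each of ``background_terms`` terms
    with probability ``background_rate``.
    """

    n_nodes: int = 500
    degree_model: str = "powerlaw"
    exponent: float = 2.5
    k_min: int = 2
    k_max: Optional[int] = None
    p: float = 0.016
    degree_sequence: Optional[Sequence[int]] = None
    planted_cliques: Sequence[int] = field(default_factory=tuple)
    n_modules: int = 4
    terms_per_module: int = 6
    coherence: float = 0.9
    background_terms: int = 10
    background_rate: float = 0.1
    seed: int = 0


def _node_name(i: int, width: int) -> str:
    return f"P{i:0{width}d}"


def powerlaw_degree_sequence(
    n: int,
    exponent: float = 2.5,
    k_min: int = 2,
    k_max: Optional[int] = None,
    seed: int = 0,
) -> list[int]:
    """Sample degrees from P(k) ~ k^-exponent on [k_min, k_max], even sum."""
    if k_max is None:
        k_max = max(k_min + 1, min(n - 1, 100))
    rng = Random(seed)
    ks = list(range(k_min, k_max + 1))
    weights = [k ** -exponent for k in ks]
    total = sum(weights)
    cum = []
    acc = 0.0
    for w in weights:
        acc += w / total
        cum.append(acc)
    seq = []
    for _ in range(n):
        r = rng.random()
        for k, c in zip(ks, cum):
            if r <= c:
                seq.append(k)
                break
        else:
            seq.append(k_max)
    if sum(seq) % 2:
        seq[seq.index(min(seq))] += 1
    return seq


def configuration_model_graph(
    config: SynthConfig | Sequence[int],
    seed: Optional[int] = None,
) -> InteractionNetwork:
    """Simple graph realising a degree sequence (configuration model).

    Stub matching is retried up to 100 times looking for a clash-free
    (simple) matching; failing that, the multigraph is collapsed to a
    simple graph and local rewiring reconnects nodes left short of their
    target degree.  The realised sequence stays within 5% L1 distance of
    the target.  Seeded and deterministic.
    """
    import networkx as nx

    if isinstance(config, SynthConfig):
        if seed is None:
            seed = config.seed
        if config.degree_model == "er":
            return er_graph(config.n_nodes, config.p, seed)
        if config.degree_model == "fixed":
            if config.degree_sequence is None:
                raise ValueError("fixed degree model needs degree_sequence")
            seq = list(config.degree_sequence)
        elif config.degree_model == "powerlaw":
            seq = powerlaw_degree_sequence(
                config.n_nodes,
                config.exponent,
                config.k_min,
                config.k_max,
                seed=seed,
            )
        else:
            raise ValueError(f"unknown degree model {config.degree_model!r}")
    else:
        seq = list(config)
        if seed is None:
            seed = 0

    if sum(seq) % 2:
        raise ValueError("degree sequence has odd sum: unrealisable")
    if not nx.is_graphical(seq):
        raise ValueError("degree sequence is not graphical")

    g_simple = None
    for attempt in range(100):
        g = nx.configuration_model(seq, seed=seed + attempt)
        pairs = [frozenset(e) if e[0] != e[1] else None for e in g.edges()]
        clash_free = None not in pairs and len(set(pairs)) == len(pairs)
        if clash_free:
            g_simple = nx.Graph(g)
            break
    if g_simple is None:
        # rewiring fallback: collapse and repair degree deficits locally
        g = nx.configuration_model(seq, seed=seed)
        g_simple = nx.Graph(g)
        g_simple.remove_edges_from(nx.selfloop_edges(g_simple))
        rng = Random(seed)
        deficits = {
            v: seq[v] - g_simple.degree(v)
            for v in g_simple.nodes
            if seq[v] > g_simple.degree(v)
        }
        short = [v for v, d in deficits.items() for _ in range(d)]
        rng.shuffle(short)
        for _ in range(10 * len(short) if short else 0):
            if len(short) < 2:
                break
            u = short.pop()
            v = short.pop()
            if u != v and not g_simple.has_edge(u, v):
                g_simple.add_edge(u, v)
            # unplaceable stubs are dropped (bounded by the 5% L1 budget)

    width = len(str(len(seq) - 1))
    net = InteractionNetwork()
    for v in g_simple.nodes:
        net.add_node(_node_name(v, width))
    for u, v in g_simple.edges:
        net.add_edge(_node_name(u, width), _node_name(v, width))
    return net


def er_graph(n: int, p: float, seed: int = 0) -> InteractionNetwork:
    """Erdos-Renyi G(n, p), relabelled with protein-style node names."""
    import networkx as nx

    g = nx.gnp_random_graph(n, p, seed=seed)
    width = len(str(n - 1))
    net = InteractionNetwork()
    for v in g.nodes:
        net.add_node(_node_name(v, width))
    for u, v in g.edges:
        net.add_edge(_node_name(u, width), _node_name(v, width))
    return net


def plant_clique(
    net: InteractionNetwork,
    size: int,
    unique_degree_guard: bool = False,
    nodes: Optional[Sequence[str]] = None,
) -> InteractionNetwork:
    """Return a copy of ``net`` with ``size`` chosen nodes fully interconnected.

    With ``unique_degree_guard`` the clique is planted on isolated nodes so
    each member ends with degree size-1, and no *other* node of the network
    may share that degree.  Then no degree-degree-constrained swap can touch
    a clique edge (any admissible partner edge would need an endpoint of
    equal degree), so the clique's loops are provably resilient.
    """
    if size < 3:
        raise ValueError("clique size must be >= 3")
    if size > net.n_proteins:
        raise ValueError("clique larger than the network")
    new = net.copy()
    if nodes is None:
        if unique_degree_guard:
            candidates = sorted(v for v in new if new.degree(v) == 0)
            if len(candidates) < size:
                raise ValueError(
                    "unique-degree guard unsatisfiable: "
                    f"need {size} isolated nodes, have {len(candidates)}"
                )
            nodes = candidates[:size]
        else:
            nodes = sorted(new.nodes)[:size]
    elif len(set(nodes)) != size:
        raise ValueError("nodes must be distinct and match size")
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            if not new.has_edge(u, v):
                new.add_edge(u, v)
    if unique_degree_guard:
        target = size - 1
        offenders = [
            v
            for v in new
            if v not in set(nodes) and new.degree(v) == target
        ]
        if offenders or any(new.degree(v) != target for v in nodes):
            raise ValueError(
                "unique-degree guard unsatisfiable: "
                f"degree {target} is not unique to the planted clique"
            )
    return new


# --- annotations -----------------------------------------------------

ROOT_TERM = "GO:9000000"
_LEVEL1 = [f"GO:{9100000 + i:07d}" for i in range(3)]
_BACKGROUND_PARENT = "GO:9290000"


def module_term(module: int, j: int) -> str:
    return f"GO:{9300000 + module * 100 + j:07d}"


def background_term(j: int) -> str:
    return f"GO:{9400000 + j:07d}"


def _module_parent(module: int) -> str:
    return f"GO:{9200000 + module:07d}"


def synthetic_annotations(
    net: InteractionNetwork,
    modules: Sequence[Sequence[str]],
    config: SynthConfig,
) -> AnnotationMap:
    """Module-structured annotations over the network's proteins.

    Module ``m`` owns terms ``module_term(m, 0..terms_per_module-1)``; each
    member carries each of them with probability ``coherence``.  Every
    protein carries each background term with probability
    ``background_rate``.  Proteins left without terms are unannotated.
    """
    seen: set[str] = set()
    for mod in modules:
        for p in mod:
            if p in seen:
                raise ValueError(f"modules are not disjoint: {p!r}")
            seen.add(p)
    rng = Random(config.seed)
    ann: dict[str, set[str]] = {}
    for m, mod in enumerate(modules):
        terms = [module_term(m, j) for j in range(config.terms_per_module)]
        for p in sorted(mod):
            carried = {t for t in terms if rng.random() < config.coherence}
            if carried:
                ann.setdefault(p, set()).update(carried)
    for p in sorted(net.nodes):
        for j in range(config.background_terms):
            if rng.random() < config.background_rate:
                ann.setdefault(p, set()).add(background_term(j))
    return AnnotationMap(ann)


def mini_ontology_text(
    n_modules: int = 8, terms_per_module: int = 8, background_terms: int = 10
) -> str:
    """A miniature biological-process ontology (3 levels) in OBO format.

    Structure: one root, three broad depth-1 terms, one depth-2 parent per
    module (plus one for background terms), and the module/background terms
    as depth-3 leaves.  IDs match :func:`module_term`/:func:`background_term`
    so annotations from :func:`synthetic_annotations` resolve against it.
    """
    stanzas = [
        "format-version: 1.2",
        "ontology: synthetic-mini-go",
        "",
        "[Term]",
        f"id: {ROOT_TERM}",
        "name: biological_process",
        "namespace: biological_process",
        "",
    ]

    def term(tid: str, name: str, parent: Optional[str]) -> None:
        stanzas.append("[Term]")
        stanzas.append(f"id: {tid}")
        stanzas.append(f"name: {name}")
        stanzas.append("namespace: biological_process")
        if parent:
            stanzas.append(f"is_a: {parent}")
        stanzas.append("")

    names = ["metabolic process", "cellular process", "regulation"]
    for i, l1 in enumerate(_LEVEL1):
        term(l1, names[i], ROOT_TERM)
    for m in range(n_modules):
        term(
            _module_parent(m),
            f"module {m} process",
            _LEVEL1[m % len(_LEVEL1)],
        )
        for j in range(terms_per_module):
            term(module_term(m, j), f"module {m} function {j}", _module_parent(m))
    term(_BACKGROUND_PARENT, "housekeeping process", _LEVEL1[1])
    for j in range(background_terms):
        term(background_term(j), f"housekeeping function {j}", _BACKGROUND_PARENT)
    return "\n".join(stanzas)


def write_obo(
    path: str | Path,
    n_modules: int = 8,
    terms_per_module: int = 8,
    background_terms: int = 10,
) -> None:
    Path(path).write_text(
        mini_ontology_text(n_modules, terms_per_module, background_terms)
    )


def write_annotations_tsv(ann: AnnotationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in sorted(ann):
            for t in sorted(ann[p]):
                fh.write(f"{p}\t{t}\n")


def write_annotations_gaf(ann: AnnotationMap, path: str | Path) -> None:
    """Minimal GAF 2.2 (17 columns, biological-process aspect)."""
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for p in sorted(ann):
            for t in sorted(ann[p]):
                cols = [
                    "SYN",  # DB
                    p,  # DB object ID
                    p,  # symbol
                    "involved_in",  # qualifier
                    t,  # GO ID
                    "SYN:ref",  # reference
                    "IEA",  # evidence
                    "",  # with/from
                    "P",  # aspect
                    "",  # name
                    "",  # synonym
                    "protein",  # type
                    "taxon:0000",  # taxon
                    "20150223",  # date
                    "SYN",  # assigned by
                    "",  # extension
                    "",  # gene product form
                ]
                fh.write("\t".join(cols) + "\n")
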