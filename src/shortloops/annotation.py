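"""Functional-consensus analysis of loops against Gene Ontology annotation.

The central statistic is the *functional consensus* of a loop: the
percentage of GO biological-process terms shared by all the proteins in the
loop, relative to the terms annotated within the loop,

    consensus(loop) = 100 * |intersection of member term sets|
                          / |union of member term sets|.

It is 100% iff all members carry identical term sets and 0% iff no term is
shared.  The module also provides the binned consensus distribution, a
resampling randomisation null (random protein sets of the same size), and
the per-term frequency table comparing term occurrence in loops of length
3-5 with occurrence in the whole network.

Annotation input is GAF 2.x or a simple two-column TSV; ontology structure
is read from OBO (via ``obonet``).  By default annotations are propagated
to ancestors over is_a/part_of, excluding the aspect root.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from random import Random
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .loops import Loop
from .network import InteractionNetwork

__all__ = [
    "GOGraph",
    "AnnotationMap",
    "ConsensusResult",
    "ResamplingResult",
    "load_annotations",
    "functional_consensus",
    "consensus_distribution",
    "resampling_null",
    "term_frequency_table",
    "classify_term_trend",
]

ASPECT_NAMESPACES = {
    "P": "biological_process",
    "F": "molecular_function",
    "C": "cellular_component",
}


class GOGraph:
    """Ontology structure restricted to one aspect: parents, depths, children.

    ``depth`` is the shortest is_a/part_of distance from the aspect root
    (root depth 0).  Terms at depth <= 1 are the "general" terms common to
    most annotated proteins; depth-2 terms with many children are similarly
    broad.  Both are excluded from term-frequency analyses.
    """

    def __init__(self, parents: Mapping[str, set[str]]) -> None:
        self.parents: dict[str, set[str]] = {
            t: set(ps) for t, ps in parents.items()
        }
        for ps in parents.values():  # ensure parents are nodes too
            for p in ps:
                self.parents.setdefault(p, set())
        self.children: dict[str, set[str]] = {t: set() for t in self.parents}
        for t, ps in self.parents.items():
            for p in ps:
                self.children[p].add(t)
        roots = sorted(t for t, ps in self.parents.items() if not ps)
        if not roots:
            raise ValueError("ontology graph has no root (cycle?)")
        self.roots = roots
        self.depth: dict[str, int] = {}
        frontier = list(roots)
        for r in roots:
            self.depth[r] = 0
        d = 0
        while frontier:
            d += 1
            nxt = []
            for t in frontier:
                for c in self.children[t]:
                    if c not in self.depth:
                        self.depth[c] = d
                        nxt.append(c)
            frontier = nxt
        self._anc_cache: dict[str, frozenset[str]] = {}

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of ``term`` (excluding the term itself)."""
        cached = self._anc_cache.get(term)
        if cached is not None:
            return cached
        out: set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            p = stack.pop()
            if p not in out:
                out.add(p)
                stack.extend(self.parents.get(p, ()))
        result = frozenset(out)
        self._anc_cache[term] = result
        return result

    def n_children(self, term: str) -> int:
        return len(self.children.get(term, ()))

    @classmethod
    def from_obo(
        cls, path: str | Path, aspect: str = "biological_process"
    ) -> "GOGraph":
        """Read an OBO file, keeping one namespace and is_a/part_of edges."""
        import obonet

        g = obonet.read_obo(path)
        keep = {
            t
            for t, data in g.nodes(data=True)
            if data.get("namespace", aspect) == aspect
        }
        parents: dict[str, set[str]] = {t: set() for t in keep}
        for child, parent, rel in g.edges(keys=True):
            if rel in ("is_a", "part_of") and child in keep and parent in keep:
                parents[child].add(parent)
        if not parents:
            raise ValueError(f"no terms with namespace {aspect!r} in {path}")
        return cls(parents)


class AnnotationMap(Mapping[str, frozenset]):
    """protein -> set of GO terms (one aspect, optionally propagated)."""

    def __init__(self, mapping: Mapping[str, Iterable[str]]) -> None:
        self._map: dict[str, frozenset[str]] = {
            p: frozenset(ts) for p, ts in mapping.items() if ts
        }

    def __getitem__(self, protein: str) -> frozenset[str]:
        return self._map[protein]

    def __iter__(self):
        return iter(self._map)

    def __len__(self) -> int:
        return len(self._map)

    def coverage(self, net: InteractionNetwork) -> float:
        """Fraction of network proteins with at least one annotation."""
        if net.n_proteins == 0:
            return 0.0
        return sum(1 for p in net if p in self._map) / net.n_proteins

    def annotated(self, proteins: Iterable[str]) -> list[str]:
        return [p for p in proteins if p in self._map]


def _looks_like_gaf(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.startswith("!"):
                return True
            if not line.strip():
                continue
            return len(line.rstrip("\n").split("\t")) >= 15
    return False


def _parse_gaf(path: Path, aspect_letter: str) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("!") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 15:
                raise ValueError(f"{path}: GAF row with {len(cols)} columns")
            qualifier, term, aspect = cols[3], cols[4], cols[8]
            if "NOT" in qualifier.split("|"):
                continue
            if aspect != aspect_letter:
                continue
            out.setdefault(cols[1], set()).add(term)
    return out


def _parse_tsv(path: Path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'protein<TAB>term'"
                )
            out.setdefault(cols[0], set()).add(cols[1])
    return out


def load_annotations(
    annotation_path: str | Path,
    ontology_path: str | Path,
    aspect: str = "biological_process",
    propagate: bool = True,
) -> tuple[AnnotationMap, GOGraph]:
    """Read protein->GO annotations (GAF 2.x or two-column TSV) plus OBO.

    Only the requested aspect is retained; NOT-qualified GAF rows are
    dropped.  With ``propagate`` each term set is closed under is_a/part_of
    ancestry, excluding the aspect root(s).  Terms absent from the ontology
    are kept as leaves with a warning.
    """
    annotation_path = Path(annotation_path)
    if aspect in ASPECT_NAMESPACES:
        aspect_letter, namespace = aspect, ASPECT_NAMESPACES[aspect]
    else:
        namespace = aspect
        letters = {v: k for k, v in ASPECT_NAMESPACES.items()}
        aspect_letter = letters.get(aspect, "P")
    go = GOGraph.from_obo(ontology_path, aspect=namespace)

    if _looks_like_gaf(annotation_path):
        raw = _parse_gaf(annotation_path, aspect_letter)
    else:
        raw = _parse_tsv(annotation_path)
        # TSV carries no aspect column: keep known-aspect terms plus unknowns
        known_any = {t for ts in raw.values() for t in ts if t in go}
        unknown = {t for ts in raw.values() for t in ts if t not in go}
        raw = {
            p: {t for t in ts if t in known_any or t in unknown}
            for p, ts in raw.items()
        }

    missing = sorted(
        {t for ts in raw.values() for t in ts if t not in go}
    )
    if missing:
        warnings.warn(
            f"{len(missing)} annotated term(s) absent from the ontology; "
            "kept as leaves without ancestors"
        )

    roots = set(go.roots)
    result: dict[str, set[str]] = {}
    for protein, terms in raw.items():
        terms = set(terms) - roots
        if propagate:
            closed = set(terms)
            for t in terms:
                closed |= go.ancestors(t)
            terms = closed - roots
        if terms:
            result[protein] = terms
    if not result:
        raise ValueError(f"{annotation_path}: zero annotated proteins")
    return AnnotationMap(result), go


def functional_consensus(loop: Sequence[str], ann: AnnotationMap) -> float:
    """Percentage of terms shared by all loop members, of the terms in the loop.

    Raises KeyError when a member is unannotated (such loops are excluded
    upstream and counted separately).
    """
    sets = [ann[p] for p in loop]
    union = frozenset().union(*sets)
    if not union:
        raise ValueError("empty term union")
    common = sets[0]
    for s in sets[1:]:
        common = common & s
    return 100.0 * len(common) / len(union)


def consensus_set(loop: Sequence[str], ann: AnnotationMap) -> frozenset[str]:
    """The terms shared by all members of a loop."""
    sets = [ann[p] for p in loop]
    common = sets[0]
    for s in sets[1:]:
        common = common & s
    return common


@dataclass
class ConsensusResult:
    """Per-length consensus values, binned distribution and exclusion counts."""

    bin_width: float
    values: dict[int, list[float]]  # per scorable loop
    histogram: dict[int, list[float]]  # fractions per bin, sum to 1
    excluded: dict[int, int]  # loops with an unannotated member

    def bin_edges(self) -> list[float]:
        edges = list(np.arange(0.0, 100.0, self.bin_width))
        return edges + [100.0]


def _bin_index(value: float, bin_width: float, n_bins: int) -> int:
    idx = int(value // bin_width)
    return min(idx, n_bins - 1)  # 100% goes in the closed top bin


def consensus_distribution(
    loops_by_length: Mapping[int, Iterable[Loop]],
    ann: AnnotationMap,
    bin_width: float = 25.0,
) -> ConsensusResult:
    """Histogram of functional consensus per loop length.

    Bins are [0,25), [25,50), [50,75), [75,100] for the default width.
    Loops containing an unannotated member are excluded from the histogram
    and reported in ``excluded``.
    """
    n_bins = int(round(100.0 / bin_width))
    values: dict[int, list[float]] = {}
    histogram: dict[int, list[float]] = {}
    excluded: dict[int, int] = {}
    any_scorable = False
    for length, loops in loops_by_length.items():
        vals: list[float] = []
        skipped = 0
        for loop in loops:
            try:
                vals.append(functional_consensus(loop, ann))
            except KeyError:
                skipped += 1
        values[length] = vals
        excluded[length] = skipped
        if vals:
            any_scorable = True
            counts = [0] * n_bins
            for v in vals:
                counts[_bin_index(v, bin_width, n_bins)] += 1
            histogram[length] = [c / len(vals) for c in counts]
        else:
            histogram[length] = [0.0] * n_bins
    if not any_scorable:
        raise ValueError("no scorable loops (all members unannotated?)")
    return ConsensusResult(
        bin_width=bin_width,
        values=values,
        histogram=histogram,
        excluded=excluded,
    )


@dataclass
class ResamplingResult:
    null: np.ndarray  # consensus of each resampled protein set
    observed_mean: float
    p_value: float
    n_samples: int


def resampling_null(
    net: InteractionNetwork,
    ann: AnnotationMap,
    set_size: int,
    n_samples: int = 10_000,
    seed: int = 0,
    observed_loops: Optional[Iterable[Loop]] = None,
) -> ResamplingResult:
    """Resampling randomisation test for loop functional consensus.

    Draws ``n_samples`` uniform sets of ``set_size`` distinct annotated
    network proteins, scores each with the same consensus statistic, and
    compares the observed mean loop consensus with this null:

        p = (1 + #{null >= observed mean}) / (1 + n_samples).

    ``observed_loops`` defaults to the network's own loops of length
    ``set_size``.
    """
    if n_samples < 100:
        warnings.warn("n_samples < 100: resampling p-value will be coarse")
    annotated = sorted(ann.annotated(net.nodes))
    if len(annotated) < set_size:
        raise ValueError(
            f"need at least {set_size} annotated proteins, have {len(annotated)}"
        )
    if observed_loops is None:
        from .loops import enumerate_loops

        observed_loops = enumerate_loops(net, set_size)
    observed = []
    for loop in observed_loops:
        try:
            observed.append(functional_consensus(loop, ann))
        except KeyError:
            continue
    if not observed:
        raise ValueError("no scorable observed loops")
    observed_mean = float(np.mean(observed))

    rng = Random(seed)
    null = np.empty(n_samples)
    for i in range(n_samples):
        members = rng.sample(annotated, set_size)
        null[i] = functional_consensus(members, ann)
    p = (1 + int(np.sum(null >= observed_mean))) / (1 + n_samples)
    return ResamplingResult(
        null=null, observed_mean=observed_mean, p_value=p, n_samples=n_samples
    )


def classify_term_trend(
    freq_network: float,
    freq_loops: Sequence[float],
    large_complex_removed: bool = False,
) -> str:
    """Label a term's loop-vs-network frequency pattern.

    Trend 1: the term is more frequent in loops of every length than in the
    network.  Trend 3: loop frequencies decrease monotonically with length
    while each stays below the network frequency.  Trend 2: every loop
    frequency is below the network frequency (non-monotone).  With
    ``large_complex_removed`` (the ribosome-excluded analysis) only two
    patterns remain, relabelled 4 and 5.  Anything else is "unclassified".
    """
    above = min(freq_loops) > freq_network
    below = max(freq_loops) < freq_network
    monotone_down = all(
        freq_loops[i] > freq_loops[i + 1] for i in range(len(freq_loops) - 1)
    )
    if large_complex_removed:
        if above:
            return "4"
        if below:
            return "5"
        return "unclassified"
    if above:
        return "1"
    if below and monotone_down:
        return "3"
    if below:
        return "2"
    return "unclassified"


def term_frequency_table(
    net: InteractionNetwork,
    loops_by_length: Mapping[int, Iterable[Loop]],
    ann: AnnotationMap,
    go: GOGraph,
    *,
    any_member: bool = False,
    large_complex_removed: bool = False,
):
    """Per-term relative frequencies (%) in the network and in loops.

    freq_network(term) = % of annotated network proteins carrying the term;
    freq_loopL(term) = % of scorable length-L loops whose consensus set
    contains the term (with ``any_member``, loops where any member carries
    it).  General terms are excluded: the root, depth-1 terms and depth-2
    terms with more than 4 children.  Returns a pandas DataFrame indexed by
    term with columns freq_network, freq_loop<L>... and trend.
    """
    import pandas as pd

    lengths = sorted(loops_by_length)
    if not lengths:
        raise ValueError("no loop sets supplied")

    annotated = [p for p in sorted(net.nodes) if p in ann]
    if not annotated:
        raise ValueError("no annotated proteins in the network")

    def keep(term: str) -> bool:
        d = go.depth.get(term)
        if d is None:  # unknown to the ontology: keep as specific leaf
            return True
        if d <= 1:
            return False
        if d == 2 and go.n_children(term) > 4:
            return False
        return True

    net_counts: Counter[str] = Counter()
    for p in annotated:
        for t in ann[p]:
            if keep(t):
                net_counts[t] += 1

    loop_freqs: dict[int, Counter[str]] = {}
    n_scorable: dict[int, int] = {}
    for length in lengths:
        counter: Counter[str] = Counter()
        scorable = 0
        for loop in loops_by_length[length]:
            try:
                terms = (
                    frozenset().union(*(ann[p] for p in loop))
                    if any_member
                    else consensus_set(loop, ann)
                )
            except KeyError:
                continue
            scorable += 1
            for t in terms:
                if keep(t):
                    counter[t] += 1
        if scorable == 0:
            raise ValueError(f"no scorable loops of length {length}")
        loop_freqs[length] = counter
        n_scorable[length] = scorable

    terms = sorted(net_counts)
    rows = []
    for t in terms:
        freq_net = 100.0 * net_counts[t] / len(annotated)
        freqs = [
            100.0 * loop_freqs[length][t] / n_scorable[length]
            for length in lengths
        ]
        rows.append(
            {
                "term": t,
                "freq_network": freq_net,
                **{
                    f"freq_loop{length}": f
                    for length, f in zip(lengths, freqs)
                },
                "trend": classify_term_trend(
                    freq_net, freqs, large_complex_removed
                ),
            }
        )
    return pd.DataFrame(rows).set_index("term")
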