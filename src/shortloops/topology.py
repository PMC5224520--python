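"""Global topological profiling of interaction networks.

Computes the standard descriptor set used to compare interaction networks
across organisms and detection methods — size (NP, NI), connectivity
(mean/max degree), spectral properties (leading adjacency eigenvalue,
eigenvector centrality), mean betweenness, degree assortativity, the
transitivity ratio and the average degree-degree correlation — plus the
joint edge-end degree matrix W(k,k') and a PCA classification of networks
in descriptor space.

Conventions (they matter for comparability):

* ``kk_corr`` is the edge-wise mean of deg(u)*deg(v) — large for hub-rich
  networks.
* eigenvector centrality is the principal adjacency eigenvector normalised
  to unit Euclidean norm (its mean component is then ~1/sqrt(NP)).
* betweenness is unnormalised shortest-path betweenness averaged over all
  nodes (disconnected networks allowed; paths are counted per component).
* assortativity is the Pearson correlation over the 2*NI ordered edge-end
  degree pairs, undefined (NaN) for degree-regular graphs.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .network import InteractionNetwork

__all__ = [
    "TopologyProfile",
    "DegreeCorrelationMatrix",
    "PCAResult",
    "compute_profile",
    "degree_correlation_matrix",
    "pca_classify",
    "profiles_to_csv",
    "PCA_DEFAULT_VARIABLES",
]

#: variables used to classify networks: size, degree-degree correlation,
#: assortativity and mean eigenvector centrality are near-independent
#: descriptors of size, connectivity structure and node centrality.
PCA_DEFAULT_VARIABLES = ("NI", "kk_corr", "assort", "evc_mean")

PROFILE_COLUMNS = (
    "NP",
    "NI",
    "k_mean",
    "k_max",
    "kk_corr",
    "ev",
    "evc_mean",
    "btwn",
    "assort",
    "transitivity",
)


@dataclass
class TopologyProfile:
    NP: int
    NI: int
    k_mean: float
    k_max: int
    kk_corr: float
    ev: float
    evc_mean: float
    btwn: float
    assort: float  # NaN when undefined (degree-regular network)
    transitivity: float

    @property
    def assort_defined(self) -> bool:
        return not math.isnan(self.assort)

    def as_row(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in PROFILE_COLUMNS}


@dataclass
class DegreeCorrelationMatrix:
    """W(k,k'): number of ordered edge-end pairs with end degrees k and k'."""

    W: dict[tuple[int, int], int]

    def total(self) -> int:
        return sum(self.W.values())

    def kk_corr(self) -> float:
        """Recover the edge-wise mean of deg(u)*deg(v) from W.

        W holds ordered pairs (total mass 2*NI), so the ordered sum divided
        by the total equals the per-edge mean.
        """
        return sum(k * kp * w for (k, kp), w in self.W.items()) / self.total()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DegreeCorrelationMatrix):
            return NotImplemented
        return self.W == other.W


def _principal_eigenpair(net: InteractionNetwork) -> tuple[float, np.ndarray, list[str]]:
    nodes = sorted(net.nodes)
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    if n <= 500:
        a = np.zeros((n, n))
        for u, v in net.edges():
            a[index[u], index[v]] = a[index[v], index[u]] = 1.0
        vals, vecs = np.linalg.eigh(a)
        ev = float(vals[-1])
        vec = vecs[:, -1]
    else:
        from scipy.sparse import lil_matrix
        from scipy.sparse.linalg import eigsh

        a = lil_matrix((n, n))
        for u, v in net.edges():
            a[index[u], index[v]] = a[index[v], index[u]] = 1.0
        vals, vecs = eigsh(a.tocsr(), k=1, which="LA", tol=1e-10)
        ev = float(vals[0])
        vec = vecs[:, 0]
    # Perron vector is non-negative on its component; fix the global sign
    vec = np.abs(vec)
    vec /= np.linalg.norm(vec)
    return ev, vec, nodes


def compute_profile(net: InteractionNetwork) -> TopologyProfile:
    """Compute the full topological descriptor row for one network."""
    if net.n_proteins < 2 or net.n_interactions < 1:
        raise ValueError("profile requires NP >= 2 and NI >= 1")
    import networkx as nx

    degs = net.degrees()
    np_, ni = net.n_proteins, net.n_interactions
    k_mean = 2 * ni / np_
    k_max = max(degs.values())
    kk_corr = sum(degs[u] * degs[v] for u, v in net.edges()) / ni

    ev, vec, _ = _principal_eigenpair(net)
    evc_mean = float(vec.mean())

    g = net.to_networkx()
    btwn = float(
        np.mean(list(nx.betweenness_centrality(g, normalized=False).values()))
    )
    transitivity = float(nx.transitivity(g))

    ends = np.array(
        [[degs[u], degs[v]] for u, v in net.edges()], dtype=float
    )
    x = np.concatenate([ends[:, 0], ends[:, 1]])
    y = np.concatenate([ends[:, 1], ends[:, 0]])
    if x.std() == 0.0:
        assort = float("nan")
    else:
        assort = float(np.corrcoef(x, y)[0, 1])

    return TopologyProfile(
        NP=np_,
        NI=ni,
        k_mean=k_mean,
        k_max=k_max,
        kk_corr=kk_corr,
        ev=ev,
        evc_mean=evc_mean,
        btwn=btwn,
        assort=assort,
        transitivity=transitivity,
    )


def degree_correlation_matrix(net: InteractionNetwork) -> DegreeCorrelationMatrix:
    """Joint distribution W(k,k') of degrees at the two ends of every edge.

    Symmetric by construction; the total mass is 2*NI (ordered pairs).
    """
    degs = net.degrees()
    w: Counter[tuple[int, int]] = Counter()
    for u, v in net.edges():
        w[(degs[u], degs[v])] += 1
        w[(degs[v], degs[u])] += 1
    return DegreeCorrelationMatrix(W=dict(w))


@dataclass
class PCAResult:
    scores: dict[str, tuple[float, float]]
    loadings: dict[str, tuple[float, float]]
    explained_variance: tuple[float, float]


def pca_classify(
    profiles: Sequence[TopologyProfile],
    variables: Sequence[str] = PCA_DEFAULT_VARIABLES,
    names: Sequence[str] | None = None,
) -> PCAResult:
    """Classify networks by PCA on standardised topological descriptors.

    Profiles with a non-finite value in any chosen variable (e.g. undefined
    assortativity) are excluded with a warning.  Variables are standardised
    to mean 0 / sd 1 so the decomposition acts on the correlation matrix;
    the sign of each component is fixed so its largest-magnitude loading is
    positive.
    """
    if names is None:
        names = [f"net{i}" for i in range(len(profiles))]
    if len(names) != len(profiles):
        raise ValueError("names and profiles length mismatch")
    rows, kept_names = [], []
    for name, prof in zip(names, profiles):
        vals = [getattr(prof, v) for v in variables]
        if all(math.isfinite(x) for x in vals):
            rows.append(vals)
            kept_names.append(name)
        else:
            warnings.warn(
                f"excluding {name}: non-finite value among {tuple(variables)}"
            )
    if len(rows) < 3:
        raise ValueError("PCA requires at least 3 profiles with finite values")
    x = np.asarray(rows, dtype=float)
    sd = x.std(axis=0)
    if np.any(sd == 0.0):
        bad = [v for v, s in zip(variables, sd) if s == 0.0]
        raise ValueError(f"zero variance in variable(s): {bad}")
    xs = (x - x.mean(axis=0)) / sd

    from sklearn.decomposition import PCA

    n_comp = min(2, len(variables))
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(xs)
    comps = pca.components_
    for i in range(n_comp):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
            scores[:, i] = -scores[:, i]
    if n_comp == 1:  # degenerate but keep the (PC1, PC2) contract
        comps = np.vstack([comps, np.zeros_like(comps[0])])
        scores = np.hstack([scores, np.zeros((scores.shape[0], 1))])
        evr = (float(pca.explained_variance_ratio_[0]), 0.0)
    else:
        evr = (
            float(pca.explained_variance_ratio_[0]),
            float(pca.explained_variance_ratio_[1]),
        )
    return PCAResult(
        scores={
            name: (float(scores[i, 0]), float(scores[i, 1]))
            for i, name in enumerate(kept_names)
        },
        loadings={
            v: (float(comps[0, j]), float(comps[1, j]))
            for j, v in enumerate(variables)
        },
        explained_variance=evr,
    )


def profiles_to_csv(
    profiles: Sequence[TopologyProfile],
    names: Sequence[str],
    path: str | Path,
) -> None:
    """One CSV row per network, with the standard descriptor column names."""
    import pandas as pd

    df = pd.DataFrame([p.as_row() for p in profiles], index=list(names))
    df.index.name = "network"
    df.to_csv(path)
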