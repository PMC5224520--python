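# Methods

This note records the models, conventions and numerical choices behind
`shortloops`, and what the synthetic fixtures do and do not establish
about real interaction data.

## Networks and cleaning

A PPIN is a simple undirected graph over opaque, case-sensitive protein
identifiers. On load, self-interactions and duplicate records (in either
order) are dropped silently and counted in the log; nodes that appear only
in removed self-records are dropped entirely, since a degree-0 node
carries no loop or rewiring information and published protein counts (NP)
enumerate interacting proteins. No identifier mapping or normalisation is
attempted — accession schemes vary between sources, and mapping is a
separate concern. Isolated nodes are permitted in programmatically built
networks (they serve as scaffolds for planted motifs).

## Loop census

A loop is a simple cycle treated as an unoriented, unrooted subgraph.
The census runs a depth-first search bounded by loop length: a path is
rooted at node *s*, extended only through identifiers larger than *s*
(so *s* is the cycle's minimum), and a closure back to *s* is recorded
only when the second node precedes the last (fixing the traversal
direction). Each cycle is therefore counted exactly once, and neighbour
lists are visited in sorted order, making enumeration deterministic.
Lengths are capped at 6 by design: counts grow near-exponentially with
length (length-6 counts reach 10^9 in dense networks) and longer cycles
lose the reading as a compact functional motif. Enumerated loops are kept
in canonical form (start at the smallest member, proceed toward its
smaller neighbour) and retained per length only up to a configurable cap
(default 10^7); above it, only counts are produced.

The test oracle is an independent exhaustive search over rooted, directed
simple paths that counts every L-cycle 2L times and divides; it shares no
pruning with the main implementation. `networkx.simple_cycles` with a
length bound serves as a second, third-party oracle in the tests.

## Randomisation (MCGD)

Null models are sampled by iterated edge swaps (a,b),(c,d) → (a,d),(c,b)
on quadruplets of distinct nodes, which conserve all degrees. Proposals
draw two distinct edges uniformly and pick one of the two rewirings
uniformly. A proposal is rejected when it would create a self-edge or a
parallel edge (the chain stays in simple-graph space). Under the
degree-degree constraint the swap must additionally leave the multiset of
edge degree pairs unchanged — equivalent to requiring that the two
exchanged partners have equal degree — which conserves W(k,k′) *exactly*,
bit for bit. This hard-rejection formulation was chosen over a soft
acceptance-rate ensemble because it makes the constraint testable exactly;
the cost is that, without a mobility correction, sampling over the
constrained graph space is approximately rather than provably uniform.
This bias is a known limitation, as is the fact that ergodicity of
hard-constrained swaps over the fixed-W space is not guaranteed.

Moves are counted as *proposed* swaps, accepted or not, so a budget of
100·NI moves (the default, with five replicas seeded base_seed+i) means
the same chain length under both modes despite their different rejection
rates. Trajectories sample loop counts and the Hamming distance every NI
moves by default, starting at step 0. The Hamming distance is the size of
the symmetric difference of edge sets divided by C(NP,2) — all node pairs
— the convention under which sparse networks plateau at small values
(max 2·NI/C(NP,2); ≈0.004 for the 2000-node, ~4000-edge reference
fixture, below the 0.02 plateau bound asserted in the acceptance run). A
chain that accumulates a configurable number of consecutive rejections
(default 1000) is declared frozen and stopped with a warning; a path
a–b–c, whose every edge pair shares a node, demonstrates the case.

## Trend taxonomy and resilient core

A network's response at one loop length is summarised by comparing the
original count with the mean final count over replicas of each ensemble.
Relative changes below a flat tolerance (default 1%) are "flat". The
labels are: purple (up under both constraints), pink (up under degree
only, down under degree-degree), cyan and green (down under both, steeper
under the degree-degree or the degree constraint respectively), and
irregular for anything flat or down-then-up. "Steeper" is reported only
for joint decreases — the mode with the lower mean final count — since a
steepness comparison between an increase and a decrease has no single
reading; the published pattern set needs it only there. The exact
increase/decrease threshold used in the original analyses is not public;
the 1% tolerance is this package's explicit substitute.

The resilient core intersects the original network's loop set with the
loop sets of every replica's final network, per length. Loop identity is
by canonical node sequence (labels persist through rewiring). Retention is
core/original; the induced subnetwork contains exactly the nodes and edges
of core loops. A constructive guarantee anchors the tests: a planted
triangle whose members' degree is unique in the network admits no
degree-degree-constrained swap on its edges (any partner edge would need
an endpoint of equal degree, and the triangle's own edges always share a
node), so it must be retained with fraction 1.

## Topology profile

Conventions were fixed to match the magnitudes conventional in published
network tables: kk_corr is the edgewise mean of deg(u)·deg(v) (large in
hub-rich networks, ≥ k_min²); eigenvector centrality is the principal
adjacency eigenvector at unit Euclidean norm (mean component ≈ 1/√NP),
computed densely below 500 nodes and by sparse Lanczos iteration above;
betweenness is unnormalised and averaged over nodes, with shortest paths
unweighted and disconnected networks allowed; assortativity is the Pearson
correlation over the 2·NI ordered edge-end degree pairs, reported as NaN
(undefined) rather than 0 for degree-regular graphs. Exact reproduction of
any specific published table may require adjusting these conventions —
centrality normalisations are rarely stated in print.

PCA for network classification uses four near-independent descriptors
(NI, kk_corr, assortativity, mean eigenvector centrality), standardised to
mean 0 / sd 1 so the decomposition acts on the correlation matrix;
profiles with an undefined descriptor are excluded with a warning, a
variable with zero variance is an error, and each component's sign is
fixed so its largest-magnitude loading is positive. The implementation
delegates to scikit-learn and is verified against a direct
eigendecomposition of the correlation matrix.

## Functional consensus

The consensus denominator is the union of the loop members' term sets —
"the fraction of annotated terms common to all members" read as terms
annotated *within the loop*. This makes the statistic bounded, symmetric
and equal to 100% exactly when all members carry identical sets. Loops
containing an unannotated protein are excluded from consensus statistics
and reported separately. Annotation sets are propagated to ancestors over
is_a/part_of by default (excluding the aspect root); propagation is
toggleable since consensus "independently of hierarchy level" admits both
readings. The resampling null draws unconstrained uniform sets of
annotated proteins — not connected subgraphs — so its p-value asks whether
loop membership (not mere adjacency) concentrates function; the
add-one-smoothed estimator p = (1+#{null ≥ observed})/(1+n) never returns
0. No multiple-testing correction is applied; p-values are reported raw.

The term-frequency table excludes general terms: the aspect root, depth-1
terms, and depth-2 terms with more than 4 direct children, with depth the
shortest is_a/part_of distance from the root. Loop frequency of a term
counts loops whose *consensus set* contains the term (an any-member
variant is available behind a flag). Trend labels order their rules as
Trend 1 (all loop frequencies above network), then Trend 3 (monotone
decreasing with length, all below network), then Trend 2 (all below,
non-monotone); in the large-complex-removed analysis only the above/below
dichotomy remains, labelled 4 and 5.

## Synthetic fixtures

The generator emulates what the analyses assume about real PPINs: sparse
hub-rich wiring (power-law degrees, default exponent 2.5, k_min 2, cap
100 — mean degree ≈ 4, the regime of mid-size two-hybrid screens),
planted cliques standing in for protein complexes, and module-structured
annotations (members of a module carry each of its terms with probability
`coherence`; everyone carries background terms at a background rate). The
configuration model tries clash-free stub matching up to 100 times and
falls back to collapsing the multigraph and repairing degree deficits by
local rewiring; the realised sequence stays within 5% L1 distance of the
target. A miniature three-level biological-process ontology (~50 terms)
is generated in OBO format so GO-dependent paths run offline.

What the fixtures do **not** establish: real annotation is incomplete,
hierarchical and biased toward well-studied complexes; real networks mix
detection-method artefacts with biology; and the planted-module geometry
is cleaner than any purification experiment. Passing tests show the
machinery is correct and the statistics behave as designed under the
stated conditions — not that any particular organism's network will show
a given trend.

## Problem sizes

Default analysis scales were chosen to keep every routine exact rather
than approximate: oracle cross-validation on graphs of ≤25 nodes across
the 0.05–0.5 density range; conservation checks on a 500-node
configuration model sampled every NI of 100·NI moves; the Hamming plateau
on a 2000-node, ~4000-edge network; resilience on 40-node guarded
fixtures over 5 replicas (20 independent runs for the destruction rate);
and 10,000 resampling draws for consensus p-values.
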