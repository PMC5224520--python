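# shortloops

Short-loop profiling of protein–protein interaction networks (PPINs).

Protein interactions detected by yeast two-hybrid, AP-MS or complex
purification assemble into sparse, hub-rich networks whose small cyclic
motifs — *short loops*, simple cycles of 3–6 proteins — concentrate
biological signal: proteins closing a loop tend to share a function, and
the loops a tailored null model cannot rewire away mark a functional core.
`shortloops` is a toolkit for systems biologists who want to profile those
motifs: it counts and enumerates loops exhaustively, builds
degree-constrained randomised ensembles for comparison, classifies how
loop counts respond to randomisation, extracts the resilient loop core,
and scores loops against Gene Ontology annotation.

## What it computes

**Loop census.** All simple cycles of length *l* ∈ {3,…,6} are counted by
a depth-first search bounded by loop length, rooted at each cycle's
lexicographically smallest node so every cycle-as-subgraph is counted
exactly once. A brute-force path-search oracle validates the census on
small graphs.

**Tailored null models (MCGD).** Randomised reference networks are
generated by Markov Chain Graph Dynamics: repeated edge swaps
(a,b),(c,d) → (a,d),(c,b) acting on quadruplets of nodes, which conserve
every degree k_i. Two constraint sets are supported — the degree sequence
{k} alone, or {k} plus the degree-degree correlation W(k,k′) (the joint
distribution of degrees at the two ends of an edge), enforced exactly by
rejecting any swap that would alter the edge degree-pair multiset.
Convergence is monitored by the Hamming distance between original and
rewired networks, normalised by C(NP,2) node pairs.

**Trend and resilience.** Comparing the original census with ensemble
equilibria under both constraint sets yields a four-pattern taxonomy
(purple/pink/cyan/green, plus irregular) of loop-count response, and the
*resilient core*: loops present in the original network and in every
replica of the degree-degree-constrained ensemble.

**Functional consensus.** For a loop with member term sets T_1,…,T_l
(GO biological process, propagated over is_a/part_of),

    consensus = 100 · |T_1 ∩ … ∩ T_l| / |T_1 ∪ … ∪ T_l| ,

with a binned distribution (25% bins), a resampling randomisation null
(uniform random sets of annotated proteins, p = (1 + #{null ≥ observed
mean}) / (1 + n_samples)), and a per-term frequency table comparing term
occurrence in loops of length 3–5 with the whole network.

**Topology profile.** NP, NI, mean/max degree, mean edgewise degree
product kk_corr, leading adjacency eigenvalue, eigenvector centrality,
mean betweenness, assortativity and transitivity per network, plus a PCA
classification of networks in descriptor space.

## Worked example

`examples/02_randomisation.py` plants three cliques in a 300-node
configuration-model network and randomises under both constraint sets:

```
original triangles: 118
mode=k: final triangles per replica [64, 42, 48, 50, 44] (hamming plateau 0.0260)
mode=kk: final triangles per replica [64, 59, 72, 50, 74] (hamming plateau 0.0252)
trend: green (k:down, kk:down, steeper:k)
```

Randomisation destroys the planted local structure (118 → ~50 triangles),
but constraining the degree-degree correlation preserves more of it
(~64 vs ~50): part of the loop wiring is encoded in W(k,k′). The joint
decrease that is steeper under the degree-only constraint is the "green"
pattern. `examples/04_functional_consensus.py` shows the functional side:
triangles inside an annotation-coherent complex score a mean consensus of
42.5% against a resampling null mean of 3.8% (p = 0.0022 at 10,000 draws).

The other examples cover the census/profile (`01`) and the resilient core
(`03`), including a planted triangle of uniquely-degreed proteins that is
provably frozen under the degree-degree constraint.

## Command line

The same pipeline is scriptable from a shell:

```sh
shortloops synth --nodes 300 --seed 3 --out net.tsv
shortloops loops --input net.tsv --out census.csv
shortloops randomise --input net.tsv --mode k  --replicas 5 --seed 1 --outdir rand/
shortloops randomise --input net.tsv --mode kk --replicas 5 --seed 1 --outdir rand/
shortloops trend --input net.tsv --ensembles rand/ --out trend.csv
shortloops core  --input net.tsv --ensembles rand/ --outdir core/
shortloops consensus --input net.tsv --annotations ann.tsv --ontology go.obo --outdir cons/
```

Inputs are two-column TSV or SIF edge lists (self-interactions and
duplicates are dropped on load), GAF 2.x or two-column TSV annotations,
and OBO ontologies. Every run writes a `run_config.json` echo with the
seed and package version.

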