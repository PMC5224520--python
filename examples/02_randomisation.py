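"""Compare a network's loop counts against degree-constrained null models.

Runs edge-swap randomisation (MCGD) under the two constraint sets — degree
sequence only ("k") and degree sequence plus degree-degree correlation
("kk") — and prints how triangle counts change and how far the rewired
network drifts (Hamming distance).  The trend label summarises the pattern:
a steeper decrease under "k" (green) means the degree-degree correlation
carries part of the loop wiring.
"""

from shortloops import classify_trend, count_loops, run_ensemble
from shortloops.synth import SynthConfig, configuration_model_graph, plant_clique

net = configuration_model_graph(SynthConfig(n_nodes=300, seed=23))
nodes = sorted(net.nodes)
for start, size in ((0, 6), (6, 6), (12, 5)):
    net = plant_clique(net, size, nodes=nodes[start:start + size])

orig = count_loops(net, 3, 3)
print(f"original triangles: {orig.counts[3]}")

ens = {}
for mode in ("k", "kk"):
    ens[mode] = run_ensemble(
        net, mode, n_replicas=5,
        total_moves=100 * net.n_interactions, base_seed=7, lengths=(3,),
        measure_every=20 * net.n_interactions,
    )
    finals = ens[mode].final_counts(3)
    last_hamming = ens[mode].replicas[0].trajectory.samples[-1].hamming
    print(
        f"mode={mode}: final triangles per replica {finals} "
        f"(hamming plateau {last_hamming:.4f})"
    )

pattern = classify_trend(orig, ens["k"], ens["kk"], length=3)
print(f"trend: {pattern.label} (k:{pattern.sign_k}, kk:{pattern.sign_kk}, steeper:{pattern.steeper})")
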