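"""Extract the resilient loop core of a network.

Plants a triangle whose three members have a degree unique in the network:
under degree-degree-constrained rewiring no admissible swap can touch its
edges, so it must appear in the core — the loops preserved in every
randomised replica.  Retention fractions per length quantify how much of
the original loop structure the tightest null model cannot explain away.
"""

import networkx as nx

from shortloops import InteractionNetwork, resilient_core, run_ensemble
from shortloops.synth import plant_clique

base = InteractionNetwork.from_networkx(nx.random_regular_graph(4, 40, seed=31))
for t in ("t1", "t2", "t3"):
    base.add_node(t)
net = plant_clique(base, 3, unique_degree_guard=True, nodes=["t1", "t2", "t3"])

ensemble = run_ensemble(
    net, "kk", n_replicas=5,
    total_moves=100 * net.n_interactions, base_seed=0, lengths=(3,),
)
core = resilient_core(net, ensemble, lengths=(3,))

print(f"core loops of length 3: {len(core.loops[3])}")
print(f"retention fraction: {core.retention_fraction[3]:.3f}")
print(f"core proteins: {sorted(core.proteins)}")
print("planted triangle in core:", ("t1", "t2", "t3") in core.loops[3])
print("(the guarded triangle is provably frozen; background 4-regular "
      "triangles may be rewired away)")
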