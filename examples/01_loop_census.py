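"""Count short loops in a small interaction network.

Builds a hub-rich configuration-model network, counts all simple cycles of
length 3-6 and prints the census alongside the topological profile.  Loop
counts grow steeply with length even in sparse networks; the profile row
carries the descriptors (mean/max degree, degree-degree correlation,
assortativity, transitivity) used to compare networks between experiments.
"""

from shortloops import compute_profile, count_loops
from shortloops.synth import SynthConfig, configuration_model_graph

net = configuration_model_graph(SynthConfig(n_nodes=400, seed=1))
print(f"network: NP={net.n_proteins} proteins, NI={net.n_interactions} interactions")

census = count_loops(net)
for length, count in census.counts.items():
    print(f"  loops of length {length}: {count}")

profile = compute_profile(net)
print(
    f"k_mean={profile.k_mean:.2f} k_max={profile.k_max} "
    f"kk_corr={profile.kk_corr:.1f} assort={profile.assort:.2f} "
    f"transitivity={profile.transitivity:.4f}"
)
print("(hub-rich wiring: kk_corr far above k_mean^2 signals degree-degree correlation)")
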