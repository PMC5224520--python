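"""Measure the functional consensus of loops against module annotations.

Builds a network with a planted protein complex (8-clique) whose members
share a coherent block of biological-process terms, scores every triangle
by functional consensus (the percentage of terms shared by all members,
of the terms annotated within the loop), bins the distribution, and runs a
10,000-draw resampling randomisation test: loops score far above random
protein sets of the same size.
"""

from shortloops import consensus_distribution, enumerate_loops, resampling_null
from shortloops.synth import (
    SynthConfig,
    er_graph,
    plant_clique,
    synthetic_annotations,
)

net = er_graph(80, 0.04, seed=19)
nodes = sorted(net.nodes)
clique = nodes[:8]
net = plant_clique(net, 8, nodes=clique)
ann = synthetic_annotations(
    net, [clique],
    SynthConfig(coherence=1.0, background_rate=0.3, terms_per_module=5, seed=4),
)

loops = {3: enumerate_loops(net, 3)}
result = consensus_distribution(loops, ann)
print("consensus histogram (bins [0,25) [25,50) [50,75) [75,100]):")
print("  ", [f"{f:.2f}" for f in result.histogram[3]],
      f"({result.excluded[3]} loops excluded: unannotated member)")

test = resampling_null(net, ann, set_size=3, n_samples=10_000, seed=2,
                       observed_loops=loops[3])
print(f"observed mean consensus: {test.observed_mean:.1f}%")
print(f"null mean: {test.null.mean():.1f}%  resampling p = {test.p_value:.2g}")
print("(p << 0.01: loop members share functions far beyond chance)")
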