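"""Build the 82-region bilateral analysis network and filter weak projections.

The packaged region nomenclature (38 bilaterally mirrored Fos-expressing
regions plus 6 left-hemisphere lesion regions) is combined with a synthetic
mesoscale connectome standing in for the unpublished curated one.
"""

from strokenet import LesionSet, build_bilateral_network, filter_by_weight
from strokenet.datasets import fos_region_abbreviations, lesion_region_abbreviations
from strokenet.metrics import global_parameters
from strokenet.pipeline import reference_connectome

source = reference_connectome(seed=1)
lesion = LesionSet([a + "_L" for a in lesion_region_abbreviations()])
network = build_bilateral_network(fos_region_abbreviations(), lesion, source)
g = global_parameters(network)
print(f"bilateral network: {g.n_regions} regions, {g.n_edges} directed connections")
print(f"reciprocal pairs: {g.n_reciprocal_pairs}")
print(f"average pathlength {g.avg_pathlength:.3f}, directed clustering {g.avg_clustering:.3f}")

strong = filter_by_weight(network, 1.5)  # keep projections of at least moderate strength
print(f"after dropping sub-moderate weights (< 1.5): {strong.n_edges} connections remain")
print("-> the network keeps every region as a node; only weak projections are pruned")
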