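"""Distance-to-lesion versus hypoactivation on a synthetic per-animal dataset.

The generator plants an ipsilesional hypoactivation that decays exponentially
with Euclidean distance from the nearest lesioned region (depth 0.8, length
constant 2 mm). The analysis recovers it: the hypoactivation magnitude
(−Dr of the stroke-at-exploration contrast) correlates negatively with the
distance to each damaged region.
"""

import pandas as pd

from strokenet.association import distance_fos_correlation, euclidean_distance_matrix
from strokenet.fos import effects_table, group_means
from strokenet.synthetic import SimConfig, default_lesion_set, generate_connectome, generate_fos

cfg = SimConfig(seed=4)
c = generate_connectome(cfg)
lesion = default_lesion_set(c)
fos_table, truth = generate_fos(cfg, c, lesion)

means = group_means(fos_table)
stroke = effects_table(means, "stroke@expl", sides=("ipsi",))
hypo = pd.Series((-stroke.Dr).to_numpy(), index=[r + "_L" for r in stroke.region])

dm = euclidean_distance_matrix(c)
out = distance_fos_correlation(dm, lesion, hypo).sort_values("r")
print("Pearson r between distance-to-damaged-region and hypoactivation magnitude:")
for _, row in out.iterrows():
    print(f"  {row.damaged_region}: r = {row.r:+.3f} (n = {row.n})")
print("-> strongly negative r: the closer a region sits to the lesion, the more "
      "its exploration-induced activation is suppressed")
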