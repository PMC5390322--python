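"""Exploration and stroke effects from the packaged group-mean Fos table.

Relative differences Dr = (mean_test − mean_reference)/mean_reference:
positive for activation relative to the reference group, negative for
hypoactivation. The exploration contrast compares exploring vs home-caged
sham animals; the stroke contrast compares dMCAO vs sham animals during
exploration, on the ipsilesional side.
"""

from strokenet.datasets import load_table1
from strokenet.fos import effects_table, mean_absolute_difference, means_from_table1

means = means_from_table1(load_table1())

expl = effects_table(means, "explore@sham", sides=("ipsi",)).set_index("region")
print(f"exploration activated {(expl.Dr > 0).sum()} of {len(expl)} regions "
      f"(mean |Dr| = {mean_absolute_difference(expl.Dr):.2f})")
print("strongest exploration responses (Dr = fold-change minus one):")
for region, row in expl.nlargest(3, "Dr").iterrows():
    print(f"  {region}: {row.mean_ref:.1f} -> {row.mean_test:.1f} cells/mm2, Dr = {row.Dr:+.2f}")

stroke = effects_table(means, "stroke@expl", sides=("ipsi",)).set_index("region")
print("\nstrongest ipsilesional hypoactivation during exploration:")
for region, row in stroke.nsmallest(3, "Dr").iterrows():
    print(f"  {region}: {row.mean_ref:.1f} -> {row.mean_test:.1f} cells/mm2, Dr = {row.Dr:+.2f}")
print("-> Dr < 0 marks regions whose activation collapses after cortical stroke")
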