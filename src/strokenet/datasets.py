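"""Packaged reference data: group-mean Fos densities and the region lists.

The packaged table transcribes the published group means (cells/mm²) for the
38 constitutively Fos-expressing regions across the four experimental groups
(sham/dMCAO surgery × home-cage/exploration environment). Per-animal counts
were never deposited, so only means are available here; per-animal tables come
from :mod:`strokenet.synthetic`.

Two printed abbreviations are normalized to the axis-label nomenclature used
for network nodes: ``cRSP`` → ``RSGca`` (caudal retrosplenial granular cortex)
and ``Sch`` → ``SCh`` (suprachiasmatic nucleus).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_table1",
    "fos_region_abbreviations",
    "lesion_region_abbreviations",
    "CANONICAL_ABBREVIATIONS",
]

#: Printed-table spelling -> network node abbreviation.
CANONICAL_ABBREVIATIONS = {"cRSP": "RSGca", "Sch": "SCh"}

#: The six dMCAO-damaged regions (left hemisphere): agranular insular cortex
#: (dorsal and ventral parts), dysgranular and granular insular cortex,
#: primary somatosensory cortex, parietal association cortex.
LESION_ABBREVIATIONS = ("AID", "AIV", "DI", "GI", "S1", "PtA")


def load_table1(canonical: bool = True) -> pd.DataFrame:
    """Group-mean Fos densities per region (cells/mm²).

    Columns: ``region``, ``sham_home``, ``sham_expl``, ``mcao_expl_ipsi``,
    ``mcao_expl_contra``. With ``canonical=True`` region abbreviations are
    mapped to the network node nomenclature.
    """
    with resources.files("strokenet.data").joinpath("table1_means.csv").open() as fh:
        df = pd.read_csv(fh)
    if canonical:
        df["region"] = df["region"].replace(CANONICAL_ABBREVIATIONS)
    return df


def fos_region_abbreviations() -> list[str]:
    """The 38 bilaterally mirrored Fos-expressing region abbreviations."""
    return list(load_table1()["region"])


def lesion_region_abbreviations() -> list[str]:
    """The six stroke-damaged (left-hemisphere) region abbreviations."""
    return list(LESION_ABBREVIATIONS)
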