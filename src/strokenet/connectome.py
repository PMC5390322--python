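"""Data model and I/O for regions and the directed weighted bilateral network.

The mesoscale connectome is represented as a :class:`Connectome`: a set of
:class:`Region` records (identity, hemisphere, lesion flag, stereotaxic
centre-of-gravity coordinates) plus a directed, weighted :class:`networkx.DiGraph`
whose nodes are region ids. Region ids follow the ``<abbrev>_<L|R|M>`` convention
(e.g. ``"PtA_L"``), so a bilateral region appears as two nodes.

Edge weights are semiquantitative projection strengths on a continuous ordinal
scale with conventional anchors 0.5 (very light), 1 (light), 2 (moderate),
3 (strong), 4 (very strong).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Region",
    "Connectome",
    "LesionSet",
    "ConnectomeError",
    "load_connectome",
    "write_connectome",
    "build_bilateral_network",
    "filter_by_weight",
    "export_graphml",
    "export_adjacency_csv",
    "WEIGHT_ANCHORS",
]

#: Conventional semiquantitative strength anchors.
WEIGHT_ANCHORS = {"very light": 0.5, "light": 1.0, "moderate": 2.0, "strong": 3.0, "very strong": 4.0}

HEMISPHERES = ("left", "right", "midline")
_HEMI_SUFFIX = {"left": "L", "right": "R", "midline": "M"}


class ConnectomeError(ValueError):
    """Raised when a connectome violates its structural contract."""


@dataclass(frozen=True)
class Region:
    """A brain region (graph node) with stereotaxic metadata.

    Coordinates are the centre of gravity of the region in stereotaxic
    millimetres, ordered (x, y, z) with x the medio-lateral axis (negated for
    the contralateral mirror image).
    """

    region_id: str
    name: str
    abbreviation: str
    hemisphere: str
    lesioned: bool = False
    coordinates: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ConnectomeError(
                f"region {self.region_id!r}: hemisphere must be one of {HEMISPHERES}, got {self.hemisphere!r}"
            )
        if self.lesioned and self.hemisphere != "left":
            raise ConnectomeError(
                f"region {self.region_id!r}: lesioned regions must be in the left (ipsilesional) hemisphere"
            )
        if not np.all(np.isfinite(self.coordinates)) or len(self.coordinates) != 3:
            raise ConnectomeError(f"region {self.region_id!r}: coordinates must be three finite numbers")

    def mirrored(self) -> "Region":
        """Contralateral counterpart: medio-lateral coordinate negated."""
        other = {"left": "right", "right": "left"}.get(self.hemisphere)
        if other is None:
            raise ConnectomeError(f"cannot mirror midline region {self.region_id!r}")
        x, y, z = self.coordinates
        return replace(
            self,
            region_id=f"{self.abbreviation}_{_HEMI_SUFFIX[other]}",
            hemisphere=other,
            lesioned=False,
            coordinates=(-x, y, z),
        )


@dataclass(frozen=True)
class LesionSet:
    """Non-empty set of lesioned (left-hemisphere) region ids."""

    region_ids: frozenset[str]

    def __init__(self, region_ids: Iterable[str]):
        ids = frozenset(region_ids)
        if not ids:
            raise ConnectomeError("lesion set must be non-empty")
        object.__setattr__(self, "region_ids", ids)

    def __iter__(self):
        return iter(sorted(self.region_ids))

    def __len__(self) -> int:
        return len(self.region_ids)

    def __contains__(self, region_id: str) -> bool:
        return region_id in self.region_ids

    def validate(self, c: "Connectome") -> None:
        for rid in self.region_ids:
            if rid not in c.regions:
                raise ConnectomeError(f"lesion region {rid!r} not in connectome")
            if not c.regions[rid].lesioned:
                raise ConnectomeError(f"lesion region {rid!r} is not flagged lesioned")


class Connectome:
    """Directed weighted labelled graph over a set of regions.

    Invariants enforced at construction: unique region ids, every edge endpoint
    resolves to a region, non-negative weights, no duplicate directed edges, and
    (by default) no self-loops.
    """

    def __init__(
        self,
        regions: Iterable[Region],
        edges: Iterable[tuple[str, str, float]] = (),
        allow_self_loops: bool = False,
    ):
        self.regions: dict[str, Region] = {}
        for r in regions:
            if r.region_id in self.regions:
                raise ConnectomeError(f"duplicate region id {r.region_id!r}")
            self.regions[r.region_id] = r
        self.allow_self_loops = allow_self_loops
        g = nx.DiGraph()
        g.add_nodes_from(self.regions)
        for src, dst, w in edges:
            for endpoint in (src, dst):
                if endpoint not in self.regions:
                    raise ConnectomeError(f"edge endpoint {endpoint!r} is not a known region")
            if src == dst and not allow_self_loops:
                raise ConnectomeError(f"self-loop on {src!r} (self-loops disabled)")
            w = float(w)
            if w < 0:
                raise ConnectomeError(f"negative weight {w} on edge {src!r}->{dst!r}")
            if g.has_edge(src, dst):
                raise ConnectomeError(f"duplicate directed edge {src!r}->{dst!r}")
            g.add_edge(src, dst, weight=w)
        self.graph = g

    # -- basic views -------------------------------------------------------
    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def node_order(self) -> list[str]:
        """Regions in insertion order (the region-table row order)."""
        return list(self.regions)

    def edge_list(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]

    def adjacency_matrix(self, weighted: bool = True, order: Sequence[str] | None = None) -> np.ndarray:
        """Dense adjacency; rows are outputs (sources), columns are inputs (targets)."""
        order = list(order) if order is not None else self.node_order
        index = {rid: i for i, rid in enumerate(order)}
        a = np.zeros((len(order), len(order)))
        for u, v, w in self.edge_list():
            a[index[u], index[v]] = w if weighted else 1.0
        return a

    def coordinates(self, order: Sequence[str] | None = None) -> np.ndarray:
        order = list(order) if order is not None else self.node_order
        return np.array([self.regions[rid].coordinates for rid in order], float)

    def subgraph(self, region_ids: Iterable[str]) -> "Connectome":
        """Induced subgraph on ``region_ids`` (order preserved from this connectome)."""
        keep = set(region_ids)
        unknown = keep - set(self.regions)
        if unknown:
            raise ConnectomeError(f"unknown region id(s): {sorted(unknown)}")
        regions = [self.regions[rid] for rid in self.node_order if rid in keep]
        edges = [(u, v, w) for u, v, w in self.edge_list() if u in keep and v in keep]
        return Connectome(regions, edges, allow_self_loops=self.allow_self_loops)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Connectome):
            return NotImplemented
        return self.regions == other.regions and set(self.edge_list()) == set(other.edge_list())

    def __repr__(self) -> str:
        return f"<Connectome: {self.n_regions} regions, {self.n_edges} edges>"


# ---------------------------------------------------------------------------
# I/O

REGION_COLUMNS = ["region_id", "name", "abbreviation", "hemisphere", "lesioned", "x_mm", "y_mm", "z_mm"]
EDGE_COLUMNS = ["source_id", "target_id", "weight"]


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep)


def load_connectome(region_table: str | Path, edge_table: str | Path, allow_self_loops: bool = False) -> Connectome:
    """Load a connectome from a region CSV/TSV and an edge CSV/TSV.

    Duplicate directed edges are collapsed by keeping the maximum weight, with
    a logged warning. An edge referencing an unknown region id raises
    :class:`ConnectomeError` naming the id.
    """
    rdf = _read_table(region_table)
    missing = [c for c in REGION_COLUMNS if c not in rdf.columns]
    if missing:
        raise ConnectomeError(f"region table missing column(s) {missing}")
    regions = [
        Region(
            region_id=str(row.region_id),
            name=str(row.name_),
            abbreviation=str(row.abbreviation),
            hemisphere=str(row.hemisphere),
            lesioned=bool(row.lesioned),
            coordinates=(float(row.x_mm), float(row.y_mm), float(row.z_mm)),
        )
        for row in rdf.rename(columns={"name": "name_"}).itertuples(index=False)
    ]
    edf = _read_table(edge_table)
    missing = [c for c in EDGE_COLUMNS if c not in edf.columns]
    if missing:
        raise ConnectomeError(f"edge table missing column(s) {missing}")
    known = {r.region_id for r in regions}
    collapsed: dict[tuple[str, str], float] = {}
    n_dup = 0
    for row in edf.itertuples(index=False):
        src, dst, w = str(row.source_id), str(row.target_id), float(row.weight)
        for endpoint in (src, dst):
            if endpoint not in known:
                raise ConnectomeError(f"edge table references unknown region id {endpoint!r}")
        if w < 0:
            raise ConnectomeError(f"negative weight {w} on edge {src!r}->{dst!r}")
        key = (src, dst)
        if key in collapsed:
            n_dup += 1
            collapsed[key] = max(collapsed[key], w)
        else:
            collapsed[key] = w
    if n_dup:
        warnings.warn(f"collapsed {n_dup} duplicate directed edge(s), keeping maximum weight", stacklevel=2)
    return Connectome(regions, [(s, t, w) for (s, t), w in collapsed.items()], allow_self_loops=allow_self_loops)


def write_connectome(c: Connectome, region_table: str | Path, edge_table: str | Path) -> None:
    """Write region and edge tables; exact round-trip with :func:`load_connectome`."""
    rows = [
        {
            "region_id": r.region_id,
            "name": r.name,
            "abbreviation": r.abbreviation,
            "hemisphere": r.hemisphere,
            "lesioned": r.lesioned,
            "x_mm": r.coordinates[0],
            "y_mm": r.coordinates[1],
            "z_mm": r.coordinates[2],
        }
        for r in c.regions.values()
    ]
    pd.DataFrame(rows, columns=REGION_COLUMNS).to_csv(region_table, index=False)
    pd.DataFrame(c.edge_list(), columns=EDGE_COLUMNS).to_csv(edge_table, index=False)


def export_graphml(c: Connectome, path: str | Path) -> None:
    """GraphML export with region metadata as node attributes and weights on edges."""
    g = c.graph.copy()
    for rid, r in c.regions.items():
        g.nodes[rid].update(
            name=r.name,
            abbreviation=r.abbreviation,
            hemisphere=r.hemisphere,
            lesioned=r.lesioned,
            x_mm=r.coordinates[0],
            y_mm=r.coordinates[1],
            z_mm=r.coordinates[2],
        )
    nx.write_graphml(g, path)


def export_adjacency_csv(c: Connectome, path: str | Path, weighted: bool = True) -> None:
    """Square adjacency matrix ordered by region_id; rows are outputs, columns inputs."""
    order = sorted(c.node_order)
    a = c.adjacency_matrix(weighted=weighted, order=order)
    pd.DataFrame(a, index=order, columns=order).to_csv(path)


# ---------------------------------------------------------------------------
# Construction

def build_bilateral_network(
    fos_region_abbrevs: Sequence[str],
    lesion: LesionSet,
    source: Connectome,
) -> Connectome:
    """Induced subgraph on the bilateral instances of the Fos regions plus the lesion regions.

    Every Fos abbreviation must exist in both hemispheres of ``source``; the
    node count is ``2 * len(fos_region_abbrevs) + |lesion regions not already
    included|``. Deterministic and idempotent for fixed arguments.
    """
    lesion.validate(source)
    by_abbrev: dict[tuple[str, str], str] = {}
    for rid, r in source.regions.items():
        by_abbrev[(r.abbreviation, r.hemisphere)] = rid
    keep: list[str] = []
    for ab in fos_region_abbrevs:
        pair = [by_abbrev.get((ab, "left")), by_abbrev.get((ab, "right"))]
        if None in pair:
            raise ConnectomeError(f"Fos region {ab!r} lacks a hemispheric counterpart in the source connectome")
        keep.extend(pair)  # type: ignore[arg-type]
    for rid in lesion:
        if rid not in keep:
            keep.append(rid)
    return source.subgraph(keep)


def filter_by_weight(c: Connectome, threshold: float) -> Connectome:
    """Drop edges with weight strictly below ``threshold`` (>= survives); nodes retained."""
    if threshold < 0:
        raise ConnectomeError("threshold must be >= 0")
    edges = [(u, v, w) for u, v, w in c.edge_list() if w >= threshold]
    return Connectome(c.regions.values(), edges, allow_self_loops=c.allow_self_loops)
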