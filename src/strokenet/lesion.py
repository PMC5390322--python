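"""Node-removal lesion simulation.

Removing a lesion set from the connectome emulates the structural effect of
the infarct: the induced subgraph on the complement is compared with the
intact graph through global parameters, and each region's *vulnerability*
quantifies how much the network's average closeness drops when that single
region is deleted (positive = closeness decreases = the region matters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectome import Connectome, ConnectomeError, LesionSet
from .metrics._paths import avg_out_closeness, length_matrix
from .metrics.globalstats import (
    EnsembleStats,
    GlobalParams,
    global_parameters,
    randomized_ensemble,
    small_worldness,
)

__all__ = ["LesionResult", "remove_regions", "vulnerability", "lesion_delta"]


@dataclass
class LesionResult:
    """Before/after global parameters with relative deltas and per-region vulnerability."""

    removed: LesionSet | set[str]
    globals_before: GlobalParams
    globals_after: GlobalParams
    relative_delta: dict[str, float]
    vulnerability: dict[str, float]

    def to_dict(self) -> dict:
        removed = self.removed.region_ids if isinstance(self.removed, LesionSet) else self.removed
        return {
            "removed": sorted(removed),
            "globals_before": self.globals_before.to_dict(),
            "globals_after": self.globals_after.to_dict(),
            "relative_delta_percent": {k: 100.0 * v for k, v in self.relative_delta.items()},
            "vulnerability": dict(self.vulnerability),
        }


def remove_regions(c: Connectome, lesion: LesionSet | set[str]) -> Connectome:
    """Induced subgraph on the complement of the lesion set."""
    ids = set(lesion.region_ids) if isinstance(lesion, LesionSet) else set(lesion)
    unknown = ids - set(c.regions)
    if unknown:
        raise ConnectomeError(f"unknown region id(s): {sorted(unknown)}")
    remaining = [rid for rid in c.node_order if rid not in ids]
    if not remaining:
        raise ConnectomeError("removing every region would leave an empty graph")
    return c.subgraph(remaining)


def vulnerability(c: Connectome, region_id: str, mode: str = "unweighted", closeness: str = "out") -> float:
    """V = avgCloseness(G) − avgCloseness(G − region); positive when removal hurts.

    Closeness is computed over reachable sets. ``closeness`` selects the
    out-distance convention (default), ``"in"`` the transpose, ``"all"`` the
    symmetrized structure.
    """
    if region_id not in c.regions:
        raise ConnectomeError(f"unknown region id {region_id!r}")
    if c.n_regions < 3:
        raise ConnectomeError("vulnerability needs at least 3 regions")
    order = c.node_order
    a = c.adjacency_matrix(weighted=True)
    if closeness == "in":
        a = a.T
    elif closeness == "all":
        a = np.maximum(a, a.T)
    elif closeness != "out":
        raise ValueError(f"closeness must be 'out', 'in' or 'all', got {closeness!r}")
    lengths = length_matrix(a, weighted=(mode == "weighted"))
    i = order.index(region_id)
    keep = np.array([j for j in range(len(order)) if j != i])
    return float(avg_out_closeness(lengths) - avg_out_closeness(lengths[np.ix_(keep, keep)]))


def lesion_delta(
    c: Connectome,
    lesion: LesionSet | set[str],
    ensemble_reps: int = 50,
    seed: int | None = 0,
    compute_vulnerability: bool = True,
) -> LesionResult:
    """Global-parameter change caused by removing the lesion set.

    Relative deltas are (after − before)/before per field. Small-worldness of
    both graphs is scored against one randomized ensemble matched to the
    post-lesion (n, m), so an empty lesion is exactly the identity.
    """
    ids = set(lesion.region_ids) if isinstance(lesion, LesionSet) else set(lesion)
    if isinstance(lesion, LesionSet):
        lesion.validate(c)
    if len(ids) >= c.n_regions:
        raise ConnectomeError("lesion set must leave at least one region")
    before = global_parameters(c)
    after_graph = remove_regions(c, ids) if ids else c
    after = global_parameters(after_graph)
    rng = np.random.default_rng(seed)
    ens_seed = int(rng.integers(0, 2**31 - 1))
    ensemble = None
    if after.n_edges > 0 and np.isfinite(after.avg_pathlength):
        ensemble = randomized_ensemble(after.n_regions, after.n_edges, reps=ensemble_reps, seed=ens_seed)
    before.small_worldness = _against_ensemble(before, ensemble)
    after.small_worldness = _against_ensemble(after, ensemble)
    fields = ["n_edges", "n_reciprocal_pairs", "avg_pathlength", "avg_clustering", "small_worldness"]
    rel: dict[str, float] = {}
    for f in fields:
        b, a_val = getattr(before, f), getattr(after, f)
        if b is None or a_val is None or not np.isfinite(b) or b == 0:
            rel[f] = float("nan")
        else:
            rel[f] = float((a_val - b) / b)
    vul = {}
    if compute_vulnerability:
        vul = {rid: vulnerability(c, rid) for rid in c.node_order}
    return LesionResult(
        removed=lesion if isinstance(lesion, LesionSet) else LesionSet(ids) if ids else lesion,
        globals_before=before,
        globals_after=after,
        relative_delta=rel,
        vulnerability=vul,
    )


def _against_ensemble(g: GlobalParams, ensemble: EnsembleStats | None) -> float | None:
    if ensemble is None or g.n_edges == 0 or not np.isfinite(g.avg_pathlength):
        return None
    try:
        return small_worldness(g, ensemble)
    except ValueError:
        return None
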