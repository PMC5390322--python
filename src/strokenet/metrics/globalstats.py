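"""Whole-graph summaries and the size-matched random-graph baseline.

Global parameters follow the conventions used throughout the package:

* ``avg_pathlength`` — mean shortest-path hop distance over *reachable*
  ordered pairs (no infinite-distance imputation).
* ``avg_clustering`` — mean over nodes of the directed clustering
  coefficient: the density of directed links within the union (in ∪ out)
  neighbourhood. On a uniform random digraph its expectation is the edge
  density, which is what makes the random-baseline value interpretable.
* ``n_reciprocal_pairs`` — unordered node pairs connected in both directions.

The randomized baseline is the null model with the same number of nodes and
edges but uniformly random connections (no self-loops, no duplicates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..connectome import Connectome
from ._paths import distance_matrix

__all__ = [
    "GlobalParams",
    "EnsembleStats",
    "directed_union_clustering",
    "global_parameters",
    "randomized_ensemble",
    "small_worldness",
]


@dataclass
class GlobalParams:
    """Whole-graph summary; ``small_worldness`` stays None until an ensemble is supplied."""

    n_regions: int
    n_edges: int
    n_reciprocal_pairs: int
    avg_pathlength: float
    avg_clustering: float
    small_worldness: float | None = None

    def to_dict(self) -> dict:
        return {
            "n_regions": self.n_regions,
            "n_edges": self.n_edges,
            "n_reciprocal_pairs": self.n_reciprocal_pairs,
            "avg_pathlength": self.avg_pathlength,
            "avg_clustering": self.avg_clustering,
            "small_worldness": self.small_worldness,
        }


@dataclass
class EnsembleStats:
    """Randomized-baseline ensemble: per-replicate globals plus mean/SD summaries."""

    reps: int
    seed: int | None
    replicates: list[GlobalParams]
    mean: dict[str, float] = field(init=False)
    sd: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        fields = ["n_edges", "n_reciprocal_pairs", "avg_pathlength", "avg_clustering"]
        arrays = {f: np.array([getattr(r, f) for r in self.replicates], float) for f in fields}
        self.mean = {f: float(np.nanmean(v)) for f, v in arrays.items()}
        self.sd = {f: float(np.nanstd(v)) for f, v in arrays.items()}

    def to_dict(self) -> dict:
        return {"reps": self.reps, "seed": self.seed, "mean": self.mean, "sd": self.sd}


def directed_union_clustering(adjacency: np.ndarray) -> np.ndarray:
    """Per-node directed link density within the union neighbourhood; 0 if < 2 neighbours."""
    a = np.asarray(adjacency) > 0
    n = a.shape[0]
    nb = a | a.T
    np.fill_diagonal(nb, False)
    out = np.zeros(n)
    for i in range(n):
        idx = np.flatnonzero(nb[i])
        k = idx.size
        if k < 2:
            continue
        out[i] = a[np.ix_(idx, idx)].sum() / (k * (k - 1))
    return out


def _globals_from_adjacency(a: np.ndarray) -> GlobalParams:
    binary = np.asarray(a) > 0
    n = binary.shape[0]
    m = int(binary.sum())
    recip = int((binary & binary.T).sum() // 2)
    if m == 0:
        pathlength = float("nan")
    else:
        d = distance_matrix(binary.astype(float))
        off = ~np.eye(n, dtype=bool)
        finite = np.isfinite(d) & off
        pathlength = float(d[finite].mean()) if finite.any() else float("nan")
    clustering = float(directed_union_clustering(binary).mean()) if n else float("nan")
    return GlobalParams(n, m, recip, pathlength, clustering)


def global_parameters(c: Connectome) -> GlobalParams:
    """Global network parameters of a connectome (hop-based, binary structure)."""
    if c.n_regions == 0:
        raise ValueError("global parameters are undefined for an empty graph")
    return _globals_from_adjacency(c.adjacency_matrix(weighted=False))


def random_directed_adjacency(n: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform directed graph with exactly ``n`` nodes and ``m`` edges."""
    slots = n * (n - 1)
    if not 0 <= m <= slots:
        raise ValueError(f"edge count {m} out of range for {n} nodes (max {slots})")
    chosen = rng.choice(slots, size=m, replace=False)
    rows, cols = divmod(chosen, n - 1)
    cols = cols + (cols >= rows)  # skip the diagonal slot
    a = np.zeros((n, n), bool)
    a[rows, cols] = True
    return a


def randomized_ensemble(n: int, m: int, reps: int = 50, seed: int | None = None) -> EnsembleStats:
    """Global parameters over ``reps`` uniform directed graphs with ``n`` nodes, ``m`` edges."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    replicates = [_globals_from_adjacency(random_directed_adjacency(n, m, rng)) for _ in range(reps)]
    return EnsembleStats(reps=reps, seed=seed, replicates=replicates)


def small_worldness(g: GlobalParams, e: EnsembleStats) -> float:
    """S = (C / C_rand) / (L / L_rand) against the ensemble means; > 1 is small-world."""
    c_rand = e.mean["avg_clustering"]
    l_rand = e.mean["avg_pathlength"]
    if not c_rand > 0:
        raise ValueError("ensemble clustering mean must be positive")
    if not l_rand > 0 or not np.isfinite(l_rand):
        raise ValueError("ensemble pathlength mean must be positive and finite")
    return float((g.avg_clustering / c_rand) / (g.avg_pathlength / l_rand))
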