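"""Shared shortest-path machinery for the parameter registry.

All functions operate on dense adjacency arrays (rows = sources, columns =
targets). Unweighted distances are hop counts; weighted path metrics map an
edge weight ``w`` to a length ``1/w`` so that stronger projections are shorter.
Unreachable pairs carry ``inf``.
"""

from __future__ import annotations

import heapq

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = ["length_matrix", "distance_matrix", "path_counts", "out_closeness", "avg_out_closeness"]


def length_matrix(adjacency: np.ndarray, weighted: bool) -> np.ndarray:
    """Edge-length matrix: 1 per edge (unweighted) or 1/weight; 0 encodes no edge."""
    a = np.asarray(adjacency, float)
    if not weighted:
        return (a > 0).astype(float)
    with np.errstate(divide="ignore"):
        lengths = np.where(a > 0, 1.0 / np.where(a > 0, a, 1.0), 0.0)
    return lengths


def distance_matrix(lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances; diagonal 0, unreachable inf."""
    n = lengths.shape[0]
    if n == 0:
        return np.zeros((0, 0))
    unweighted = np.all(np.isin(lengths, (0.0, 1.0)))
    d = shortest_path(csr_matrix(lengths), method="D", directed=True, unweighted=unweighted)
    np.fill_diagonal(d, 0.0)
    return d


def path_counts(lengths: np.ndarray, rtol: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """Distances and shortest-path multiplicities ``sigma[s, t]`` per ordered pair.

    Dijkstra with path counting per source; ``sigma[s, s] = 1`` by convention.
    """
    n = lengths.shape[0]
    d = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    targets = [np.flatnonzero(lengths[u]) for u in range(n)]
    for s in range(n):
        dist = d[s]
        dist[s] = 0.0
        sig = sigma[s]
        sig[s] = 1.0
        done = np.zeros(n, bool)
        heap = [(0.0, s)]
        while heap:
            du, u = heapq.heappop(heap)
            if done[u]:
                continue
            done[u] = True
            for v in targets[u]:
                alt = du + lengths[u, v]
                if alt < dist[v] * (1 - rtol) or (not np.isfinite(dist[v]) and np.isfinite(alt)):
                    dist[v] = alt
                    sig[v] = sig[u]
                    heapq.heappush(heap, (alt, v))
                elif np.isfinite(dist[v]) and abs(alt - dist[v]) <= rtol * max(dist[v], 1.0):
                    sig[v] += sig[u]
    return d, sigma


def out_closeness(d: np.ndarray) -> np.ndarray:
    """Closeness over reachable sets, Wasserman–Faust scaled: (r/(n−1)) · (r/Σd).

    ``r`` is the number of reachable nodes. The reachability scaling keeps the
    score comparable across components: without it, fragmenting a graph can
    *increase* raw reachable-set closeness, inverting the sign convention of
    the vulnerability measure (a cut vertex must have positive vulnerability).
    """
    n = d.shape[0]
    if n <= 1:
        return np.zeros(n)
    finite = np.isfinite(d) & ~np.eye(n, dtype=bool)
    n_reach = finite.sum(axis=1)
    total = np.where(finite, d, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = np.where(total > 0, (n_reach / (n - 1)) * (n_reach / np.where(total > 0, total, 1.0)), 0.0)
    return cc


def avg_out_closeness(lengths: np.ndarray) -> float:
    """Mean out-closeness over all nodes (the vulnerability building block)."""
    return float(out_closeness(distance_matrix(lengths)).mean())
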