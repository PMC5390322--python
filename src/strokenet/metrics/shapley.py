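"""Game-theoretic region importance and the knotty-centre search.

The coalition game values a node subset ``S`` by the number of strongly
connected components of the induced subgraph, ``v(S) = #SCC(G[S])``. The
Shapley value of a node is its average marginal contribution ``v(S ∪ {i}) −
v(S)`` over orderings; a *more negative* value marks a region whose presence
merges components, i.e. a more integrative region.
"""

from __future__ import annotations

from itertools import combinations
from math import factorial

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = ["scc_game_value", "shapley_values", "knotty_centre"]

_EXACT_MAX_N = 8


def scc_game_value(adjacency: np.ndarray, members: np.ndarray) -> int:
    """Number of strongly connected components of the induced subgraph (0 for ∅)."""
    if len(members) == 0:
        return 0
    sub = adjacency[np.ix_(members, members)]
    n_comp, _ = connected_components(csr_matrix(sub), directed=True, connection="strong")
    return int(n_comp)


def _exact_shapley(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    values = np.zeros(1 << n)
    for mask in range(1, 1 << n):
        members = np.flatnonzero([(mask >> k) & 1 for k in range(n)])
        values[mask] = scc_game_value(a, members)
    coeff = [factorial(s) * factorial(n - s - 1) / factorial(n) for s in range(n)]
    phi = np.zeros(n)
    for i in range(n):
        bit = 1 << i
        for mask in range(1 << n):
            if mask & bit:
                continue
            s = bin(mask).count("1")
            phi[i] += coeff[s] * (values[mask | bit] - values[mask])
    return phi


def shapley_values(
    adjacency: np.ndarray,
    n_permutations: int = 5000,
    seed: int | None = None,
    method: str = "auto",
) -> np.ndarray:
    """Shapley values of the SCC-count game.

    ``method``: ``"exact"`` (all ``2^n`` coalitions; n ≤ 20 enforced),
    ``"mc"`` (seeded Monte-Carlo permutation estimate), or ``"auto"``
    (exact for n ≤ 8, Monte-Carlo otherwise).
    """
    a = (np.asarray(adjacency) > 0).astype(np.int8)
    n = a.shape[0]
    if method == "auto":
        method = "exact" if n <= _EXACT_MAX_N else "mc"
    if method == "exact":
        if n > 20:
            raise ValueError(f"exact Shapley enumeration is infeasible for n={n}")
        return _exact_shapley(a)
    if method != "mc":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    phi = np.zeros(n)
    cache: dict[int, int] = {0: 0}
    use_cache = n <= 24
    for _ in range(n_permutations):
        order = rng.permutation(n)
        prev = 0
        mask = 0
        for k, i in enumerate(order):
            if use_cache:
                mask |= 1 << int(i)
                cur = cache.get(mask)
                if cur is None:
                    cur = scc_game_value(a, np.sort(order[: k + 1]))
                    cache[mask] = cur
            else:
                cur = scc_game_value(a, np.sort(order[: k + 1]))
            phi[i] += cur - prev
            prev = cur
    return phi / n_permutations


def knotty_centre(adjacency: np.ndarray, betweenness: np.ndarray) -> np.ndarray:
    """Greedy knotty-centre membership (1 inside, 0 outside).

    The knotty-centrality of a subset ``S`` is the fraction of total
    betweenness captured by ``S`` times the internal edge density of ``S``.
    The search scans prefixes of the betweenness ordering, then runs greedy
    add/remove refinement; deterministic for a fixed graph.
    """
    a = (np.asarray(adjacency) > 0).astype(float)
    n = a.shape[0]
    bc = np.asarray(betweenness, float)
    total_bc = bc.sum()
    member = np.zeros(n)
    if n < 2 or total_bc <= 0:
        return member

    def kc(s: set[int]) -> float:
        k = len(s)
        if k < 2:
            return 0.0
        idx = np.fromiter(s, int)
        density = a[np.ix_(idx, idx)].sum() / (k * (k - 1))
        return float(bc[idx].sum() / total_bc * density)

    order = sorted(range(n), key=lambda i: (-bc[i], i))
    best: set[int] = set(order[:2])
    best_kc = kc(best)
    for k in range(3, n + 1):
        cand = set(order[:k])
        score = kc(cand)
        if score > best_kc:
            best, best_kc = cand, score
    improved = True
    while improved:
        improved = False
        for i in range(n):  # deterministic scan order
            cand = best | {i} if i not in best else best - {i}
            score = kc(cand)
            if score > best_kc + 1e-15:
                best, best_kc = cand, score
                improved = True
    member[list(best)] = 1.0
    return member
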