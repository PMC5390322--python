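"""The local (per-region) network-parameter registry.

:func:`local_parameters` computes one row per region with every registry
column, in either ``unweighted`` (connection counts, hop distances) or
``weighted`` mode (strengths for degree-based measures, edge length ``1/w``
for path-based measures, the weighted adjacency for spectral measures).

Undefined cells (eccentricity of a node with an empty reachable set, the
variation coefficient of an empty neighbourhood, ...) are emitted as ``NaN``
— the documented sentinel — and excluded pairwise downstream, never silently
dropped.

``AvgRang`` (the cross-parameter average rank) is a registry column owned by
the ranking step in :mod:`strokenet.association`; here it is emitted as the
sentinel.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd
from scipy.linalg import expm

from ..connectome import Connectome
from ._paths import avg_out_closeness, length_matrix, out_closeness, path_counts
from .globalstats import directed_union_clustering
from .shapley import knotty_centre, shapley_values

__all__ = ["PARAMETER_KEYS", "local_parameters", "hits_scores", "modularity_partition"]

#: Registry column order.
PARAMETER_KEYS = [
    "REC", "AvgRang", "DGAll", "DGOut", "DGIn", "CDC",
    "LatAll", "LatOut", "LatIn", "LatRec",
    "Katz", "LCircle", "Triag", "CyclC", "EccOut", "EccIn",
    "CluCOut", "CluCIn", "CluCAll", "CluCTriag", "CluC2",
    "AvgDGnb", "VCDG", "Lev", "Loc",
    "CCOut", "CCIn", "BC", "IN", "EC", "SC", "PRC", "FC", "Stress", "Shapley",
    "ZOut", "ZIn", "ZAll", "PCOut", "PCIn", "PCAll",
    "RadOut", "RadIn", "CenOut", "CenIn", "Hub", "Aut", "Knot", "Vul",
]

_HITS_TOL = 1e-10
_HITS_MAX_ITER = 1000


def hits_scores(adjacency: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Kleinberg hub/authority scores by mutual-reinforcement iteration.

    Hub and authority vectors are each normalized to unit squared sum;
    convergence when the largest absolute change drops below 1e-10 (or after
    1000 iterations). Connection weights do not enter the iteration.
    """
    a = (np.asarray(adjacency) > 0).astype(float)
    n = a.shape[0]
    if n == 0 or a.sum() == 0:
        return np.zeros(n), np.zeros(n)
    hub = np.full(n, 1.0 / np.sqrt(n))
    aut = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(_HITS_MAX_ITER):
        new_aut = a.T @ hub
        norm = np.linalg.norm(new_aut)
        if norm > 0:
            new_aut /= norm
        new_hub = a @ new_aut
        norm = np.linalg.norm(new_hub)
        if norm > 0:
            new_hub /= norm
        delta = max(np.abs(new_hub - hub).max(), np.abs(new_aut - aut).max())
        hub, aut = new_hub, new_aut
        if delta < _HITS_TOL:
            break
    return hub, aut


def modularity_partition(adjacency: np.ndarray, weighted: bool) -> np.ndarray:
    """Module label per node: greedy modularity maximization on the symmetrized graph."""
    w = np.asarray(adjacency, float)
    sym = w + w.T if weighted else ((w > 0) | (w > 0).T).astype(float)
    g = nx.from_numpy_array(sym)  # undirected
    if g.number_of_edges() == 0:
        return np.arange(w.shape[0])
    communities = nx.algorithms.community.greedy_modularity_communities(g, weight="weight")
    labels = np.zeros(w.shape[0], int)
    for mod_id, members in enumerate(communities):
        for i in members:
            labels[i] = mod_id
    return labels


def _eigenvector_centrality(in_adjacency: np.ndarray) -> np.ndarray:
    """Dominant-eigenvector influence score, max-normalized to 1."""
    if in_adjacency.sum() == 0:
        return np.zeros(in_adjacency.shape[0])
    eigvals, eigvecs = np.linalg.eig(in_adjacency)
    lead = int(np.argmax(np.abs(eigvals)))
    vec = np.abs(np.real(eigvecs[:, lead]))
    peak = vec.max()
    return vec / peak if peak > 0 else vec


def _second_neighbourhoods(union_nb: np.ndarray) -> list[np.ndarray]:
    """Nodes at undirected hop distance exactly 2, per node."""
    n = union_nb.shape[0]
    out = []
    for i in range(n):
        first = union_nb[i]
        second = union_nb[first].any(axis=0)
        second = second & ~first
        second[i] = False
        out.append(np.flatnonzero(second))
    return out


def _cyclic_coefficient(union_nb: np.ndarray) -> np.ndarray:
    """Mean inverse smallest-cycle length over neighbour pairs (undirected closure)."""
    n = union_nb.shape[0]
    g = nx.from_numpy_array(union_nb)
    out = np.full(n, np.nan)
    for i in range(n):
        nbrs = np.flatnonzero(union_nb[i])
        if nbrs.size < 2:
            continue
        h = g.copy()
        h.remove_node(i)
        total = 0.0
        pairs = 0
        dists = {j: nx.single_source_shortest_path_length(h, int(j)) for j in nbrs}
        for a_idx in range(nbrs.size):
            for b_idx in range(a_idx + 1, nbrs.size):
                j, k = int(nbrs[a_idx]), int(nbrs[b_idx])
                pairs += 1
                d = dists[j].get(k)
                if d is not None:
                    total += 1.0 / (d + 2)  # cycle i-j-...-k-i
        out[i] = total / pairs
    return out


def local_parameters(
    c: Connectome,
    mode: str = "unweighted",
    seed: int | None = 0,
    shapley_permutations: int = 5000,
    shapley_method: str = "auto",
) -> pd.DataFrame:
    """One row per region with every registry column (see module docstring).

    Deterministic given (graph, mode, seed): the Monte-Carlo Shapley estimate
    is the only stochastic component, and the greedy modularity partition is
    deterministic.
    """
    if mode not in ("weighted", "unweighted"):
        raise ValueError(f"mode must be 'weighted' or 'unweighted', got {mode!r}")
    if c.n_regions == 0:
        raise ValueError("local parameters are undefined for an empty graph")
    weighted = mode == "weighted"
    order = c.node_order
    n = len(order)
    a_w = c.adjacency_matrix(weighted=True)
    a_b = a_w > 0
    w = a_w if weighted else a_b.astype(float)
    lengths = length_matrix(a_w, weighted)
    d, sigma = path_counts(lengths)
    d_in = d.T
    off = ~np.eye(n, dtype=bool)
    union_nb = (a_b | a_b.T) & off
    recip = a_b & a_b.T

    p: dict[str, np.ndarray] = {}

    # -- degree family -----------------------------------------------------
    dg_out = w.sum(axis=1)
    dg_in = w.sum(axis=0)
    dg_all = dg_out + dg_in
    p["DGOut"], p["DGIn"], p["DGAll"] = dg_out, dg_in, dg_all
    p["REC"] = recip.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p["CDC"] = np.where(dg_all > 0, (dg_out - dg_in) / np.where(dg_all > 0, dg_all, 1.0), np.nan)

    # -- laterality --------------------------------------------------------
    hemis = np.array([c.regions[r].hemisphere for r in order])
    lateral = np.isin(hemis, ("left", "right"))
    same = (hemis[:, None] == hemis[None, :]) & lateral[:, None] & lateral[None, :]
    cross = (hemis[:, None] != hemis[None, :]) & lateral[:, None] & lateral[None, :]

    def _laterality(conn: np.ndarray) -> np.ndarray:
        ipsi = (conn * same).sum(axis=1)
        contra = (conn * cross).sum(axis=1)
        denom = ipsi + contra
        with np.errstate(invalid="ignore", divide="ignore"):
            lat = np.where(denom > 0, (ipsi - contra) / np.where(denom > 0, denom, 1.0), np.nan)
        return np.where(lateral, lat, np.nan)

    p["LatOut"] = _laterality(w)
    p["LatIn"] = _laterality(w.T)
    p["LatAll"] = _laterality(w + w.T)
    p["LatRec"] = _laterality((w + w.T) * recip / 2.0)

    # -- clustering family -------------------------------------------------
    g_bin = nx.from_numpy_array(a_b.astype(int), create_using=nx.DiGraph)
    g_wt = nx.from_numpy_array(w, create_using=nx.DiGraph)

    def _set_density(sets: list[np.ndarray]) -> np.ndarray:
        vals = np.zeros(n)
        for i, idx in enumerate(sets):
            k = idx.size
            if k >= 2:
                vals[i] = a_b[np.ix_(idx, idx)].sum() / (k * (k - 1))
        return vals

    out_sets = [np.flatnonzero(a_b[i] & off[i]) for i in range(n)]
    in_sets = [np.flatnonzero(a_b[:, i] & off[i]) for i in range(n)]
    p["CluCOut"] = _set_density(out_sets)
    p["CluCIn"] = _set_density(in_sets)
    p["CluCAll"] = directed_union_clustering(a_b)
    clu_triag = nx.clustering(g_wt if weighted else g_bin, weight="weight" if weighted else None)
    p["CluCTriag"] = np.array([clu_triag[i] for i in range(n)])
    p["CluC2"] = _set_density(_second_neighbourhoods(union_nb))
    undirected = nx.from_numpy_array(union_nb)
    tri = nx.triangles(undirected)
    p["Triag"] = np.array([tri[i] for i in range(n)], float)
    p["CyclC"] = _cyclic_coefficient(union_nb)

    # -- neighbourhood family ----------------------------------------------
    avg_nb = np.full(n, np.nan)
    vc_nb = np.full(n, np.nan)
    lev = np.full(n, np.nan)
    for i in range(n):
        idx = np.flatnonzero(union_nb[i])
        if idx.size == 0:
            continue
        nb_deg = dg_all[idx]
        avg_nb[i] = nb_deg.mean()
        if nb_deg.mean() > 0:
            vc_nb[i] = nb_deg.std() / nb_deg.mean()
        denom = dg_all[i] + nb_deg
        valid = denom > 0
        if valid.any():
            lev[i] = ((dg_all[i] - nb_deg[valid]) / denom[valid]).sum() / idx.size
    p["AvgDGnb"] = avg_nb
    p["VCDG"] = vc_nb
    p["Lev"] = lev
    with np.errstate(invalid="ignore", divide="ignore"):
        p["Loc"] = np.where(avg_nb > 0, dg_all / np.where(avg_nb > 0, avg_nb, 1.0), np.nan)

    flow = np.full(n, np.nan)
    for i in range(n):
        k_nb = union_nb[i].sum()
        if k_nb < 2:
            continue
        src, dst = in_sets[i], out_sets[i]
        realized = len(set((s, t) for s in src for t in dst if s != t))
        flow[i] = realized / (k_nb * (k_nb - 1))
    p["FC"] = flow

    # -- path family -------------------------------------------------------
    p["CCOut"] = out_closeness(d)
    p["CCIn"] = out_closeness(d_in)

    graph_for_paths = g_wt.copy()
    if weighted:
        for u, v, data in graph_for_paths.edges(data=True):
            data["length"] = 1.0 / data["weight"]
    bc = nx.betweenness_centrality(graph_for_paths, normalized=False, weight="length" if weighted else None)
    p["BC"] = np.array([bc[i] for i in range(n)])

    shortest_two = np.zeros(n)
    for i in range(n):
        src, dst = in_sets[i], out_sets[i]
        if src.size and dst.size:
            block = ~a_b[np.ix_(src, dst)]
            shortest_two[i] = block.sum() - sum(1 for s in src if s in set(dst) and not a_b[s, s])
    p["IN"] = shortest_two

    finite = np.isfinite(d)
    stress = np.zeros(n)
    tol = 1e-9
    for i in range(n):
        with np.errstate(invalid="ignore"):
            through = (
                finite[:, [i]] & finite[[i], :] & finite
                & (np.abs(d[:, [i]] + d[[i], :] - d) <= tol * np.maximum(d, 1.0))
            )
        through[i, :] = False
        through[:, i] = False
        np.fill_diagonal(through, False)
        stress[i] = (sigma[:, [i]] * sigma[[i], :] * through).sum()
    p["Stress"] = stress

    ecc_out = np.full(n, np.nan)
    ecc_in = np.full(n, np.nan)
    for i in range(n):
        row = d[i][off[i] & finite[i]]
        col = d_in[i][off[i] & finite[:, i]]
        if row.size:
            ecc_out[i] = row.max()
        if col.size:
            ecc_in[i] = col.max()
    p["EccOut"], p["EccIn"] = ecc_out, ecc_in

    def _radiality(dist: np.ndarray) -> np.ndarray:
        fin = np.isfinite(dist) & off
        if not fin.any():
            return np.full(n, np.nan)
        diam = dist[fin].max()
        rad = np.full(n, np.nan)
        for i in range(n):
            reach = fin[i]
            if reach.any():
                rad[i] = (diam + 1 - dist[i][reach]).sum() / (n - 1)
        return rad

    p["RadOut"] = _radiality(d)
    p["RadIn"] = _radiality(d_in)

    def _centroid(dist: np.ndarray) -> np.ndarray:
        if n < 2:
            return np.zeros(n)
        gamma = np.zeros((n, n))
        for i in range(n):
            closer = dist[i][None, :] < dist  # gamma[i, j] over k
            gamma[i] = closer.sum(axis=1)
            gamma[i] -= (dist[:, i] > 0).astype(float)  # exclude k = i term
        f = gamma - gamma.T
        np.fill_diagonal(f, np.inf)
        return f.min(axis=1)

    p["CenOut"] = _centroid(d)
    p["CenIn"] = _centroid(d_in)

    lcircle = np.full(n, np.nan)
    for i in range(n):
        succ = out_sets[i]
        if succ.size:
            cyc = lengths[i, succ] + d[succ, i]
            cyc = cyc[np.isfinite(cyc)]
            if cyc.size:
                lcircle[i] = cyc.min()
    p["LCircle"] = lcircle

    # -- spectral family ---------------------------------------------------
    p["EC"] = _eigenvector_centrality(w.T)
    p["SC"] = expm(w).diagonal().copy()
    spectral_radius = np.max(np.abs(np.linalg.eigvals(w))) if w.any() else 0.0
    alpha = 0.9 / spectral_radius if spectral_radius > 0 else 0.1
    try:
        katz = nx.katz_centrality_numpy(g_wt, alpha=alpha, weight="weight" if weighted else None)
        p["Katz"] = np.array([katz[i] for i in range(n)])
    except np.linalg.LinAlgError:  # pragma: no cover - singular resolvent
        p["Katz"] = np.full(n, np.nan)
    prc = nx.pagerank(g_wt, alpha=0.85, weight="weight" if weighted else None)
    p["PRC"] = np.array([prc[i] for i in range(n)])
    hub, aut = hits_scores(a_b)
    p["Hub"], p["Aut"] = hub, aut

    # -- module family -----------------------------------------------------
    labels = modularity_partition(a_w, weighted)

    def _z_and_pc(conn: np.ndarray, degree: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        kappa = np.zeros(n)
        pc = np.zeros(n)
        for i in range(n):
            kappa[i] = conn[i][labels == labels[i]].sum() - conn[i, i]
        z = np.zeros(n)
        for mod_id in np.unique(labels):
            sel = labels == mod_id
            mu, sd = kappa[sel].mean(), kappa[sel].std()
            z[sel] = (kappa[sel] - mu) / sd if sd > 0 else 0.0
        for i in range(n):
            if degree[i] > 0:
                per_mod = np.array([conn[i][labels == mod_id].sum() for mod_id in np.unique(labels)])
                pc[i] = 1.0 - ((per_mod / degree[i]) ** 2).sum()
        return z, pc

    p["ZOut"], p["PCOut"] = _z_and_pc(w, dg_out)
    p["ZIn"], p["PCIn"] = _z_and_pc(w.T, dg_in)
    p["ZAll"], p["PCAll"] = _z_and_pc(w + w.T, dg_all)

    # -- game / deletion family --------------------------------------------
    p["Shapley"] = shapley_values(a_b, n_permutations=shapley_permutations, seed=seed, method=shapley_method)
    p["Knot"] = knotty_centre(a_b, p["BC"])

    base_closeness = avg_out_closeness(lengths)
    vul = np.zeros(n)
    keep_all = np.arange(n)
    for i in range(n):
        keep = keep_all[keep_all != i]
        vul[i] = base_closeness - avg_out_closeness(lengths[np.ix_(keep, keep)])
    p["Vul"] = vul

    p["AvgRang"] = np.full(n, np.nan)

    table = pd.DataFrame({key: p[key] for key in PARAMETER_KEYS}, index=pd.Index(order, name="region_id"))
    table.attrs["mode"] = mode
    table.attrs["module_partition"] = {order[i]: int(labels[i]) for i in range(n)}
    return table


def parameter_table_to_tidy(table: pd.DataFrame) -> pd.DataFrame:
    """Tidy export: columns ``region_id, parameter, mode, value``."""
    tidy = table.reset_index().melt(id_vars="region_id", var_name="parameter", value_name="value")
    tidy["mode"] = table.attrs.get("mode", "unweighted")
    return tidy[["region_id", "parameter", "mode", "value"]]
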