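"""Local-parameter registry: closed-form examples, independent oracles, invariants."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from strokenet import metrics
from strokenet.connectome import Connectome, Region
from strokenet.metrics.local import PARAMETER_KEYS, hits_scores, local_parameters
from strokenet.metrics.shapley import scc_game_value, shapley_values

from conftest import make_connectome, make_regions, random_digraph_edges


# ---------------------------------------------------------------------------
# independent oracles

def oracle_bc_stress(g: nx.DiGraph):
    """Betweenness and stress by exhaustive simple-path enumeration."""
    nodes = list(g.nodes)
    bc = {v: 0.0 for v in nodes}
    stress = {v: 0.0 for v in nodes}
    for s, t in itertools.permutations(nodes, 2):
        paths = list(nx.all_simple_paths(g, s, t))
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        best = [p for p in paths if len(p) == shortest]
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in best if v in p)
            stress[v] += through
            bc[v] += through / len(best)
    return bc, stress


def oracle_subgraph_centrality(a: np.ndarray, k_max=40):
    """Truncated walk series sum_k (A^k)_ii / k!."""
    n = a.shape[0]
    total = np.zeros(n)
    power = np.eye(n)
    for k in range(k_max + 1):
        total += np.diag(power) / math.factorial(k)
        power = power @ a
    return total


def oracle_hits(a: np.ndarray):
    """Dominant eigenvectors of A Aᵀ (hubs) and Aᵀ A (authorities)."""
    def lead(m):
        vals, vecs = np.linalg.eigh(m)
        v = np.abs(vecs[:, np.argmax(vals)])
        return v / np.linalg.norm(v)

    return lead(a @ a.T), lead(a.T @ a)


def oracle_shapley_permutations(a: np.ndarray):
    """Exact Shapley value by full permutation enumeration (n ≤ 6)."""
    n = a.shape[0]
    phi = np.zeros(n)
    count = 0
    for order in itertools.permutations(range(n)):
        prev = 0
        for k, i in enumerate(order):
            cur = scc_game_value(a, np.sort(np.array(order[: k + 1])))
            phi[i] += cur - prev
            prev = cur
        count += 1
    return phi / count


# ---------------------------------------------------------------------------
# closed-form examples

def test_directed_three_cycle_degree_and_clustering():
    c = make_connectome(3, [(0, 1), (1, 2), (2, 0)])
    t = local_parameters(c)
    assert (t.DGIn == 1).all() and (t.DGOut == 1).all() and (t.DGAll == 2).all()
    assert (t.REC == 0).all()
    # each node's union neighbourhood {j, k} carries exactly one of two possible
    # directed links, and the cycle is the sole directed triangle motif
    assert np.allclose(t.CluCAll, 0.5)
    assert np.allclose(t.CluCTriag, 0.5)
    assert np.allclose(t.LCircle, 3.0)


def test_complete_digraph_clustering_is_one():
    c = make_connectome(3, [(i, j) for i in range(3) for j in range(3) if i != j])
    t = local_parameters(c)
    for col in ("CluCAll", "CluCOut", "CluCIn", "CluCTriag"):
        assert np.allclose(t[col], 1.0), col


def test_star_hits_fixed_point():
    c = make_connectome(4, [(0, 1), (0, 2), (0, 3)])
    t = local_parameters(c)
    assert t.Hub.iloc[0] == pytest.approx(1.0, abs=1e-9)
    assert np.allclose(t.Aut.iloc[1:], 1 / np.sqrt(3), atol=1e-9)
    assert t.Aut.iloc[0] == pytest.approx(0.0, abs=1e-9)


def test_isolated_node_sentinels():
    c = make_connectome(3, [(0, 1)])
    t = local_parameters(c)
    assert np.isnan(t.loc["n2", "EccOut"]) and np.isnan(t.loc["n2", "EccIn"])
    assert np.isnan(t.loc["n2", "CDC"])
    assert np.isnan(t.loc["n2", "AvgDGnb"])


def test_all_registry_columns_present_and_avgrang_deferred(small_random_connectome):
    t = local_parameters(small_random_connectome)
    assert list(t.columns) == PARAMETER_KEYS
    assert t.AvgRang.isna().all()


def test_laterality_contrasts_hemispheres():
    regions = make_regions(2, hemisphere="left", prefix="L") + make_regions(2, hemisphere="right", prefix="R")
    c = Connectome(regions, [("L0", "L1", 1.0), ("L0", "R0", 1.0), ("L0", "R1", 1.0)])
    t = local_parameters(c)
    # L0: 1 ipsilateral vs 2 contralateral outputs
    assert t.loc["L0", "LatOut"] == pytest.approx((1 - 2) / 3)
    assert np.isnan(t.loc["R1", "LatOut"])  # no outputs


# ---------------------------------------------------------------------------
# oracle equivalence on seeded small digraphs

@pytest.mark.parametrize("seed", range(6))
def test_bc_and_stress_match_path_enumeration(seed):
    rng = np.random.default_rng(seed)
    c = make_connectome(7, random_digraph_edges(7, 0.3, rng))
    t = local_parameters(c)
    bc, stress = oracle_bc_stress(c.graph)
    for i, rid in enumerate(c.node_order):
        assert t.BC.loc[rid] == pytest.approx(bc[rid], abs=1e-9)
        assert t.Stress.loc[rid] == pytest.approx(stress[rid], abs=1e-9)


@pytest.mark.parametrize("seed", range(6))
def test_subgraph_centrality_matches_walk_series(seed):
    rng = np.random.default_rng(100 + seed)
    c = make_connectome(8, random_digraph_edges(8, 0.35, rng))
    t = local_parameters(c)
    expected = oracle_subgraph_centrality(c.adjacency_matrix(weighted=False))
    assert np.allclose(t.SC.to_numpy(), expected, atol=1e-9)


@pytest.mark.parametrize("seed", range(6))
def test_hits_matches_eigendecomposition(seed):
    rng = np.random.default_rng(200 + seed)
    a = np.array(
        [[1.0 if (i != j and rng.random() < 0.4) else 0.0 for j in range(8)] for i in range(8)]
    )
    hub, aut = hits_scores(a)
    ehub, eaut = oracle_hits(a)
    assert abs(np.dot(hub, ehub)) > 1 - 1e-9
    assert abs(np.dot(aut, eaut)) > 1 - 1e-9


def test_exact_shapley_matches_permutation_enumeration():
    rng = np.random.default_rng(7)
    a = (rng.random((5, 5)) < 0.4) & ~np.eye(5, dtype=bool)
    exact = shapley_values(a, method="exact")
    expected = oracle_shapley_permutations(a.astype(float))
    assert np.allclose(exact, expected, atol=1e-12)
    # efficiency: Shapley values sum to v(grand coalition)
    assert exact.sum() == pytest.approx(scc_game_value(a, np.arange(5)))


def test_monte_carlo_shapley_converges_to_exact():
    rng = np.random.default_rng(11)
    a = (rng.random((8, 8)) < 0.3) & ~np.eye(8, dtype=bool)
    exact = shapley_values(a, method="exact")
    mc = shapley_values(a, method="mc", n_permutations=5000, seed=1)
    assert np.abs(mc - exact).max() < 0.05


# ---------------------------------------------------------------------------
# invariants

def test_normalizations(small_random_connectome):
    t = local_parameters(small_random_connectome)
    assert t.EC.max() == pytest.approx(1.0)
    assert np.linalg.norm(t.Hub) == pytest.approx(1.0, abs=1e-8)
    assert np.linalg.norm(t.Aut) == pytest.approx(1.0, abs=1e-8)
    assert t.PRC.sum() == pytest.approx(1.0, abs=1e-8)
    for col in ("CluCOut", "CluCIn", "CluCAll", "CluCTriag", "CluC2"):
        vals = t[col].dropna()
        assert ((vals >= 0) & (vals <= 1)).all(), col
    for col in ("PCOut", "PCIn", "PCAll"):
        vals = t[col].dropna()
        assert ((vals >= -1e-12) & (vals <= 1)).all(), col


def test_relabelling_permutes_parameters():
    # two well-separated communities so the modularity partition is unambiguous
    edges = [(i, j) for i in range(4) for j in range(4) if i != j]
    edges += [(i, j) for i in range(4, 8) for j in range(4, 8) if i != j]
    edges += [(0, 4), (4, 0)]
    rng = np.random.default_rng(0)
    c1 = make_connectome(8, edges)
    perm = rng.permutation(8)
    regions = make_regions(8)
    shuffled = [regions[i] for i in perm]
    c2 = Connectome(shuffled, [(f"n{i}", f"n{j}", 1.0) for i, j in edges])
    t1 = local_parameters(c1, seed=0)
    t2 = local_parameters(c2, seed=0).loc[t1.index]
    for col in PARAMETER_KEYS:
        v1, v2 = t1[col].to_numpy(), t2[col].to_numpy()
        both = np.isfinite(v1) & np.isfinite(v2)
        assert (np.isfinite(v1) == np.isfinite(v2)).all(), col
        assert np.allclose(v1[both], v2[both], atol=1e-8), col


def test_adding_edge_never_decreases_degree():
    rng = np.random.default_rng(3)
    edges = random_digraph_edges(9, 0.25, rng)
    c = make_connectome(9, edges)
    t = local_parameters(c)
    present = {(u, v) for u, v, _ in c.edge_list()}
    new = next(
        (i, j) for i in range(9) for j in range(9) if i != j and (f"n{i}", f"n{j}") not in present
    )
    c2 = make_connectome(9, edges + [new])
    t2 = local_parameters(c2)
    assert t2.DGAll.loc[f"n{new[0]}"] >= t.DGAll.loc[f"n{new[0]}"]
    assert t2.DGAll.loc[f"n{new[1]}"] >= t.DGAll.loc[f"n{new[1]}"]


def test_removing_node_never_increases_triangles():
    rng = np.random.default_rng(4)
    c = make_connectome(9, random_digraph_edges(9, 0.35, rng))
    t = local_parameters(c)
    sub = c.subgraph([rid for rid in c.node_order if rid != "n0"])
    t2 = local_parameters(sub)
    assert (t2.Triag <= t.Triag.loc[t2.index]).all()


def test_weighted_mode_uses_strengths_and_inverse_lengths():
    c = make_connectome(3, [(0, 1, 4.0), (1, 2, 0.5), (0, 2, 0.5)])
    t = local_parameters(c, mode="weighted")
    assert t.DGOut.loc["n0"] == pytest.approx(4.5)
    # strong 0->1->2 route (length 1/4 + 2) beats nothing; direct 0->2 length 2
    assert t.EccOut.loc["n0"] == pytest.approx(2.0)  # min(2, 0.25 + 2) = 2 to n2, 0.25 to n1


def test_empty_graph_rejected():
    with pytest.raises(ValueError):
        local_parameters(Connectome([]))
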