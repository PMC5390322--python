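"""Ranking, correlation and PCA over the parameter table."""

import numpy as np
import pandas as pd
import pytest

from strokenet.association import (
    DEFAULT_ORIENTATIONS,
    correlate_parameters_fos,
    distance_fos_correlation,
    euclidean_distance_matrix,
    pca_six,
    rank,
)
from strokenet.connectome import Connectome, LesionSet
from strokenet.metrics import local_parameters

from conftest import make_connectome, make_regions, random_digraph_edges


def _frame(values: dict, index):
    return pd.DataFrame(values, index=pd.Index(index, name="region_id"))


class TestRank:
    def test_row_numbering_with_ties_broken_by_id(self):
        t = _frame({"DGAll": [5.0, 3.0, 3.0, 1.0]}, ["a", "b", "c", "d"])
        r = rank(t)
        assert list(r["DGAll"]) == [1, 2, 3, 4]

    def test_inverted_orientation_for_shapley(self):
        t = _frame({"Shapley": [-2.0, 0.0, 1.0]}, ["a", "b", "c"])
        assert list(rank(t)["Shapley"]) == [1, 2, 3]

    def test_average_rank_matches_naive_sorter(self, rng):
        cols = {f"P{k}": rng.normal(size=20) for k in range(5)}
        t = _frame(cols, [f"r{i:02d}" for i in range(20)])
        orientations = {c: "largerIsMoreImportant" for c in cols}
        r = rank(t, orientations)
        for col in cols:
            naive = sorted(t.index, key=lambda rid: (-t.loc[rid, col], rid))
            expected = {rid: i + 1 for i, rid in enumerate(naive)}
            assert all(r.loc[rid, col] == expected[rid] for rid in t.index)
        assert np.allclose(r["AvgRang"], r[list(cols)].mean(axis=1))

    def test_invariant_under_monotone_transform(self, rng):
        values = rng.normal(size=15)
        t1 = _frame({"X": values}, [f"r{i}" for i in range(15)])
        t2 = _frame({"X": np.exp(values)}, [f"r{i}" for i in range(15)])
        o = {"X": "largerIsMoreImportant"}
        assert (rank(t1, o)["X"] == rank(t2, o)["X"]).all()

    def test_sentinels_excluded_and_ranks_compacted(self):
        t = _frame({"X": [3.0, np.nan, 1.0]}, ["a", "b", "c"])
        r = rank(t, {"X": "largerIsMoreImportant"})
        assert r.loc["a", "X"] == 1 and r.loc["c", "X"] == 2 and np.isnan(r.loc["b", "X"])

    def test_default_orientations_cover_registry(self):
        from strokenet.metrics import PARAMETER_KEYS

        o = DEFAULT_ORIENTATIONS(PARAMETER_KEYS)
        assert o["Shapley"] == "smallerIsMoreImportant"
        assert o["DGAll"] == "largerIsMoreImportant"
        assert set(o) == set(PARAMETER_KEYS)


@pytest.fixture(scope="module")
def table():
    rng = np.random.default_rng(5)
    c = make_connectome(40, random_digraph_edges(40, 0.2, rng))
    return local_parameters(c, shapley_permutations=100)


class TestParameterFosCorrelation:
    def test_self_correlation_is_one(self, table):
        out = correlate_parameters_fos(table[["EC"]], table["EC"])
        assert out.set_index("parameter").loc["EC", "r"] == pytest.approx(1.0)

    def test_independent_fos_gives_small_r(self, table):
        rng = np.random.default_rng(0)
        hits = 0
        reps = 40
        for _ in range(reps):
            fos = pd.Series(rng.normal(size=len(table)), index=table.index)
            out = correlate_parameters_fos(table[["DGAll"]], fos)
            r, n = out.iloc[0].r, out.iloc[0].n
            if abs(r) <= 2 / np.sqrt(n):
                hits += 1
        assert hits / reps >= 0.85  # ~95% expected, with simulation slack

    def test_planted_loading_recovered(self, table):
        rng = np.random.default_rng(1)
        z = (table.SC - table.SC.mean()) / table.SC.std()
        fos = 0.6 * z + 0.8 * pd.Series(rng.normal(size=len(table)), index=table.index)
        out = correlate_parameters_fos(table[["SC"]], fos)
        assert out.iloc[0].r == pytest.approx(0.6, abs=0.25)

    def test_lesion_regions_excluded(self, table):
        fos = pd.Series(np.arange(len(table), dtype=float), index=table.index)
        out = correlate_parameters_fos(table[["DGAll"]], fos, exclude={"n0", "n1"})
        assert out.iloc[0].n == len(table) - 2

    def test_zero_variance_sentinel(self, table):
        fos = pd.Series(1.0, index=table.index)
        with pytest.warns(UserWarning, match="zero variance"):
            out = correlate_parameters_fos(table[["DGAll"]], fos)
        assert np.isnan(out.iloc[0].r)


class TestDistanceFos:
    def _connectome(self, rng, n=20, lesioned=("n0",)):
        coords = rng.normal(scale=3.0, size=(n, 3))
        regions = make_regions(n, hemisphere="left", lesioned=lesioned, coords=coords)
        return Connectome(regions, [])

    def test_distance_matrix_properties(self, rng):
        c = self._connectome(rng)
        dm = euclidean_distance_matrix(c)
        assert np.allclose(dm, dm.T) and np.allclose(np.diag(dm), 0)
        a, b, d = dm.iloc[0, 1], dm.iloc[1, 2], dm.iloc[0, 2]
        assert d <= a + b + 1e-12

    def test_perfect_linear_relation(self, rng):
        c = self._connectome(rng)
        dm = euclidean_distance_matrix(c)
        lesion = LesionSet(["n0"])
        others = [r for r in c.node_order if r != "n0"]
        fos = pd.Series(10.0 - 0.5 * dm.loc[others, "n0"].to_numpy(), index=others)
        out = distance_fos_correlation(dm, lesion, fos)
        assert out.iloc[0].r == pytest.approx(-1.0)

    def test_exponential_decay_recovery_improves_with_less_noise(self, rng):
        c = self._connectome(rng, n=40)
        dm = euclidean_distance_matrix(c)
        lesion = LesionSet(["n0"])
        others = [r for r in c.node_order if r != "n0"]
        d = dm.loc[others, "n0"].to_numpy()
        signal = np.exp(-d / 2.0)  # hypoactivation magnitude
        rs = []
        for noise in (0.02, 0.2):
            fos = pd.Series(signal + rng.normal(scale=noise, size=len(others)), index=others)
            rs.append(distance_fos_correlation(dm, lesion, fos).iloc[0].r)
        assert rs[0] < -0.7 and rs[0] < rs[1] < 0

    def test_constant_fos_sentinel(self, rng):
        c = self._connectome(rng)
        dm = euclidean_distance_matrix(c)
        fos = pd.Series(1.0, index=[r for r in c.node_order if r != "n0"])
        with pytest.warns(UserWarning, match="zero variance"):
            out = distance_fos_correlation(dm, LesionSet(["n0"]), fos)
        assert np.isnan(out.iloc[0].r)


class TestPCA:
    def test_correlated_pair_explains_everything(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        t = _frame(
            {"DGAll": x, "CluCAll": 2 * x + 1, "CluC2": np.ones(30), "AvgDGnb": np.ones(30),
             "VCDG": np.ones(30), "Loc": np.ones(30)},
            [f"r{i}" for i in range(30)],
        )
        with pytest.warns(UserWarning, match="constant"):
            out = pca_six(t)
        assert out["explained_variance_ratio"][0] == pytest.approx(1.0)
        assert out["columns"] == ["DGAll", "CluCAll"]

    def test_matches_eigendecomposition_of_correlation_matrix(self, rng):
        data = rng.normal(size=(82, 6))
        t = _frame({k: data[:, i] for i, k in enumerate(["DGAll", "CluCAll", "CluC2", "AvgDGnb", "VCDG", "Loc"])},
                   [f"r{i:02d}" for i in range(82)])
        out = pca_six(t)
        corr = np.corrcoef(data, rowvar=False)
        eigvals = np.sort(np.linalg.eigvalsh(corr))[::-1]
        # explained variances of standardized PCA = eigenvalues of the correlation matrix
        np.testing.assert_allclose(out["explained_variance_ratio"][:2] * 6, eigvals[:2], rtol=0.02)
        assert eigvals.sum() == pytest.approx(6.0)
        assert out["loadings"].loc["PC1", "DGAll"] >= 0

    def test_planted_cluster_stays_tight_in_score_space(self, rng):
        base = rng.normal(size=(40, 6))
        cluster_row = rng.normal(size=6)
        base[:6] = cluster_row + 0.01 * rng.normal(size=(6, 6))
        t = _frame({k: base[:, i] for i, k in enumerate(["DGAll", "CluCAll", "CluC2", "AvgDGnb", "VCDG", "Loc"])},
                   [f"r{i:02d}" for i in range(40)])
        scores = pca_six(t)["scores"].to_numpy()
        from scipy.spatial.distance import pdist, squareform

        dist = squareform(pdist(scores))
        cluster_pairs = dist[:6, :6][np.triu_indices(6, 1)]
        threshold = np.percentile(pdist(scores), 10)
        assert (cluster_pairs < threshold).all()

    def test_too_few_rows_rejected(self):
        t = _frame({k: [1.0, 2.0] for k in ["DGAll", "CluCAll", "CluC2", "AvgDGnb", "VCDG", "Loc"]}, ["a", "b"])
        with pytest.raises(ValueError, match="at least 3"):
            pca_six(t)
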