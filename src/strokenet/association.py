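"""Direction-aware ranking, parameter–Fos and distance–Fos correlation, PCA.

Ranking follows the "row numbering" convention: for each parameter the
regions are sorted by importance under that parameter's orientation (most
important first) and numbered 1, 2, 3, ..., ties broken deterministically by
region id; the per-region mean of these ordinal ranks is the average rank
(``AvgRang``).

Most parameters are oriented larger-is-more-important; the exceptions are
distance-like quantities (eccentricities, shortest-cycle length, the average
rank itself) and the Shapley value, whose *more negative* values mark more
integrative regions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .connectome import Connectome, LesionSet

__all__ = [
    "DEFAULT_ORIENTATIONS",
    "rank",
    "average_rank",
    "correlate_parameters_fos",
    "euclidean_distance_matrix",
    "distance_fos_correlation",
    "pca_six",
    "PCA_SIX_PARAMETERS",
]

_SMALLER_IS_MORE_IMPORTANT = {"Shapley", "EccIn", "EccOut", "LCircle", "AvgRang"}


def DEFAULT_ORIENTATIONS(columns) -> dict[str, str]:
    """Orientation registry covering ``columns``; see module docstring."""
    return {
        c: ("smallerIsMoreImportant" if c in _SMALLER_IS_MORE_IMPORTANT else "largerIsMoreImportant")
        for c in columns
    }


def rank(table: pd.DataFrame, orientations: dict[str, str] | None = None) -> pd.DataFrame:
    """Ordinal ranks per parameter (1 = most important) with ties broken by region id.

    NaN sentinel cells are excluded from that column's ranking (ranks
    compacted) and stay NaN. The returned frame carries the same shape as the
    input plus an ``AvgRang`` column, the row mean of the ordinal ranks.
    """
    orientations = orientations or DEFAULT_ORIENTATIONS(table.columns)
    missing = set(table.columns) - set(orientations) - {"AvgRang"}
    if missing:
        raise ValueError(f"no orientation for column(s) {sorted(missing)}")
    ranks = pd.DataFrame(index=table.index, dtype=float)
    ids = np.asarray(table.index.astype(str))
    for col in table.columns:
        if col == "AvgRang":
            continue
        values = table[col].to_numpy(float)
        valid = np.flatnonzero(np.isfinite(values))
        col_rank = np.full(len(values), np.nan)
        if valid.size:
            v = values[valid]
            if orientations[col] == "smallerIsMoreImportant":
                keys = v
            elif orientations[col] == "largerIsMoreImportant":
                keys = -v
            else:
                raise ValueError(f"unknown orientation {orientations[col]!r} for {col!r}")
            order = np.lexsort((ids[valid], keys))
            col_rank[valid[order]] = np.arange(1, valid.size + 1)
        ranks[col] = col_rank
    ranks["AvgRang"] = ranks.mean(axis=1, skipna=True)
    return ranks


def average_rank(table: pd.DataFrame, orientations: dict[str, str] | None = None) -> pd.Series:
    """Per-region average ordinal rank across parameters (fills the AvgRang registry column)."""
    return rank(table, orientations)["AvgRang"]


def _pearson(x: np.ndarray, y: np.ndarray, min_n: int = 3) -> tuple[float, int]:
    paired = np.isfinite(x) & np.isfinite(y)
    n = int(paired.sum())
    if n < min_n:
        return float("nan"), n
    xv, yv = x[paired], y[paired]
    if np.std(xv) == 0 or np.std(yv) == 0:
        warnings.warn("zero variance in a correlation input; emitting sentinel", stacklevel=3)
        return float("nan"), n
    r, _ = stats.pearsonr(xv, yv)
    return float(r), n


def correlate_parameters_fos(
    table: pd.DataFrame,
    fos: pd.Series,
    exclude: LesionSet | set[str] | None = None,
) -> pd.DataFrame:
    """Pearson r of every parameter column against a per-region Fos measure.

    Damaged regions are excluded; NaN sentinels are removed pairwise; the
    sample size enters the output next to each coefficient.
    """
    drop = set()
    if exclude is not None:
        drop = set(exclude.region_ids) if isinstance(exclude, LesionSet) else set(exclude)
    keep = [rid for rid in table.index if rid not in drop and rid in fos.index]
    sub = table.loc[keep]
    y = fos.loc[keep].to_numpy(float)
    rows = []
    for col in sub.columns:
        r, n = _pearson(sub[col].to_numpy(float), y)
        rows.append({"parameter": col, "r": r, "n": n})
    out = pd.DataFrame(rows)
    out["mode"] = table.attrs.get("mode", "unweighted")
    return out[["parameter", "mode", "r", "n"]]


def euclidean_distance_matrix(c: Connectome, order=None) -> pd.DataFrame:
    """Euclidean distances (mm) between region centres of gravity."""
    order = list(order) if order is not None else c.node_order
    coords = c.coordinates(order)
    d = cdist(coords, coords)
    return pd.DataFrame(d, index=order, columns=order)


def distance_fos_correlation(
    dm: pd.DataFrame,
    lesion: LesionSet,
    fos: pd.Series,
) -> pd.DataFrame:
    """Per damaged region: Pearson r between distance-to-it and the Fos measure.

    Computed across the non-damaged regions present in both the distance
    matrix and the Fos vector.
    """
    damaged = sorted(lesion.region_ids)
    others = [rid for rid in dm.index if rid not in lesion.region_ids and rid in fos.index]
    y = fos.loc[others].to_numpy(float)
    rows = []
    for rid in damaged:
        if rid not in dm.index:
            raise ValueError(f"damaged region {rid!r} missing from the distance matrix")
        x = dm.loc[others, rid].to_numpy(float)
        r, n = _pearson(x, y)
        rows.append({"damaged_region": rid, "r": r, "n": n})
    return pd.DataFrame(rows)


#: The six local parameters entering the PCA.
PCA_SIX_PARAMETERS = ["DGAll", "CluCAll", "CluC2", "AvgDGnb", "VCDG", "Loc"]


def pca_six(table: pd.DataFrame, parameters=None) -> dict:
    """PCA of the six local connectivity parameters on z-scored columns.

    Returns scores (regions × 2), loadings, and the explained-variance ratio.
    Constant columns are dropped with a warning. The sign convention fixes a
    positive ``DGAll`` loading on component 1.
    """
    from sklearn.decomposition import PCA

    parameters = list(parameters) if parameters is not None else list(PCA_SIX_PARAMETERS)
    missing = [c for c in parameters if c not in table.columns]
    if missing:
        raise ValueError(f"missing PCA column(s) {missing}")
    sub = table[parameters].dropna(axis=0, how="any")
    if len(sub) < 3:
        raise ValueError("PCA needs at least 3 complete rows")
    keep = []
    for col in parameters:
        if np.std(sub[col].to_numpy(float)) == 0:
            warnings.warn(f"dropping constant PCA column {col!r}", stacklevel=2)
        else:
            keep.append(col)
    if len(keep) < 2:
        raise ValueError("fewer than 2 non-constant PCA columns")
    x = sub[keep].to_numpy(float)
    z = (x - x.mean(axis=0)) / x.std(axis=0)
    pca = PCA(n_components=min(2, len(keep)))
    scores = pca.fit_transform(z)
    loadings = pca.components_
    anchor = keep.index("DGAll") if "DGAll" in keep else 0
    for comp in range(loadings.shape[0]):
        ref = loadings[comp, anchor] if comp == 0 else loadings[comp, np.argmax(np.abs(loadings[comp]))]
        if ref < 0:
            loadings[comp] *= -1
            scores[:, comp] *= -1
    explained = pca.explained_variance_ratio_ * len(keep)
    return {
        "scores": pd.DataFrame(scores, index=sub.index, columns=["PC1", "PC2"][: scores.shape[1]]),
        "loadings": pd.DataFrame(loadings, index=["PC1", "PC2"][: loadings.shape[0]], columns=keep),
        "explained_variance": explained,
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "columns": keep,
    }
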