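"""Group-level Fos-density statistics.

Fos-immunopositive cell densities (cells/mm²) are organized by region,
hemisphere-relative side (``ipsi``/``contra`` to the occlusion), surgery
(``sham``/``mcao``) and environment (``home``/``expl``). Contrasts are
expressed as raw differences ``D = mean(test) − mean(reference)``, relative
differences ``Dr = D / mean(reference)``, and dispersion-normalized
differences ``Dσ = D / dispersion(reference)`` where the dispersion is the
reference SEM by default (switchable to the SD).

Reference groups follow the contrast semantics: home-cage animals for the
exploration contrasts, sham-operated animals for the stroke contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FosTable",
    "CONTRASTS",
    "group_means",
    "means_from_table1",
    "effect",
    "effects_table",
    "mean_absolute_difference",
    "classify_regions",
]

SIDES = ("ipsi", "contra")
SURGERIES = ("sham", "mcao")
ENVIRONMENTS = ("home", "expl")

#: contrast name -> ((test surgery, test environment), (reference surgery, reference environment))
CONTRASTS = {
    "stroke@home": (("mcao", "home"), ("sham", "home")),
    "stroke@expl": (("mcao", "expl"), ("sham", "expl")),
    "explore@sham": (("sham", "expl"), ("sham", "home")),
    "explore@mcao": (("mcao", "expl"), ("mcao", "home")),
}

COLUMNS = ["region", "side", "surgery", "environment", "animal_id", "density"]


@dataclass
class FosTable:
    """Per-animal Fos densities in tidy form (columns: region, side, surgery, environment, animal_id, density)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"Fos table missing column(s) {missing}")
        df = self.data
        if (df["density"] < 0).any():
            raise ValueError("Fos densities must be non-negative")
        for col, allowed in (("side", SIDES), ("surgery", SURGERIES), ("environment", ENVIRONMENTS)):
            bad = set(df[col].unique()) - set(allowed)
            if bad:
                raise ValueError(f"unknown {col} value(s) {sorted(bad)}; allowed: {allowed}")

    @classmethod
    def from_csv(cls, path) -> "FosTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data[COLUMNS].to_csv(path, index=False)

    @property
    def regions(self) -> list[str]:
        return sorted(self.data["region"].unique())


def group_means(t: FosTable) -> pd.DataFrame:
    """Per-cell mean, SD, SEM and n; one row per (region, side, surgery, environment).

    Empty cells are simply absent; a single-animal cell has a defined mean and
    NaN dispersion.
    """
    df = t.data if isinstance(t, FosTable) else t
    grouped = df.groupby(["region", "side", "surgery", "environment"], sort=True)["density"]
    out = grouped.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out[["region", "side", "surgery", "environment", "mean", "sd", "sem", "n"]]


def means_from_table1(table1: pd.DataFrame) -> pd.DataFrame:
    """Group-means table from the packaged published means (means only, no dispersion).

    The published sham means are not split by side (sham hemispheres do not
    differ), so sham cells are emitted for both sides; dMCAO home-cage means
    were not published and are absent. Group sizes come from the published
    caption (sham home n=11, sham exploration n=8, dMCAO exploration n=10).
    """
    rows = []
    spec = [
        ("sham_home", "sham", "home", SIDES, 11),
        ("sham_expl", "sham", "expl", SIDES, 8),
        ("mcao_expl_ipsi", "mcao", "expl", ("ipsi",), 10),
        ("mcao_expl_contra", "mcao", "expl", ("contra",), 10),
    ]
    for col, surgery, environment, sides, n in spec:
        for _, r in table1.iterrows():
            for side in sides:
                rows.append(
                    {
                        "region": r["region"],
                        "side": side,
                        "surgery": surgery,
                        "environment": environment,
                        "mean": float(r[col]),
                        "sd": np.nan,
                        "sem": np.nan,
                        "n": n,
                    }
                )
    return pd.DataFrame(rows)


def _cell(means: pd.DataFrame, region: str, side: str, surgery: str, environment: str) -> pd.Series | None:
    sel = means[
        (means["region"] == region)
        & (means["side"] == side)
        & (means["surgery"] == surgery)
        & (means["environment"] == environment)
    ]
    if sel.empty:
        return None
    return sel.iloc[0]


def effect(
    means: pd.DataFrame,
    region: str,
    side: str,
    contrast: str,
    dispersion: str = "sem",
) -> dict:
    """D, Dr and Dσ for one region/side/contrast from a group-means table.

    ``Dr`` is NaN when the reference mean is zero; ``Dσ`` is NaN when the
    reference dispersion is unavailable.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; choose from {sorted(CONTRASTS)}")
    if dispersion not in ("sem", "sd"):
        raise ValueError("dispersion must be 'sem' or 'sd'")
    (t_surg, t_env), (r_surg, r_env) = CONTRASTS[contrast]
    test = _cell(means, region, side, t_surg, t_env)
    ref = _cell(means, region, side, r_surg, r_env)
    if test is None or ref is None:
        raise ValueError(f"missing group mean for region {region!r}, side {side!r}, contrast {contrast!r}")
    d = float(test["mean"] - ref["mean"])
    dr = d / float(ref["mean"]) if ref["mean"] != 0 else float("nan")
    disp = float(ref[dispersion]) if dispersion in ref and np.isfinite(ref[dispersion]) else float("nan")
    dsigma = d / disp if np.isfinite(disp) and disp > 0 else float("nan")
    return {
        "region": region,
        "side": side,
        "contrast": contrast,
        "D": d,
        "Dr": dr,
        "Dsigma": dsigma,
        "mean_test": float(test["mean"]),
        "mean_ref": float(ref["mean"]),
    }


def effects_table(
    means: pd.DataFrame,
    contrast: str,
    sides: tuple[str, ...] = SIDES,
    dispersion: str = "sem",
) -> pd.DataFrame:
    """All-region effect table for one contrast; regions with missing cells are skipped with a warning."""
    rows = []
    skipped = []
    for region in sorted(means["region"].unique()):
        for side in sides:
            try:
                rows.append(effect(means, region, side, contrast, dispersion=dispersion))
            except ValueError:
                skipped.append((region, side))
    if skipped:
        warnings.warn(f"skipped {len(skipped)} region/side cell(s) with missing group means", stacklevel=2)
    return pd.DataFrame(rows)


def mean_absolute_difference(values) -> float:
    """Mean of |D_i| over the supplied effect values (NaN sentinels excluded)."""
    arr = np.asarray(values, float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("no finite effect values supplied")
    return float(np.abs(arr).mean())


def classify_regions(t: FosTable, alpha: float = 0.05, side: str = "ipsi") -> pd.DataFrame:
    """Two-factor (surgery × environment) classification per region.

    Per region a two-way ANOVA is fit on the per-animal densities of the
    requested side; p-values are Bonferroni-adjusted across the regions
    tested. Labels: ``interaction`` (significant surgery × environment term),
    ``explorationActivated`` (environment main effect, exploration higher),
    ``strokeHypoactive`` (surgery main effect, dMCAO lower), else
    ``unchanged``. Regions lacking two animals in any of the four cells are
    skipped with a warning.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = t.data[t.data["side"] == side]
    results = []
    skipped = []
    for region, sub in df.groupby("region"):
        counts = sub.groupby(["surgery", "environment"])["density"].count()
        cells = {(s, e) for s in SURGERIES for e in ENVIRONMENTS}
        if set(counts.index) != cells or (counts < 2).any():
            skipped.append(region)
            continue
        model = ols("density ~ C(surgery) * C(environment)", data=sub).fit()
        anova = sm.stats.anova_lm(model, typ=2)
        results.append(
            {
                "region": region,
                "p_surgery": float(anova.loc["C(surgery)", "PR(>F)"]),
                "p_environment": float(anova.loc["C(environment)", "PR(>F)"]),
                "p_interaction": float(anova.loc["C(surgery):C(environment)", "PR(>F)"]),
                "mean_diff_surgery": float(
                    sub[sub.surgery == "mcao"]["density"].mean() - sub[sub.surgery == "sham"]["density"].mean()
                ),
                "mean_diff_environment": float(
                    sub[sub.environment == "expl"]["density"].mean() - sub[sub.environment == "home"]["density"].mean()
                ),
            }
        )
    if skipped:
        warnings.warn(f"skipped {len(skipped)} region(s) with insufficient replication", stacklevel=2)
    out = pd.DataFrame(results)
    if out.empty:
        return out
    m = len(out)  # Bonferroni family: regions tested per contrast
    for col in ("p_surgery", "p_environment", "p_interaction"):
        out[col + "_adj"] = np.minimum(out[col] * m, 1.0)

    def label(row) -> str:
        if row["p_interaction_adj"] < alpha:
            return "interaction"
        if row["p_environment_adj"] < alpha and row["mean_diff_environment"] > 0:
            return "explorationActivated"
        if row["p_surgery_adj"] < alpha and row["mean_diff_surgery"] < 0:
            return "strokeHypoactive"
        return "unchanged"

    out["label"] = out.apply(label, axis=1)
    return out
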