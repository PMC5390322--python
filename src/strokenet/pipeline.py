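"""End-to-end orchestration: build → metrics → randomize → lesion → fos → associate.

The pipeline is a thin composition of the library modules. Every output file
embeds the configuration hash and master seed; stage outputs are written as
they complete so a failing stage leaves partial results behind.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, datasets, fos as fos_mod, lesion as lesion_mod, metrics
from .connectome import Connectome, LesionSet, load_connectome, write_connectome
from .synthetic import SimConfig, default_lesion_set, generate_connectome, generate_fos

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "reference_connectome", "simulate_dataset"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    ``shapley_permutations`` defaults to a few hundred here (rather than the
    library default of 5000) so a full desk-scale pipeline completes in
    seconds; raise it for publication-grade Shapley estimates.
    """

    region_table: str | None = None
    edge_table: str | None = None
    fos_table: str | None = None
    means_only: bool = False
    mode: str = "unweighted"
    weight_threshold: float = 0.0
    contrast: str = "stroke@expl"
    ensemble_reps: int = 50
    shapley_permutations: int = 500
    seed: int = 0
    output_dir: str = "strokenet_output"

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (the output location is excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def reference_connectome(seed: int = 0, cfg: SimConfig | None = None) -> Connectome:
    """Synthetic stand-in for the curated mesoscale connectome.

    Uses the packaged region nomenclature (38 bilateral Fos regions plus the
    six left-hemisphere lesion regions → 44 regions per hemisphere) so the
    bilateral analysis network has the reference 82-node composition.
    """
    abbrevs = datasets.fos_region_abbreviations() + datasets.lesion_region_abbreviations()
    if cfg is None:
        cfg = SimConfig(n_regions_per_hemisphere=len(abbrevs), seed=seed)
    return generate_connectome(cfg, abbreviations=abbrevs, lesion_abbrevs=datasets.lesion_region_abbreviations())


def simulate_dataset(out_dir: str | Path, cfg: SimConfig | None = None) -> dict[str, Path]:
    """Write a full synthetic dataset (region/edge tables, Fos CSV, ground truth)."""
    cfg = cfg or SimConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    c = generate_connectome(cfg)
    lesion = default_lesion_set(c)
    fos_table, truth = generate_fos(cfg, c, lesion)
    paths = {
        "region_table": out / "regions.csv",
        "edge_table": out / "edges.csv",
        "fos_table": out / "fos.csv",
        "ground_truth": out / "ground_truth.json",
    }
    write_connectome(c, paths["region_table"], paths["edge_table"])
    fos_table.to_csv(paths["fos_table"])
    paths["ground_truth"].write_text(
        json.dumps({"seed": cfg.seed, "truth": truth.to_dict(orient="records")}, indent=2)
    )
    return paths


def _fos_side_series(effects: pd.DataFrame, lesion_ids: set[str], column: str, side: str) -> pd.Series:
    """Map an effects column onto network node ids (abbrev + hemisphere suffix)."""
    suffix = "_L" if side == "ipsi" else "_R"
    sub = effects[effects["side"] == side]
    return pd.Series(sub[column].to_numpy(float), index=[r + suffix for r in sub["region"]])


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and write the report bundle; returns the summary dict."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": cfg.seed, "config_hash": cfg.config_hash()}
    summary: dict = {"meta": {**meta, "config": asdict(cfg)}}
    rng = np.random.default_rng(cfg.seed)
    stage_seeds = {name: int(s) for name, s in zip(
        ("simulate", "metrics", "randomize", "lesion"), rng.integers(0, 2**31 - 1, size=4)
    )}

    # -- build -------------------------------------------------------------
    if cfg.region_table and cfg.edge_table:
        c = load_connectome(cfg.region_table, cfg.edge_table)
    else:
        logger.info("no input tables given; generating the synthetic reference connectome")
        c = reference_connectome(seed=stage_seeds["simulate"])
    if cfg.weight_threshold > 0:
        from .connectome import filter_by_weight

        c = filter_by_weight(c, cfg.weight_threshold)
    lesion_ids = [rid for rid, r in c.regions.items() if r.lesioned]
    lesion = LesionSet(lesion_ids) if lesion_ids else None
    summary["build"] = {"n_regions": c.n_regions, "n_edges": c.n_edges, "lesion_regions": sorted(lesion_ids), **meta}

    # -- metrics -----------------------------------------------------------
    table = metrics.local_parameters(
        c, mode=cfg.mode, seed=stage_seeds["metrics"], shapley_permutations=cfg.shapley_permutations
    )
    ranks = association.rank(table.drop(columns=["AvgRang"]))
    table["AvgRang"] = ranks["AvgRang"]
    metrics.parameter_table_to_tidy(table).to_csv(out / "local_parameters.csv", index=False)
    g = metrics.global_parameters(c)
    top = ranks["AvgRang"].nsmallest(5)
    summary["metrics"] = {
        "global": g.to_dict(),
        "top_ranked_regions": {k: float(v) for k, v in top.items()},
        **meta,
    }

    # -- randomize ---------------------------------------------------------
    ensemble = metrics.randomized_ensemble(c.n_regions, c.n_edges, reps=cfg.ensemble_reps, seed=stage_seeds["randomize"])
    g.small_worldness = metrics.small_worldness(g, ensemble)
    summary["randomize"] = {"ensemble": ensemble.to_dict(), "small_worldness": g.small_worldness, **meta}

    # -- lesion ------------------------------------------------------------
    if lesion is not None and len(lesion) < c.n_regions:
        result = lesion_mod.lesion_delta(c, lesion, ensemble_reps=cfg.ensemble_reps, seed=stage_seeds["lesion"])
        pd.Series(result.vulnerability, name="vulnerability").rename_axis("region_id").to_csv(out / "vulnerability.csv")
        summary["lesion"] = {**result.to_dict(), **meta}
    else:
        summary["lesion"] = {"skipped": "no lesioned regions in the connectome", **meta}

    # -- fos ---------------------------------------------------------------
    if cfg.fos_table and cfg.means_only:
        means = fos_mod.means_from_table1(pd.read_csv(cfg.fos_table))
        classification = None
        logger.info("means-only Fos input: classification stage skipped")
    elif cfg.fos_table:
        fos_table = fos_mod.FosTable.from_csv(cfg.fos_table)
        means = fos_mod.group_means(fos_table)
        classification = fos_mod.classify_regions(fos_table)
    else:
        sim = SimConfig(seed=stage_seeds["simulate"])
        fos_table, _ = generate_fos(sim, c, lesion) if lesion is not None else (None, None)
        if fos_table is None:
            raise RuntimeError("fos stage needs either a Fos table or a lesioned connectome")
        means = fos_mod.group_means(fos_table)
        classification = fos_mod.classify_regions(fos_table)
    effects = fos_mod.effects_table(means, cfg.contrast)
    effects.to_csv(out / "fos_effects.csv", index=False)
    fos_block = {
        "contrast": cfg.contrast,
        "n_regions": int(effects["region"].nunique()) if not effects.empty else 0,
        "mean_absolute_Dr": fos_mod.mean_absolute_difference(effects["Dr"]) if not effects.empty else None,
        **meta,
    }
    if classification is not None and not classification.empty:
        fos_block["classification_counts"] = classification["label"].value_counts().to_dict()
        classification.to_csv(out / "fos_classification.csv", index=False)
    summary["fos"] = fos_block

    # -- associate ---------------------------------------------------------
    associate: dict = {**meta}
    if not effects.empty and lesion is not None:
        fos_ipsi = _fos_side_series(effects, set(lesion_ids), "Dr", "ipsi")
        corr = association.correlate_parameters_fos(table, fos_ipsi, exclude=set(lesion_ids))
        corr.to_csv(out / "parameter_fos_correlations.csv", index=False)
        finite = corr.dropna(subset=["r"])
        if not finite.empty:
            top_corr = finite.reindex(finite["r"].abs().sort_values(ascending=False).index).head(5)
            associate["top_parameter_correlations"] = {
                row["parameter"]: round(float(row["r"]), 4) for _, row in top_corr.iterrows()
            }
        dm = association.euclidean_distance_matrix(c)
        dm.to_csv(out / "distance_matrix.csv")
        hypo = _fos_side_series(effects, set(lesion_ids), "Dr", "ipsi") * -1.0  # hypoactivation magnitude
        dist_corr = association.distance_fos_correlation(dm, lesion, hypo)
        dist_corr.to_csv(out / "distance_fos_correlations.csv", index=False)
        associate["distance_fos"] = {
            row["damaged_region"]: round(float(row["r"]), 4) if np.isfinite(row["r"]) else None
            for _, row in dist_corr.iterrows()
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pca = association.pca_six(table)
        pca["scores"].to_csv(out / "pca_scores.csv")
        pca["loadings"].to_csv(out / "pca_loadings.csv")
        associate["pca_explained_variance_ratio"] = [round(float(v), 4) for v in pca["explained_variance_ratio"]]
    summary["associate"] = associate

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))
    return summary
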