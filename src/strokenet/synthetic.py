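"""Synthetic bilateral connectomes and per-animal Fos tables.

The generator emulates the statistical structure the analysis assumes, at
desk scale, so every pipeline stage is testable without the (unpublished)
curated tract-tracing connectome:

* a bilateral small-world graph — a within-hemisphere ring lattice with a
  little random rewiring, sparser cross-hemisphere edges preferentially
  homotopic, reciprocal edges inserted with a configurable bias, and ordinal
  weights drawn from the semiquantitative categories;
* region centres of gravity on two mirrored three-dimensional shells, with
  the lesioned regions clustered around a cortical lesion focus;
* four experimental groups (sham/dMCAO × home/exploration) with a
  multiplicative exploration activation effect, an ipsilesional
  hypoactivation whose depth decays exponentially with Euclidean distance
  from the nearest lesioned region, a homotopic contralesional compensation,
  and mean-one lognormal per-animal noise.

Both generators are fully deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import Connectome, LesionSet, Region
from .fos import FosTable

__all__ = ["SimConfig", "generate_connectome", "generate_fos", "default_lesion_set"]


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic generators.

    Defaults mirror the reference study's scale: 41 regions per hemisphere
    (82 network nodes), edge density tuned to ≈1215 directed connections,
    six lesioned regions, a ~3-fold exploration activation, a 0.8-deep
    ipsilesional hypoactivation decaying with a 2 mm length constant, and
    10 animals per group.
    """

    n_regions_per_hemisphere: int = 41
    lesion_count: int = 6
    edge_density: float = 0.183
    reciprocity_bias: float = 0.7
    within_vs_cross_hemisphere_ratio: float = 4.0
    rewire_prob: float = 0.05
    weight_category_probabilities: dict[float, float] = field(
        default_factory=lambda: {0.5: 0.15, 1.0: 0.25, 2.0: 0.30, 3.0: 0.20, 4.0: 0.10}
    )
    exploration_fold: float = 3.0
    exploration_jitter_sigma: float = 0.2
    hypoactivation_depth: float = 0.8
    distance_decay_lambda: float = 2.0
    contralateral_compensation: float = 0.3
    baseline_log_mean: float = 5.0  # log cells/mm²; exp(5) ≈ 148
    baseline_log_sigma: float = 1.0
    noise_sigma_log: float = 0.1
    animals_per_group: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.array(list(self.weight_category_probabilities.values()))
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("weight category probabilities must sum to 1")
        if not 0.0 <= self.reciprocity_bias <= 1.0:
            raise ValueError("reciprocity_bias must be in [0, 1]")
        if not 0.0 <= self.hypoactivation_depth <= 1.0:
            raise ValueError("hypoactivation_depth must be in [0, 1]")
        for name in ("edge_density", "distance_decay_lambda", "noise_sigma_log"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


_LESION_FOCUS = np.array([-4.5, 0.0, 2.0])  # left lateral cortex, stereotaxic mm


def _default_abbreviations(n: int) -> list[str]:
    return [f"R{i + 1:02d}" for i in range(n)]


def generate_connectome(
    cfg: SimConfig,
    abbreviations: list[str] | None = None,
    lesion_abbrevs: list[str] | None = None,
) -> Connectome:
    """Bilateral small-world connectome with mirrored regions and ordinal weights.

    ``abbreviations`` (one per hemispheric region pair) and ``lesion_abbrevs``
    default to generated names with the first ``lesion_count`` names lesioned.
    Raises if the requested density cannot support the reciprocity bias.
    """
    rng = np.random.default_rng(cfg.seed)
    n_h = cfg.n_regions_per_hemisphere
    abbrevs = list(abbreviations) if abbreviations is not None else _default_abbreviations(n_h)
    if len(abbrevs) != n_h:
        raise ValueError(f"expected {n_h} abbreviations, got {len(abbrevs)}")
    lesioned = list(lesion_abbrevs) if lesion_abbrevs is not None else abbrevs[: cfg.lesion_count]
    unknown = set(lesioned) - set(abbrevs)
    if unknown:
        raise ValueError(f"lesion abbreviation(s) not in region list: {sorted(unknown)}")

    # -- coordinates: mirrored shells; lesioned regions cluster at the focus
    coords_left = np.empty((n_h, 3))
    direction = rng.standard_normal((n_h, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    radius = 4.0 + rng.uniform(-0.8, 0.8, n_h)
    coords_left[:] = direction * radius[:, None]
    coords_left[:, 0] = -np.abs(coords_left[:, 0]) - 0.5  # keep left of the midline
    for ab in lesioned:
        i = abbrevs.index(ab)
        coords_left[i] = _LESION_FOCUS + rng.normal(0.0, 0.8, 3)
        coords_left[i, 0] = -abs(coords_left[i, 0])

    regions: list[Region] = []
    for i, ab in enumerate(abbrevs):
        left = Region(
            region_id=f"{ab}_L",
            name=f"synthetic region {ab}",
            abbreviation=ab,
            hemisphere="left",
            lesioned=ab in lesioned,
            coordinates=tuple(coords_left[i]),
        )
        regions.append(left)
        regions.append(left.mirrored())

    # -- edge budget
    n = 2 * n_h
    m_target = int(round(cfg.edge_density * n * (n - 1)))
    ratio = cfg.within_vs_cross_hemisphere_ratio
    m_within = int(round(m_target * ratio / (ratio + 1.0)))
    m_cross = m_target - m_within
    k_ring = int(round(m_within / 2 / (n_h * (1.0 + cfg.reciprocity_bias))))
    if k_ring < 1 or k_ring >= n_h // 2:
        raise ValueError("edge density infeasible for the requested reciprocity/lattice structure")

    categories = np.array(list(cfg.weight_category_probabilities.keys()))
    probs = np.array(list(cfg.weight_category_probabilities.values()))

    edges: dict[tuple[str, str], float] = {}

    def _add(u: str, v: str) -> None:
        if u != v and (u, v) not in edges:
            edges[(u, v)] = float(rng.choice(categories, p=probs))

    def _add_pair(u: str, v: str) -> None:
        if rng.random() < cfg.reciprocity_bias:
            _add(u, v)
            _add(v, u)
        else:
            if rng.random() < 0.5:
                _add(u, v)
            else:
                _add(v, u)

    suffixes = ("_L", "_R")
    for suffix in suffixes:
        names = [ab + suffix for ab in abbrevs]
        for i in range(n_h):
            for step in range(1, k_ring + 1):
                _add_pair(names[i], names[(i + step) % n_h])
    # random rewiring of within-hemisphere edges (targets move, sources stay)
    within_keys = [k for k in list(edges) if k[0][-2:] == k[1][-2:]]
    for u, v in within_keys:
        if rng.random() < cfg.rewire_prob:
            suffix = u[-2:]
            candidates = [ab + suffix for ab in abbrevs if ab + suffix != u and (u, ab + suffix) not in edges]
            if candidates:
                w = edges.pop((u, v))
                edges[(u, candidates[int(rng.integers(len(candidates)))])] = w

    # cross-hemisphere: half the budget homotopic (reciprocity-biased), rest random
    homotopic = rng.permutation(n_h)
    budget_pairs = max(0, m_cross) / (1.0 + cfg.reciprocity_bias)
    n_homotopic = min(n_h, int(round(budget_pairs * 0.5)))
    for i in homotopic[:n_homotopic]:
        _add_pair(abbrevs[i] + "_L", abbrevs[i] + "_R")
    all_names = [ab + s for s in suffixes for ab in abbrevs]
    attempts = 0
    while sum(1 for (u, v) in edges if u[-2:] != v[-2:]) < m_cross and attempts < 50 * m_cross:
        attempts += 1
        u = all_names[int(rng.integers(n))]
        v = all_names[int(rng.integers(n))]
        if u[-2:] != v[-2:]:
            _add(u, v)

    edge_list = sorted((u, v, w) for (u, v), w in edges.items())
    return Connectome(regions, edge_list)


def default_lesion_set(c: Connectome) -> LesionSet:
    """LesionSet of all regions flagged lesioned in the connectome."""
    ids = [rid for rid, r in c.regions.items() if r.lesioned]
    return LesionSet(ids)


def generate_fos(
    cfg: SimConfig,
    connectome: Connectome,
    lesion: LesionSet | None = None,
) -> tuple[FosTable, pd.DataFrame]:
    """Per-animal Fos densities for the four groups plus the ground-truth effect table.

    Group-mean construction per bilateral region with ipsilesional lesion
    distance d (the homotopic left-instance distance is used for the
    contralateral side, emulating homotopic compensation):

    * sham home: lognormal baseline ``B``
    * sham exploration: ``B × F`` with ``F`` the region-jittered exploration fold
    * dMCAO, ipsi: above × ``1 − depth·exp(−d/λ)``
    * dMCAO, contra: above × ``1 + compensation·exp(−d/λ)``

    Animal densities are the group mean times mean-one lognormal noise.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    lesion = lesion if lesion is not None else default_lesion_set(connectome)
    lesion.validate(connectome)
    lesion_coords = np.array([connectome.regions[rid].coordinates for rid in lesion])
    by_abbrev: dict[str, dict[str, str]] = {}
    for rid, r in connectome.regions.items():
        if rid in lesion.region_ids:
            continue
        by_abbrev.setdefault(r.abbreviation, {})[r.hemisphere] = rid
    fos_abbrevs = sorted(ab for ab, sides in by_abbrev.items() if {"left", "right"} <= set(sides))

    sigma = cfg.noise_sigma_log
    jit = cfg.exploration_jitter_sigma
    records = []
    truth = []
    for ab in fos_abbrevs:
        left_id = by_abbrev[ab]["left"]
        coords = np.array(connectome.regions[left_id].coordinates)
        d = float(np.linalg.norm(lesion_coords - coords, axis=1).min())
        decay = float(np.exp(-d / cfg.distance_decay_lambda))
        baseline = float(np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sigma)))
        fold = cfg.exploration_fold * float(np.exp(rng.normal(-jit**2 / 2.0, jit))) if jit > 0 else cfg.exploration_fold
        ipsi_factor = 1.0 - cfg.hypoactivation_depth * decay
        contra_factor = 1.0 + cfg.contralateral_compensation * decay
        means = {
            ("sham", "home", "ipsi"): baseline,
            ("sham", "home", "contra"): baseline,
            ("sham", "expl", "ipsi"): baseline * fold,
            ("sham", "expl", "contra"): baseline * fold,
            ("mcao", "home", "ipsi"): baseline * ipsi_factor,
            ("mcao", "home", "contra"): baseline * contra_factor,
            ("mcao", "expl", "ipsi"): baseline * fold * ipsi_factor,
            ("mcao", "expl", "contra"): baseline * fold * contra_factor,
        }
        for (surgery, environment, side), mu in means.items():
            noise = np.exp(rng.normal(-sigma**2 / 2.0, sigma, cfg.animals_per_group)) if sigma > 0 else np.ones(cfg.animals_per_group)
            for a, eps in enumerate(noise):
                records.append(
                    {
                        "region": ab,
                        "side": side,
                        "surgery": surgery,
                        "environment": environment,
                        "animal_id": f"{surgery}_{environment}_{a + 1:02d}",
                        "density": mu * eps,
                    }
                )
        truth.append(
            {
                "region": ab,
                "distance_to_lesion_mm": d,
                "baseline": baseline,
                "exploration_effect": fold - 1.0,
                "ipsilesional_effect": -cfg.hypoactivation_depth * decay,
                "contralesional_effect": cfg.contralateral_compensation * decay,
            }
        )
    return FosTable(pd.DataFrame.from_records(records)), pd.DataFrame(truth)
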