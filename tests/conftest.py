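"""Shared fixtures and graph-building helpers."""

from __future__ import annotations

import numpy as np
import pytest

from strokenet.connectome import Connectome, Region


def make_regions(n, hemisphere="left", lesioned=(), prefix="n", coords=None):
    regions = []
    for i in range(n):
        rid = f"{prefix}{i}"
        xyz = tuple(coords[i]) if coords is not None else (float(i), 0.0, 0.0)
        regions.append(
            Region(
                region_id=rid,
                name=f"region {rid}",
                abbreviation=rid,
                hemisphere=hemisphere,
                lesioned=rid in lesioned,
                coordinates=xyz,
            )
        )
    return regions


def make_connectome(n, edges, **kwargs):
    """Connectome on nodes n0..n{n-1} from (i, j[, w]) tuples."""
    triples = [(f"n{e[0]}", f"n{e[1]}", e[2] if len(e) > 2 else 1.0) for e in edges]
    return Connectome(make_regions(n, **{k: v for k, v in kwargs.items() if k != "allow_self_loops"}),
                      triples, allow_self_loops=kwargs.get("allow_self_loops", False))


def random_digraph_edges(n, p, rng, weighted=False):
    edges = []
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                w = float(rng.choice([0.5, 1.0, 2.0, 3.0, 4.0])) if weighted else 1.0
                edges.append((i, j, w))
    return edges


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_random_connectome(rng):
    """Seeded 8-node digraph used by the oracle tests."""
    return make_connectome(8, random_digraph_edges(8, 0.35, rng))
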