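"""Shared fixtures: tiny hand-built pedigrees, random DAGs, and an
exhaustive path-enumeration oracle for the propagation engine."""

from __future__ import annotations

import random
from fractions import Fraction

import numpy as np
import pytest

from mcatrace.contribution import SeedAssignment
from mcatrace.pedigree import PedigreeGraph, VarietyRecord
from mcatrace.simulate import SimConfig, gen_pedigree, plant_introgression


def make_graph(spec: dict[str, tuple[str, ...]], **attrs) -> PedigreeGraph:
    """Build a PedigreeGraph from {node: (parent, ...)} with multiplicity.

    ``attrs`` may carry per-node keyword overrides, e.g.
    ``years={"A": 1950}`` or ``flags={"D": {"dummy"}}``.
    """
    years = attrs.get("years", {})
    flags = attrs.get("flags", {})
    countries = attrs.get("countries", {})
    tags = attrs.get("tags", {})
    records = [
        VarietyRecord(
            unique_id=node,
            display_name=node,
            parent_refs=tuple(parents),
            year=years.get(node),
            country=countries.get(node),
            species_tag=tags.get(node),
            flags=frozenset(flags.get(node, ())),
        )
        for node, parents in spec.items()
    ]
    return PedigreeGraph(records)


def enumerate_oracle(
    graph: PedigreeGraph, seeds: SeedAssignment
) -> tuple[dict[str, Fraction], dict[str, int], dict[str, int]]:
    """Brute-force oracle: enumerate every directed descending path.

    For each seeded variety u and each path p from u to an ancestor a
    that passes through no blocked intermediate node, a receives
    s(u) * 2**(-len(p)) mass and one walk; reach counts distinct seeded
    origins. Exponential — only for graphs of a dozen nodes.
    """
    score = {v: Fraction(0) for v in graph}
    walks = {v: 0 for v in graph}
    origins = {v: set() for v in graph}

    def edges_out(v):
        # parallel edges listed separately (self-cross = two paths)
        return graph.parents(v)

    def extend(origin: str, node: str, depth: int, s: Fraction) -> None:
        for p in edges_out(node):
            score[p] += s / 2 ** (depth + 1)
            if s != 0:
                walks[p] += 1
                origins[p].add(origin)
            if p not in seeds.blocked:
                extend(origin, p, depth + 1, s)

    for u, s in seeds.seeds.items():
        extend(u, u, 0, Fraction(s))
    return score, walks, {v: len(o) for v, o in origins.items()}


def random_dag(
    rng: random.Random, max_nodes: int = 12
) -> tuple[PedigreeGraph, SeedAssignment]:
    """Random layered DAG with random seeds, blocks and self-crosses."""
    n = rng.randint(2, max_nodes)
    names = [f"N{i}" for i in range(n)]
    spec: dict[str, tuple[str, ...]] = {}
    for i, name in enumerate(names):
        # parents only among strictly earlier nodes (graph runs child->parent
        # toward low indices)
        candidates = names[:i]
        k = rng.choice([0, 1, 2]) if candidates else 0
        if k == 0:
            spec[name] = ()
        elif k == 1:
            spec[name] = (rng.choice(candidates),)
        else:
            p1 = rng.choice(candidates)
            p2 = rng.choice(candidates)  # may equal p1: self-cross
            spec[name] = (p1, p2)
    graph = make_graph(spec)
    seed_values = {}
    for name in names:
        r = rng.random()
        if r < 0.4:
            seed_values[name] = Fraction(rng.randint(-1, 4))
        elif r < 0.55:
            seed_values[name] = Fraction(rng.randint(1, 8), 2)
    blocked = {name for name in names if rng.random() < 0.15}
    return graph, SeedAssignment(seeds=seed_values, blocked=blocked)


@pytest.fixture(scope="session")
def sim_dataset():
    """One default-condition simulated dataset shared across tests."""
    cfg = SimConfig(seed=11)
    graph = gen_pedigree(cfg)
    matrix, truth = plant_introgression(graph, cfg)
    return cfg, graph, matrix, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
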