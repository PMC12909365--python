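"""Contribution-score propagation on the pedigree DAG.

Each focal variety is seeded with a score (1.0 in the classic analysis)
and passes half of its outgoing mass to each recorded parent, so an
ancestor's score is the sum over all descending paths p from seeded
varieties of s(v) * 2**(-len(p)) — an expected-genome-share-style weight.
Ancestors of many focal varieties accumulate large scores and are the
Major Contributing Ancestors (MCAs).

Rules that matter for bookkeeping:

* a node's reported score is the mass it *receives*; its own seed is
  propagated but never counted for itself;
* a self-cross sends both halves to the single parent;
* a missing parent slot's half is lost (not redistributed);
* *blocked* nodes (dummy placeholders, and genotyped non-carriers in the
  genotype-seeded variant) transmit only their own seed and discard any
  inherited mass.

Arithmetic is exact: seeds are held as :class:`fractions.Fraction`, and
halving keeps all masses dyadic rationals, so the conservation ledger
balances identically rather than to float tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Rational
from typing import Callable, Iterable

import pandas as pd

from .pedigree import PedigreeGraph

__all__ = [
    "SeedAssignment",
    "ContributionResult",
    "seed_uniform",
    "propagate",
    "count_walks",
    "rank_mcas",
    "aggregate_donor_scores",
]


def _to_fraction(value) -> Fraction:
    if isinstance(value, Rational):
        return Fraction(value)
    f = float(value)
    if f != f or f in (float("inf"), float("-inf")):
        raise ValueError(f"non-finite seed value {value!r}")
    return Fraction(*f.as_integer_ratio())


@dataclass
class SeedAssignment:
    """Seed scores per variety plus the set of blocked (non-transmitting) nodes.

    ``blocked`` must contain every dummy/unresolved-duplicate node; the
    genotype-seeded variant adds the -1-sentinel varieties.
    """

    seeds: dict[str, Fraction]
    blocked: set[str] = field(default_factory=set)

    def validate(self, graph: PedigreeGraph) -> None:
        missing = [v for v in self.seeds if v not in graph]
        if missing:
            raise ValueError(f"seeded ids not in graph: {sorted(missing)[:5]}")
        if not self.blocked >= graph.dummy_ids:
            raise ValueError("blocked set must include all dummy nodes")

    def __add__(self, other: "SeedAssignment") -> "SeedAssignment":
        seeds = dict(self.seeds)
        for k, v in other.seeds.items():
            seeds[k] = seeds.get(k, Fraction(0)) + v
        return SeedAssignment(seeds, self.blocked | other.blocked)


@dataclass
class ContributionResult:
    """Propagation output: per-node scores, walk counts and the mass ledger.

    ``score[v]`` is the mass v received from its descendants (own seed
    excluded); ``walks[v]`` counts distinct descending paths from seeded
    varieties (edge multiplicity separates paths); ``reach[v]`` counts
    seeded varieties with at least one such path. The ledger splits the
    total seeded mass into what was absorbed at parentless nodes, lost at
    missing parent slots, and discarded at blocked nodes.
    """

    score: dict[str, Fraction]
    walks: dict[str, int]
    reach: dict[str, int]
    total_seeded: Fraction
    absorbed: Fraction
    lost_missing_parent: Fraction
    lost_blocked: Fraction
    n_focal: int = 0

    def score_float(self, unique_id: str) -> float:
        return float(self.score.get(unique_id, 0))

    @property
    def ledger_imbalance(self) -> Fraction:
        return self.total_seeded - (
            self.absorbed + self.lost_missing_parent + self.lost_blocked
        )

    def total_walks(self, unique_id: str | None = None) -> int:
        if unique_id is not None:
            return self.walks.get(unique_id, 0)
        return sum(self.walks.values())


def seed_uniform(graph: PedigreeGraph, focal: Iterable[str]) -> SeedAssignment:
    """Seed every focal variety with score 1; block only the dummy nodes."""
    focal = set(focal)
    missing = sorted(v for v in focal if v not in graph)
    if missing:
        raise ValueError(f"focal ids not in graph: {missing[:10]}")
    dummies = graph.dummy_ids
    offenders = sorted(focal & dummies)
    if offenders:
        raise ValueError(f"dummy nodes cannot be focal varieties: {offenders[:10]}")
    return SeedAssignment(
        seeds={v: Fraction(1) for v in focal},
        blocked=set(dummies),
    )


def propagate(graph: PedigreeGraph, seeds: SeedAssignment) -> ContributionResult:
    """Propagate seed mass child -> parent with generational halving.

    Nodes are visited in topological order (children first). Each node's
    outgoing mass is its seed plus inherited mass — or the seed alone if
    the node is blocked, the inherited part being discarded — and is split
    into two halves, one per parent slot. Recorded parents receive their
    half; a missing slot's half is lost; a parentless node absorbs its
    whole outgoing mass.
    """
    seeds.validate(graph)
    seed_map = {v: _to_fraction(s) for v, s in seeds.seeds.items()}
    blocked = seeds.blocked
    zero = Fraction(0)
    score: dict[str, Fraction] = {v: zero for v in graph}
    absorbed = lost_missing = lost_blocked = zero

    for v in graph.topological_order():
        inherited = score[v]
        own = seed_map.get(v, zero)
        if v in blocked:
            lost_blocked += inherited
            out = own
        else:
            out = own + inherited
        if out == 0:
            continue
        parents = graph.parents(v)
        if not parents:
            absorbed += out
            continue
        half = out / 2
        for p in parents:
            score[p] += half
        if len(parents) == 1:
            lost_missing += half

    walks, reach = count_walks(graph, seeds)
    return ContributionResult(
        score=score,
        walks=walks,
        reach=reach,
        total_seeded=sum(seed_map.values(), zero),
        absorbed=absorbed,
        lost_missing_parent=lost_missing,
        lost_blocked=lost_blocked,
        n_focal=sum(1 for s in seed_map.values() if s != 0),
    )


def count_walks(
    graph: PedigreeGraph, seeds: SeedAssignment
) -> tuple[dict[str, int], dict[str, int]]:
    """Count distinct descending paths (walks) from seeded varieties.

    ``walks[a]`` sums, over seeded varieties v, the number of distinct
    directed paths v -> a; parallel edges (self-cross) yield distinct
    paths. Blocked nodes terminate passing paths exactly as they discard
    passing mass, while a seeded blocked node still originates paths.
    ``reach[a]`` counts seeded varieties with at least one surviving path.
    """
    seeds.validate(graph)
    seeded = {v for v, s in seeds.seeds.items() if s != 0}
    blocked = seeds.blocked
    walks: dict[str, int] = {v: 0 for v in graph}
    sources: dict[str, set[str]] = {v: set() for v in graph}

    for v in graph.topological_order():
        out_paths = walks[v] if v not in blocked else 0
        out_sources = sources[v] if v not in blocked else set()
        if v in seeded:
            out_paths += 1
            out_sources = out_sources | {v}
        if not out_paths:
            continue
        for p in graph.parents(v):  # multiplicity preserved
            walks[p] += out_paths
            sources[p].update(out_sources)

    reach = {v: len(s) for v, s in sources.items()}
    return walks, reach


def rank_mcas(
    result: ContributionResult,
    graph: PedigreeGraph,
    top_n: int = 25,
) -> pd.DataFrame:
    """Rank ancestors by descending contribution score.

    Equal scores share a rank and the following rank is skipped
    (competition ranking: 1, 1, 3). ``n_offspring`` is the number of
    distinct immediate descendants in the full pedigree.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    scored = [
        (uid, s) for uid, s in result.score.items() if s != 0
    ]
    scored.sort(key=lambda kv: (-kv[1], kv[0]))
    rows = []
    last_score = None
    last_rank = 0
    for i, (uid, s) in enumerate(scored[: max(top_n, 0)], start=1):
        if s == last_score:
            rank = last_rank
        else:
            rank = i
            last_score, last_rank = s, i
        rec = graph.records[uid]
        rows.append(
            {
                "rank": rank,
                "unique_id": uid,
                "name": rec.display_name,
                "year": rec.year,
                "country": rec.country,
                "n_offspring": graph.n_offspring(uid),
                "score": round(float(s), 2),
                "walks": result.walks.get(uid, 0),
                "reach": result.reach.get(uid, 0),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "rank", "unique_id", "name", "year", "country",
            "n_offspring", "score", "walks", "reach",
        ],
    )


def vernei_predicate(rec) -> bool:
    """Default donor matcher: *S. vernei* sources by name or species tag."""
    return "S. vernei" in rec.display_name or (rec.species_tag or "") == "vrn"


def aggregate_donor_scores(
    result: ContributionResult,
    graph: PedigreeGraph,
    tag_predicate: Callable = vernei_predicate,
) -> tuple[float, list[str]]:
    """Sum contribution scores over donor-species nodes matched by the predicate.

    Returns the summed score and the sorted list of matched node ids.
    """
    matched = sorted(
        uid for uid, rec in graph.records.items() if tag_predicate(rec)
    )
    total = sum((result.score.get(uid, Fraction(0)) for uid in matched), Fraction(0))
    return float(total), matched
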