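"""Genotype-seeded MCA: tracing introgression clusters through the pedigree.

Instead of uniform unit seeds, each genotyped variety is seeded with its
mean dosage of the derived alleles of one SNP cluster. Genotyped
varieties carrying none of the alleles receive a -1.0 sentinel and become
*blocked*: an introgressed haplotype cannot have passed through a
confirmed non-carrier, so they transmit only their own penalty and
discard inherited mass. Ungenotyped varieties are transparent conduits
(seed 0, unblocked) — missing data is not evidence of absence. The
resulting score surface concentrates positive mass along the pedigree
lineages through which the haplotype actually descended.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

import networkx as nx

from .contribution import ContributionResult, SeedAssignment, propagate
from .pedigree import PedigreeGraph
from .snps import DosageMatrix, SNPCluster

logger = logging.getLogger(__name__)

__all__ = [
    "seed_genotype_scores",
    "propagate_blocked",
    "top_lineages",
    "Lineage",
]


def seed_genotype_scores(
    cluster: SNPCluster,
    matrix: DosageMatrix,
    sample_map: Mapping[str, str],
    graph: PedigreeGraph,
) -> SeedAssignment:
    """Build the genotype seed assignment for one SNP cluster.

    ``sample_map`` maps genotyped sample ids to pedigree unique ids. A
    variety's seed is the mean dosage over the cluster's member SNPs,
    missing calls excluded; a variety observed as dosage 0 at every
    non-missing member gets the -1.0 sentinel and joins the blocked set
    (alongside the dummy nodes). Samples mapping to absent pedigree nodes
    are skipped with a warning; varieties with no observed member calls
    are treated as ungenotyped.
    """
    members = [m for m in cluster.members if m in matrix.dosage.columns]
    seeds: dict[str, Fraction] = {}
    blocked: set[str] = set(graph.dummy_ids)
    for sample, uid in sample_map.items():
        if uid not in graph:
            logger.warning(
                "sample %s maps to %s, absent from pedigree; skipped", sample, uid
            )
            continue
        if sample not in matrix.dosage.index:
            continue
        obs = matrix.dosage.loc[sample, members].dropna()
        if obs.empty:
            continue  # effectively ungenotyped for this cluster
        total = int(obs.sum())
        if total == 0:
            seeds[uid] = Fraction(-1)
            blocked.add(uid)
        else:
            seeds[uid] = Fraction(total, len(obs))
    return SeedAssignment(seeds=seeds, blocked=blocked)


def propagate_blocked(
    graph: PedigreeGraph, seeds: SeedAssignment
) -> ContributionResult:
    """Propagate genotype seeds with blocking.

    The propagation rule is shared with the uniform analysis
    (:func:`mcatrace.contribution.propagate`): blocked nodes transmit only
    their own seed — for a non-carrier, -1 split over its parents — while
    inherited mass stops there and is logged to the ledger. Negative mass
    received by unblocked ancestors keeps propagating, penalising
    lineages that demonstrably did not transmit the haplotype.
    """
    return propagate(graph, seeds)


@dataclass
class Lineage:
    """One candidate independent transmission lineage.

    ``nodes`` is a weakly connected component of the subgraph induced by
    the top MCAs plus all pedigree paths between them; ``apexes`` are its
    ancestor-most nodes (no parents inside the full graph beyond the
    component), the candidate donor entry points.
    """

    nodes: frozenset[str]
    apexes: tuple[str, ...]
    top_mcas: tuple[str, ...]


def top_lineages(
    result: ContributionResult,
    graph: PedigreeGraph,
    top_n: int = 25,
) -> list[Lineage]:
    """Partition the top positive-scoring MCAs into independent lineages.

    The ``top_n`` highest positive scores are taken; the induced node set
    additionally contains every variety lying on a directed pedigree path
    between two of them. Weakly connected components of this subgraph are
    returned as candidate independent lineages, largest first; each
    component's apexes (nodes whose recorded parents all lie outside the
    component, or that are parentless) are flagged as potential donor
    entry points.
    """
    positive = sorted(
        ((uid, s) for uid, s in result.score.items() if s > 0),
        key=lambda kv: (-kv[1], kv[0]),
    )[:top_n]
    if not positive:
        return []
    top = {uid for uid, _ in positive}

    # nodes on a path u ->* w ->* v between top nodes (edges run child->parent)
    ancestor_side: set[str] = set(top)
    descendant_side: set[str] = set(top)
    for t in top:
        ancestor_side |= nx.descendants(graph.graph, t)
        descendant_side |= nx.ancestors(graph.graph, t)
    on_paths = ancestor_side & descendant_side

    sub = graph.graph.subgraph(on_paths)
    lineages = []
    for comp in nx.weakly_connected_components(sub):
        comp = frozenset(comp)
        apexes = tuple(
            sorted(
                n for n in comp
                if not any(p in comp for p in graph.parents(n))
            )
        )
        lineages.append(
            Lineage(
                nodes=comp,
                apexes=apexes,
                top_mcas=tuple(sorted(comp & top)),
            )
        )
    lineages.sort(key=lambda L: (-len(L.nodes), L.apexes))
    return lineages


def capped_display_scores(
    result: ContributionResult, floor: float = -1.0
) -> dict[str, float]:
    """Scores for visual export, capped below at ``floor``.

    Numeric outputs stay uncapped; only renderings clamp strongly negative
    nodes so colour scales remain readable.
    """
    return {
        uid: max(float(s), floor) for uid, s in result.score.items()
    }
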