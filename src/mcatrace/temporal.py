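"""Haplotype structure, occurrence over release time, and enrichment tests.

These reports sit downstream of SNP clustering: hierarchical clustering
of per-variety dosage vectors resolves haplotype groups within an
introgressed region; binning focal varieties by release year tracks how
often each cluster occurs through breeding history; and a 2x2 chi-squared
test asks whether carriers are over-represented in a labelled
subpopulation (e.g. starch cultivars).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.stats import chi2_contingency

from .snps import DosageMatrix, SNPCluster

logger = logging.getLogger(__name__)

__all__ = [
    "HaplotypeGrouping",
    "TemporalOccurrence",
    "haplotype_cluster",
    "occurrence_over_time",
    "enrichment_test",
]


@dataclass
class HaplotypeGrouping:
    """k haplotype groups over varieties plus the linkage for dendrograms.

    ``labels`` maps variety/sample id -> group label (1..k);
    ``leaf_order`` lists ids in dendrogram leaf order for heatmap
    rendering; ``linkage_matrix`` is the scipy linkage encoding.
    """

    labels: dict[str, int]
    leaf_order: list[str]
    linkage_matrix: np.ndarray
    k: int


def haplotype_cluster(
    matrix: DosageMatrix,
    snp_ids: Sequence[str] | None = None,
    k: int = 8,
) -> HaplotypeGrouping:
    """Agglomerative clustering of varieties on their dosage vectors.

    Euclidean distance, average linkage, cut at exactly ``k`` groups;
    missing dosages are treated as 0. Varieties are pre-sorted by id so
    the grouping does not depend on input order.
    """
    sub = matrix if snp_ids is None else matrix.subset_snps(snp_ids)
    samples = sorted(sub.samples)
    X = sub.imputed().loc[samples].to_numpy(dtype=float)
    if k > len(samples):
        raise ValueError(f"k={k} exceeds the {len(samples)} varieties")
    Z = linkage(X, method="average", metric="euclidean")
    flat = fcluster(Z, t=k, criterion="maxclust")
    order = [samples[i] for i in leaves_list(Z)]
    return HaplotypeGrouping(
        labels=dict(zip(samples, (int(v) for v in flat))),
        leaf_order=order,
        linkage_matrix=Z,
        k=k,
    )


@dataclass
class TemporalOccurrence:
    """Carrier counts of each cluster per release period.

    ``table`` is long-format with columns ``cluster_id, bin, n_bin,
    n_carrying``; bins are a pre-cutoff group, a transition group, then
    decades closed on the right (e.g. "1971-1980").
    """

    table: pd.DataFrame
    bins: list[str]

    def for_cluster(self, cluster_id: str) -> pd.DataFrame:
        return self.table[self.table["cluster_id"] == cluster_id].reset_index(
            drop=True
        )


def _bin_label(year: int, cutoff: int, transition_end: int) -> str:
    if year < cutoff:
        return f"<{cutoff}"
    if year <= transition_end:
        return f"{cutoff}-{transition_end}"
    start = ((year - 1) // 10) * 10 + 1
    return f"{start}-{start + 9}"


def occurrence_over_time(
    matrix: DosageMatrix,
    clusters: Sequence[SNPCluster],
    release_years: Mapping[str, int],
    cutoff: int = 1945,
    transition_end: int = 1970,
    samples: Sequence[str] | None = None,
) -> TemporalOccurrence:
    """Count, per cluster and release period, varieties carrying the cluster.

    A variety carries a cluster when it has dosage > 0 at any member SNP.
    Varieties without a known release year are excluded from binning and
    logged.
    """
    use = list(samples) if samples is not None else matrix.samples
    dated = []
    for s in use:
        if s in release_years:
            dated.append(s)
        else:
            logger.info("sample %s has no release year; excluded from binning", s)
    labels = {
        s: _bin_label(release_years[s], cutoff, transition_end) for s in dated
    }

    def bin_sort_key(label: str) -> tuple[int, int]:
        if label.startswith("<"):
            return (0, 0)
        start = int(label.split("-")[0])
        return (1, start)

    bin_names = sorted(set(labels.values()), key=bin_sort_key)
    bin_members = {
        b: [s for s in dated if labels[s] == b] for b in bin_names
    }
    rows = []
    for cluster in clusters:
        members = [m for m in cluster.members if m in matrix.dosage.columns]
        carrier = (matrix.dosage[members].fillna(0) > 0).any(axis=1)
        for b in bin_names:
            ids = bin_members[b]
            rows.append(
                {
                    "cluster_id": cluster.cluster_id,
                    "bin": b,
                    "n_bin": len(ids),
                    "n_carrying": int(carrier.loc[ids].sum()),
                }
            )
    return TemporalOccurrence(
        table=pd.DataFrame(
            rows, columns=["cluster_id", "bin", "n_bin", "n_carrying"]
        ),
        bins=bin_names,
    )


def enrichment_test(table: Sequence[Sequence[float]]) -> dict:
    """Pearson chi-squared test of a 2x2 subpopulation-by-carrier table.

    No continuity correction, df = 1; returns the statistic and upper-tail
    p-value. A zero row or column marginal makes the statistic undefined:
    the result carries NaNs and ``valid=False`` instead of raising.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("enrichment_test expects a 2x2 table")
    if (arr < 0).any():
        raise ValueError("cell counts must be nonnegative")
    if arr.sum() == 0:
        raise ValueError("table total must be positive")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return {"statistic": float("nan"), "p_value": float("nan"), "valid": False}
    stat, p, dof, _ = chi2_contingency(arr, correction=False)
    assert dof == 1
    return {"statistic": float(stat), "p_value": float(p), "valid": True}
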