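"""Detection of modern introgression SNP clusters from tetraploid dosages.

A dosage matrix records, per sample and SNP, the copy number (0-4) of the
alternate allele in an autotetraploid, with missing calls allowed. SNPs
that are homozygous in all pre-cutoff "historical" varieties but variable
among later material carry derived alleles introduced by modern
introgression breeding. Such SNPs are grouped by the similarity of their
dosage profiles across samples — PCA down to a few components followed by
density-based hierarchical clustering (HDBSCAN) — so that the markers of
one introgressed haploblock fall into one cluster, without using genomic
position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "DosageMatrix",
    "SNPCluster",
    "filter_modern_snps",
    "cluster_snps",
    "first_observed",
    "summarize_cluster",
]


@dataclass
class DosageMatrix:
    """Samples x SNPs tetraploid allele dosages with SNP annotations.

    ``dosage`` is a float DataFrame (rows = samples, columns = SNP ids)
    with values in {0..4} or NaN for missing calls; ``annotation`` is
    indexed by SNP id with at least ``chrom`` and ``pos`` (1-based bp)
    columns.
    """

    dosage: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if self.dosage.index.has_duplicates:
            raise ValueError("duplicate sample ids in dosage matrix")
        vals = self.dosage.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 4):
            raise ValueError("dosages must lie in 0..4")
        missing_annot = self.dosage.columns.difference(self.annotation.index)
        if len(missing_annot):
            raise ValueError(
                f"SNPs without annotation: {list(missing_annot[:5])}"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.dosage.index)

    @property
    def snps(self) -> list[str]:
        return list(self.dosage.columns)

    def subset_snps(self, snp_ids: Sequence[str]) -> "DosageMatrix":
        snp_ids = [s for s in snp_ids if s in self.dosage.columns]
        return DosageMatrix(
            self.dosage[snp_ids], self.annotation.loc[snp_ids]
        )

    def imputed(self) -> pd.DataFrame:
        """Dosages with missing calls set to 0 (the reference state)."""
        return self.dosage.fillna(0.0)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_tsv(
        cls, dosage_path: str | Path, annotation_path: str | Path
    ) -> "DosageMatrix":
        """Read wide-format dosages (rows = samples) + SNP annotation TSV."""
        dosage = pd.read_csv(
            dosage_path, sep="\t", index_col=0, na_values=["", "NA"]
        ).astype(float)
        annot = pd.read_csv(annotation_path, sep="\t", index_col="snp_id")
        return cls(dosage, annot)

    def to_tsv(self, dosage_path: str | Path, annotation_path: str | Path) -> None:
        self.dosage.to_csv(dosage_path, sep="\t", na_rep="NA")
        self.annotation.to_csv(annotation_path, sep="\t", index_label="snp_id")


@dataclass
class SNPCluster:
    """A group of co-occurring derived alleles marking one putative haploblock.

    ``cluster_id`` is "<chromosome>.<index>" with indices assigned per
    chromosome in descending mean frequency; ``per_snp_frequency`` is the
    fraction of focal genotyped varieties carrying each member allele
    (dosage > 0).
    """

    cluster_id: str
    members: tuple[str, ...]
    chrom: str
    start: int
    end: int
    per_snp_frequency: dict[str, float]
    mean_frequency: float
    high_confidence: bool
    attributed_origin: str | None = None
    minority_members: tuple[str, ...] = ()

    @property
    def span(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def __len__(self) -> int:
        return len(self.members)


def filter_modern_snps(
    matrix: DosageMatrix, historical: Iterable[str]
) -> list[str]:
    """SNPs homozygous in every historical sample yet variable later.

    A SNP is retained when all non-missing historical dosages equal 0, or
    all equal 4, and at least one non-historical sample departs from that
    homozygous value. SNPs missing in every historical sample are
    excluded and logged.
    """
    historical = sorted(set(historical))
    if not historical:
        raise ValueError("historical sample set must be nonempty")
    missing = [s for s in historical if s not in matrix.dosage.index]
    if missing:
        raise ValueError(f"historical samples not in matrix: {missing[:5]}")
    hist = matrix.dosage.loc[historical]
    modern = matrix.dosage.drop(index=historical)
    kept: list[str] = []
    for snp in matrix.snps:
        h = hist[snp].dropna()
        if h.empty:
            logger.info("SNP %s missing in all historical samples; excluded", snp)
            continue
        if (h == 0).all():
            base = 0.0
        elif (h == 4).all():
            base = 4.0
        else:
            continue
        m = modern[snp].dropna()
        if (m != base).any():
            kept.append(snp)
    return kept


def _presence_frequency(
    matrix: DosageMatrix, snp: str, focal_samples: Sequence[str]
) -> float:
    """Fraction of focal genotyped varieties with dosage > 0 at the SNP."""
    col = matrix.dosage.loc[list(focal_samples), snp]
    obs = col.dropna()
    if obs.empty:
        return 0.0
    return float((obs > 0).mean())


def cluster_snps(
    matrix: DosageMatrix,
    focal_samples: Sequence[str] | None = None,
    n_components: int = 5,
    min_cluster_size: int = 5,
    min_samples: int = 5,
    min_allele_freq: float = 0.003,
    max_clusters_per_chromosome: int = 25,
    high_confidence_min_carriers: int = 5,
    random_state: int = 0,
) -> list[SNPCluster]:
    """Group modern SNPs into co-occurrence clusters.

    Each SNP is a point in sample-dosage space (missing imputed as 0).
    Points are projected onto the first ``n_components`` principal
    components (mean-centred, unscaled — dosages share a scale) and
    clustered with HDBSCAN; noise points are discarded. Clusters are
    assigned to the majority chromosome of their members, numbered per
    chromosome in descending mean focal-carrier frequency, truncated at
    ``max_clusters_per_chromosome``, and dropped when their mean frequency
    falls below ``min_allele_freq``. A cluster is high-confidence when any
    member allele is carried by at least ``high_confidence_min_carriers``
    focal genotyped varieties.
    """
    snp_ids = matrix.snps
    if len(snp_ids) < min_cluster_size:
        raise ValueError(
            f"need at least {min_cluster_size} SNPs, got {len(snp_ids)}"
        )
    focal = list(focal_samples) if focal_samples is not None else matrix.samples

    X = matrix.imputed().to_numpy(dtype=float).T  # snp x sample
    k = min(n_components, min(X.shape))
    if k < n_components:
        logger.warning(
            "reducing PCA components from %d to %d (matrix shape %s)",
            n_components, k, X.shape,
        )
    pcs = PCA(n_components=k, random_state=random_state).fit_transform(X)
    labels = HDBSCAN(
        min_cluster_size=min_cluster_size,
        min_samples=min_samples,
        allow_single_cluster=True,
        copy=True,
    ).fit_predict(pcs)

    raw: list[dict] = []
    for lab in sorted(set(labels) - {-1}):
        members = [snp_ids[i] for i in np.flatnonzero(labels == lab)]
        freqs = {s: _presence_frequency(matrix, s, focal) for s in members}
        mean_freq = float(np.mean(list(freqs.values())))
        if mean_freq < min_allele_freq:
            continue
        chroms = matrix.annotation.loc[members, "chrom"].astype(str)
        majority = chroms.value_counts().idxmax()
        minority = tuple(s for s in members if str(chroms[s]) != majority)
        if minority:
            logger.info(
                "cluster on %s has %d member(s) on other chromosomes: %s",
                majority, len(minority), minority,
            )
        pos = matrix.annotation.loc[members, "pos"]
        n_focal_carriers = {
            s: int(
                (matrix.dosage.loc[focal, s].dropna() > 0).sum()
            )
            for s in members
        }
        raw.append(
            {
                "members": tuple(members),
                "chrom": str(majority),
                "start": int(pos.min()),
                "end": int(pos.max()),
                "freqs": freqs,
                "mean_freq": mean_freq,
                "high_conf": max(n_focal_carriers.values(), default=0)
                >= high_confidence_min_carriers,
                "minority": minority,
            }
        )

    clusters: list[SNPCluster] = []
    by_chrom: dict[str, list[dict]] = {}
    for c in raw:
        by_chrom.setdefault(c["chrom"], []).append(c)
    for chrom in sorted(by_chrom):
        ordered = sorted(
            by_chrom[chrom], key=lambda c: (-c["mean_freq"], c["start"])
        )[:max_clusters_per_chromosome]
        for idx, c in enumerate(ordered, start=1):
            clusters.append(
                SNPCluster(
                    cluster_id=f"{chrom}.{idx}",
                    members=c["members"],
                    chrom=chrom,
                    start=c["start"],
                    end=c["end"],
                    per_snp_frequency=c["freqs"],
                    mean_frequency=c["mean_freq"],
                    high_confidence=c["high_conf"],
                    minority_members=c["minority"],
                )
            )
    return clusters


def first_observed(
    matrix: DosageMatrix,
    release_years: Mapping[str, int],
    drop_samples: Sequence[str] = (),
    snps: Sequence[str] | None = None,
) -> dict[str, str | None]:
    """Map each SNP to the earliest-released carrier sample.

    Samples in ``drop_samples`` (e.g. suspected mislabelled accessions)
    are removed before the search; ties on release year break by sample id
    order and are logged. Alleles with no carrier map to None.
    """
    drop = set(drop_samples)
    usable = [s for s in matrix.samples if s not in drop]
    unknown = [s for s in usable if s not in release_years]
    if unknown:
        raise ValueError(
            f"release year unknown for genotyped samples: {unknown[:5]}"
        )
    out: dict[str, str | None] = {}
    for snp in (snps if snps is not None else matrix.snps):
        col = matrix.dosage.loc[usable, snp]
        carriers = col[col > 0]
        if carriers.empty:
            out[snp] = None
            continue
        ranked = sorted(carriers.index, key=lambda s: (release_years[s], s))
        best_year = release_years[ranked[0]]
        ties = [s for s in ranked if release_years[s] == best_year]
        if len(ties) > 1:
            logger.info(
                "SNP %s: first-observed tie at %d among %s; keeping %s",
                snp, best_year, ties, ranked[0],
            )
        out[snp] = ranked[0]
    return out


def summarize_cluster(
    cluster: SNPCluster,
    matrix: DosageMatrix,
    focal_samples: Sequence[str] | None = None,
    qtl_table: pd.DataFrame | None = None,
    first_observed_map: Mapping[str, str | None] | None = None,
) -> dict:
    """Summary record for one cluster: span, frequencies, origin, QTL overlaps.

    ``qtl_table`` needs columns ``chrom, start, end, name``; an interval
    overlaps the cluster span under closed-interval comparison.
    ``attributed_origin`` is the majority vote of the first-observed
    carrier over member SNPs (when a first-observed map is supplied).
    """
    focal = list(focal_samples) if focal_samples is not None else matrix.samples
    freqs = {
        s: _presence_frequency(matrix, s, focal) for s in cluster.members
    }
    origin = None
    if first_observed_map is not None:
        votes = pd.Series(
            [
                first_observed_map.get(s)
                for s in cluster.members
                if first_observed_map.get(s) is not None
            ],
            dtype=object,
        )
        if not votes.empty:
            counts = votes.value_counts()
            top = counts[counts == counts.max()].index.sort_values()
            origin = top[0]
    overlaps: list[str] = []
    if qtl_table is not None and len(qtl_table):
        q = qtl_table[qtl_table["chrom"].astype(str) == cluster.chrom]
        hit = q[(q["start"] <= cluster.end) & (q["end"] >= cluster.start)]
        overlaps = list(hit["name"])
    return {
        "cluster_id": cluster.cluster_id,
        "chrom": cluster.chrom,
        "start": cluster.start,
        "end": cluster.end,
        "n_snps": len(cluster.members),
        "per_snp_frequency": freqs,
        "mean_frequency": float(np.mean(list(freqs.values()))),
        "high_confidence": cluster.high_confidence,
        "attributed_origin": origin,
        "qtl_overlaps": overlaps,
    }


def clusters_to_frame(clusters: Sequence[SNPCluster]) -> pd.DataFrame:
    """Flatten clusters to the TSV output schema."""
    return pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "n_snps": len(c),
                "mean_freq": c.mean_frequency,
                "high_confidence": c.high_confidence,
                "attributed_origin": c.attributed_origin or "",
            }
            for c in clusters
        ]
    )
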