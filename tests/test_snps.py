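"""Modern-SNP filtering, co-occurrence clustering and cluster summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mcatrace.snps import (
    DosageMatrix,
    cluster_snps,
    filter_modern_snps,
    first_observed,
    summarize_cluster,
)


def build_matrix(dosage: dict[str, list], samples: list[str], annot: dict | None = None):
    df = pd.DataFrame(dosage, index=samples, dtype=float)
    if annot is None:
        annot = {
            s: {"chrom": "1", "pos": 1000 + i}
            for i, s in enumerate(df.columns)
        }
    ann = pd.DataFrame.from_dict(annot, orient="index")
    ann.index.name = "snp_id"
    return DosageMatrix(df, ann)


def planted_matrix(rng, n_samples=200, block_sizes=(8, 8), n_background=50,
                   carrier_frac=0.1, block_dosage=2.0):
    """Blocks of perfectly co-segregating SNPs + independent singletons."""
    cols, annot, truth = {}, {}, {}
    for b, size in enumerate(block_sizes):
        carriers = rng.random(n_samples) < carrier_frac
        for j in range(size):
            sid = f"b{b}_{j}"
            cols[sid] = np.where(carriers, block_dosage, 0.0)
            annot[sid] = {"chrom": str(b + 1), "pos": 10_000 + j * 1000}
            truth[sid] = f"block{b}"
    for k in range(n_background):
        sid = f"bg{k}"
        cols[sid] = rng.binomial(4, rng.uniform(0.1, 0.5), size=n_samples).astype(float)
        annot[sid] = {"chrom": str(1 + k % 12), "pos": 900_000 + k * 1000}
        truth[sid] = "noise"
    samples = [f"S{i}" for i in range(n_samples)]
    return build_matrix(cols, samples, annot), truth


class TestFilterModernSnps:
    def test_homozygous_historical_variable_modern_retained(self):
        m = build_matrix(
            {"s1": [0, 0, np.nan, 0, 2], "s2": [0, 2, 0, 0, 2], "s3": [4, 4, 4, 4, 4]},
            ["h1", "h2", "h3", "m1", "m2"],
        )
        kept = filter_modern_snps(m, ["h1", "h2", "h3"])
        # s1: historical {0,0,NA} and a modern 2 -> keep
        # s2: historical polymorphic -> drop; s3: never variable -> drop
        assert kept == ["s1"]

    def test_all_four_homozygous_counts(self):
        m = build_matrix(
            {"s1": [4, 4, 2, 4]}, ["h1", "h2", "m1", "m2"]
        )
        assert filter_modern_snps(m, ["h1", "h2"]) == ["s1"]

    def test_snp_missing_in_all_historical_excluded(self):
        m = build_matrix({"s1": [np.nan, np.nan, 2]}, ["h1", "h2", "m1"])
        assert filter_modern_snps(m, ["h1", "h2"]) == []

    def test_idempotent_and_sample_order_independent(self):
        rng = np.random.default_rng(5)
        m, _ = planted_matrix(rng, n_samples=60, n_background=20)
        hist = m.samples[:10]
        kept = filter_modern_snps(m, hist)
        sub = m.subset_snps(kept)
        assert filter_modern_snps(sub, hist) == kept
        shuffled = DosageMatrix(
            m.dosage.iloc[::-1], m.annotation
        )
        assert set(filter_modern_snps(shuffled, hist)) == set(kept)

    def test_empty_historical_rejected(self):
        m = build_matrix({"s1": [0, 1]}, ["a", "b"])
        with pytest.raises(ValueError):
            filter_modern_snps(m, [])


class TestClusterSnps:
    def test_planted_blocks_recovered_exactly(self):
        rng = np.random.default_rng(0)
        m, truth = planted_matrix(rng)
        clusters = cluster_snps(m)
        recovered = {frozenset(c.members) for c in clusters}
        planted = {
            frozenset(s for s, b in truth.items() if b == f"block{i}")
            for i in range(2)
        }
        assert planted <= recovered
        # no recovered cluster mixes planted-block SNPs with background
        block_snps = {s for s, b in truth.items() if b != "noise"}
        for c in clusters:
            hit = set(c.members) & block_snps
            assert not hit or frozenset(c.members) in planted

    def test_identical_columns_co_cluster(self):
        rng = np.random.default_rng(3)
        m, truth = planted_matrix(rng, block_sizes=(6,), n_background=40)
        clusters = cluster_snps(m)
        members = {s for c in clusters for s in c.members}
        block = {s for s, b in truth.items() if b == "block0"}
        assert any(block <= set(c.members) for c in clusters)
        assert block <= members

    def test_cluster_ids_numbered_by_descending_frequency(self):
        rng = np.random.default_rng(8)
        # two blocks on one chromosome with different carrier fractions
        cols, annot = {}, {}
        n = 300
        rare = rng.random(n) < 0.05
        common = rng.random(n) < 0.4
        for j in range(6):
            cols[f"r{j}"] = np.where(rare, 2.0, 0.0)
            annot[f"r{j}"] = {"chrom": "7", "pos": 100 + j}
        for j in range(6):
            cols[f"c{j}"] = np.where(common, 2.0, 0.0)
            annot[f"c{j}"] = {"chrom": "7", "pos": 5000 + j}
        m = build_matrix(cols, [f"S{i}" for i in range(n)], annot)
        clusters = cluster_snps(m)
        assert [c.cluster_id for c in clusters[:2]] == ["7.1", "7.2"]
        assert clusters[0].mean_frequency >= clusters[1].mean_frequency
        assert set(clusters[0].members) == {f"c{j}" for j in range(6)}

    def test_reproducible_under_fixed_seed(self):
        rng1 = np.random.default_rng(17)
        rng2 = np.random.default_rng(17)
        m1, _ = planted_matrix(rng1)
        m2, _ = planted_matrix(rng2)
        c1 = cluster_snps(m1)
        c2 = cluster_snps(m2)
        assert [(c.cluster_id, c.members) for c in c1] == [
            (c.cluster_id, c.members) for c in c2
        ]

    def test_min_membership_and_frequency_enforced(self):
        rng = np.random.default_rng(2)
        m, _ = planted_matrix(rng)
        for c in cluster_snps(m):
            assert len(c.members) >= 5
            assert c.mean_frequency >= 0.003

    def test_too_few_snps_rejected(self):
        m = build_matrix({"s1": [0, 2], "s2": [0, 2]}, ["a", "b"])
        with pytest.raises(ValueError):
            cluster_snps(m)


class TestFirstObserved:
    def test_earliest_carrier_wins(self):
        m = build_matrix({"s1": [0, 1, 2]}, ["X", "Y", "Z"])
        years = {"X": 1990, "Y": 1962, "Z": 1985}
        assert first_observed(m, years) == {"s1": "Y"}

    def test_dropped_sample_recomputes_to_next_earliest(self):
        m = build_matrix({"s1": [2, 1, 0]}, ["U", "Y", "Z"])
        years = {"U": 1950, "Y": 1962, "Z": 1985}
        assert first_observed(m, years, drop_samples=["U"]) == {"s1": "Y"}

    def test_tie_breaks_by_sample_id(self):
        m = build_matrix({"s1": [1, 1]}, ["B", "A"])
        years = {"A": 1962, "B": 1962}
        assert first_observed(m, years) == {"s1": "A"}

    def test_no_carrier_maps_to_none(self):
        m = build_matrix({"s1": [0, 0]}, ["A", "B"])
        assert first_observed(m, {"A": 1950, "B": 1960}) == {"s1": None}


class TestSummarizeCluster:
    def test_span_frequency_origin_and_qtl_overlap(self):
        rng = np.random.default_rng(4)
        m, truth = planted_matrix(rng, block_sizes=(6,), n_background=30)
        clusters = cluster_snps(m)
        target = next(
            c for c in clusters
            if set(c.members) == {s for s, b in truth.items() if b == "block0"}
        )
        years = {s: 1950 + i for i, s in enumerate(m.samples)}
        fo = first_observed(m, years, snps=target.members)
        qtl = pd.DataFrame(
            [
                {"chrom": "1", "start": 9_000, "end": 12_000, "name": "starch QTL"},
                {"chrom": "1", "start": 500_000, "end": 600_000, "name": "far away"},
            ]
        )
        rec = summarize_cluster(target, m, qtl_table=qtl, first_observed_map=fo)
        assert rec["qtl_overlaps"] == ["starch QTL"]
        assert rec["n_snps"] == 6
        assert 0 <= rec["mean_frequency"] <= 1
        # perfectly co-segregating members are all first seen in the
        # earliest carrier, which becomes the attributed origin
        assert rec["attributed_origin"] == fo[target.members[0]]

    def test_closed_interval_boundary_overlap(self):
        rng = np.random.default_rng(6)
        m, _ = planted_matrix(rng, block_sizes=(5,), n_background=20)
        c = cluster_snps(m)[0]
        qtl = pd.DataFrame(
            [{"chrom": c.chrom, "start": c.end, "end": c.end + 10, "name": "edge"}]
        )
        rec = summarize_cluster(c, m, qtl_table=qtl)
        assert rec["qtl_overlaps"] == ["edge"]
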