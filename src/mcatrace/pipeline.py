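"""End-to-end analysis driver over a dataset directory.

Expects the on-disk layout the simulator emits (and that a curated real
dataset can be arranged into):

* ``pedigree.tsv``       — raw pedigree table (name, parents, year, ...)
* ``catalogue.txt``      — one focal variety name per line (optional;
  default: every post-cutoff pedigree variety)
* ``dosage.tsv``         — samples x SNPs tetraploid dosages (optional)
* ``snp_annotation.tsv`` — snp_id, chrom, pos (with dosage)
* ``sample_map.tsv``     — sample_id, pedigree_name (with dosage)
* ``historical.txt``     — historical sample ids, one per line (optional;
  default: genotyped samples released before the cutoff)

Returns the headline quantities of each stage in one flat dict.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import contribution, intro_mca, pedigree, snps


def run_full_analysis(
    data_dir: str | Path,
    cutoff: int = 1945,
    top_n: int = 25,
) -> dict:
    data_dir = Path(data_dir)
    graph = pedigree.parse_pedigree(data_dir / "pedigree.tsv")

    catalogue_path = data_dir / "catalogue.txt"
    if catalogue_path.exists():
        names = [
            l.strip() for l in catalogue_path.read_text().splitlines() if l.strip()
        ]
    else:
        names = sorted(
            {
                r.display_name
                for r in graph.records.values()
                if not r.is_dummy and r.year is not None and r.year >= cutoff
            }
        )
    selection = pedigree.select_focal_set(graph, names)
    seeds = contribution.seed_uniform(graph, selection.ids)
    result = contribution.propagate(graph, seeds)
    ranking = contribution.rank_mcas(result, graph, top_n=top_n)
    vernei_sum, vernei_nodes = contribution.aggregate_donor_scores(result, graph)

    out = {
        "n_pedigree_records": len(graph),
        "n_catalogue_matched": len(selection.ids),
        "n_ancestors_score_above_2": int(
            sum(1 for s in result.score.values() if s > 2)
        ),
        "top_mca": ranking.iloc[0]["name"] if len(ranking) else None,
        "top_mca_score": float(ranking.iloc[0]["score"]) if len(ranking) else None,
        "top_mca_walks": int(ranking.iloc[0]["walks"]) if len(ranking) else None,
        "top_mca_reach_fraction": (
            float(ranking.iloc[0]["reach"]) / len(selection.ids)
            if len(ranking) and selection.ids
            else None
        ),
        "donor_species_score_sum": vernei_sum,
        "n_donor_species_nodes": len(vernei_nodes),
        "ranking": ranking,
    }

    dosage_path = data_dir / "dosage.tsv"
    if dosage_path.exists():
        matrix = snps.DosageMatrix.from_tsv(
            dosage_path, data_dir / "snp_annotation.tsv"
        )
        map_df = pd.read_csv(data_dir / "sample_map.tsv", sep="\t", dtype=str)
        name_to_id = {
            r.display_name: r.unique_id
            for r in graph.records.values()
            if "unresolved_duplicate" not in r.flags
        }
        id_set = set(graph.records)
        sample_map = {}
        for sample, ped_name in zip(map_df["sample_id"], map_df["pedigree_name"]):
            if ped_name in id_set:
                sample_map[sample] = ped_name
            elif ped_name in name_to_id:
                sample_map[sample] = name_to_id[ped_name]
        hist_path = data_dir / "historical.txt"
        if hist_path.exists():
            historical = [
                l.strip() for l in hist_path.read_text().splitlines() if l.strip()
            ]
        else:
            historical = [
                s
                for s, uid in sample_map.items()
                if s in matrix.dosage.index
                and (graph.records[uid].year or cutoff) < cutoff
            ]
        modern = snps.filter_modern_snps(matrix, historical)
        out["n_historical_samples"] = len(historical)
        out["n_modern_snps"] = len(modern)
        clusters = (
            snps.cluster_snps(matrix.subset_snps(modern))
            if len(modern) >= 5
            else []
        )
        out["n_snp_clusters"] = len(clusters)
        out["clusters"] = clusters
        per_cluster = {}
        for c in clusters:
            gseeds = intro_mca.seed_genotype_scores(c, matrix, sample_map, graph)
            res = intro_mca.propagate_blocked(graph, gseeds)
            table = contribution.rank_mcas(res, graph, top_n=top_n)
            lineages = intro_mca.top_lineages(res, graph, top_n=top_n)
            per_cluster[c.cluster_id] = {
                "ranking": table,
                "n_lineages": len(lineages),
                "lineages": lineages,
            }
        out["per_cluster_mca"] = per_cluster
    return out
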