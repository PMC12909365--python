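"""Synthetic pedigrees and tetraploid dosage matrices with planted truth.

The generator emulates the shape of historical crop-breeding data: a
layered multi-generation pedigree (new varieties cross pairs of earlier
ones, with occasional self-crosses, missing parents and duplicate display
names), release years advancing by roughly one breeding cycle per
generation, and an autotetraploid SNP dosage matrix in which

* background SNPs segregate from the founder generation onward and are
  polymorphic among pre-cutoff varieties, and
* one or more *introgression blocks* enter through a single donor variety
  after the historical cutoff and co-transmit down the donor's lineage.

Inheritance follows random bivalent pairing: each parent passes
``h ~ Hypergeometric(4, dosage, 2)`` copies per gamete (no double
reduction). Popular varieties are re-used as parents (preferential
attachment); a block's donor — and optionally its carrier descendants —
receives an extra parent-selection weight, mimicking deliberate breeding
use of an introgression carrier, which controls the block's final
carrier frequency.

Everything is deterministic given ``SimConfig.seed``; the
:class:`TruthSet` records the planted carriers, the donor and the actual
transmission edges, so every downstream stage can be validated against
ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pedigree import PedigreeGraph, VarietyRecord
from .snps import DosageMatrix

__all__ = [
    "IntrogressionBlock",
    "SimConfig",
    "TruthSet",
    "gen_pedigree",
    "transmit_dosage",
    "plant_introgression",
    "write_raw_pedigree",
    "write_dataset",
]

_COUNTRIES = ("Netherlands", "Germany", "Great Britain", "France", "USA")

# P(h = k | parent dosage d) for a gamete of 2 chromosomes drawn from 4:
# hypergeometric pmf C(d,k)*C(4-d,2-k)/C(4,2).
_GAMETE_CDF = np.array(
    [
        [1.0, 1.0, 1.0],          # d=0 -> h=0
        [1 / 2, 1.0, 1.0],        # d=1 -> 1/2, 1/2, 0
        [1 / 6, 5 / 6, 1.0],      # d=2 -> 1/6, 2/3, 1/6
        [0.0, 1 / 2, 1.0],        # d=3 -> 0, 1/2, 1/2
        [0.0, 0.0, 1.0],          # d=4 -> h=2
    ]
)


@dataclass(frozen=True)
class IntrogressionBlock:
    """One planted haploblock entering via a single post-cutoff donor."""

    donor_generation: int = 10
    n_snps: int = 8
    donor_dosage: int = 4
    co_transmission: float = 0.95
    chrom: str = "5"
    start_bp: int = 1_000_000
    spacing_bp: int = 500_000


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults produce a 1,000-variety pedigree (50 founders + 19
    generations of 50 crosses) spanning ~1850-2015 with a seven-year
    breeding cycle, one 8-SNP introgression block entering circa 1950,
    and half of the varieties genotyped.
    """

    n_founders: int = 50
    n_generations: int = 19
    crosses_per_generation: int = 50
    p_missing_parent: float = 0.05
    p_duplicate_name: float = 0.01
    p_self_cross: float = 0.02
    founder_year_range: tuple[int, int] = (1850, 1895)
    generation_spacing: int = 7
    base_year: int = 1880
    year_jitter: int = 2
    historical_cutoff: int = 1945
    n_background_snps: int = 60
    blocks: tuple[IntrogressionBlock, ...] = (IntrogressionBlock(),)
    carrier_selection_boost: float = 1.0
    donor_usage_boost: float = 12.0
    genotyped_fraction: float = 0.5
    p_missing_dosage: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.p_missing_parent,
            self.p_duplicate_name,
            self.p_self_cross,
            self.genotyped_fraction,
            self.p_missing_dosage,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_founders < 1:
            raise ValueError("need at least one founder")
        for b in self.blocks:
            if b.n_snps < 1:
                raise ValueError("blocks need at least one SNP")
            if not 1 <= b.donor_generation <= self.n_generations:
                raise ValueError("donor generation outside the pedigree")

    @property
    def n_varieties(self) -> int:
        """Total records: founders, crosses, plus one wild donor per block."""
        return (
            self.n_founders
            + self.n_generations * self.crosses_per_generation
            + len(self.blocks)
        )


@dataclass
class TruthSet:
    """Ground truth of the planted introgressions.

    Per block id: the member SNPs, the donor variety, the set of carrier
    varieties (dosage > 0 at any member, over *all* varieties), and the
    pedigree edges along which at least one derived copy was actually
    transmitted. ``lineage_nodes`` is the donor plus every variety touched
    by a transmission edge — the true transmission lineage.
    """

    block_members: dict[str, tuple[str, ...]]
    donors: dict[str, str]
    carriers: dict[str, set[str]]
    transmission_edges: dict[str, list[tuple[str, str]]]

    def lineage_nodes(self, block_id: str) -> set[str]:
        nodes = {self.donors[block_id]}
        for child, parent in self.transmission_edges[block_id]:
            nodes.add(child)
            nodes.add(parent)
        return nodes

    def to_json(self, path: str | Path) -> None:
        payload = {
            "block_members": {k: list(v) for k, v in self.block_members.items()},
            "donors": self.donors,
            "carriers": {k: sorted(v) for k, v in self.carriers.items()},
            "transmission_edges": {
                k: [list(e) for e in v] for k, v in self.transmission_edges.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# Pedigree generation
# ---------------------------------------------------------------------------

def gen_pedigree(config: SimConfig) -> PedigreeGraph:
    """Generate a layered breeding pedigree.

    Each generation's varieties pick two parents from the three preceding
    layers with preferential attachment (weight grows with offspring
    count); descendants of a block donor get an extra selection boost.
    Duplicate display names and missing parent slots are injected at the
    configured rates. The returned graph carries simulator metadata in
    ``graph.sim_generation`` (unique id -> layer) and ``graph.sim_donors``
    (block id -> donor unique id).
    """
    rng = np.random.default_rng(config.seed)
    records: list[VarietyRecord] = []
    generation: dict[str, int] = {}
    names_in_use: list[str] = []
    child_count: dict[str, int] = {}
    donor_by_generation = {
        b.donor_generation: f"block{i}" for i, b in enumerate(config.blocks)
    }
    donors: dict[str, str] = {}
    donor_descendants: set[str] = set()

    serial = 0

    def fresh_name() -> str:
        nonlocal serial
        serial += 1
        if names_in_use and rng.random() < config.p_duplicate_name:
            return str(rng.choice(names_in_use))
        return f"SIM{serial:04d}"

    def uid_for(name: str) -> str:
        return f"{name.upper()}_{serial}"

    layers: list[list[str]] = [[]]
    for _ in range(config.n_founders):
        name = fresh_name()
        uid = uid_for(name)
        year = int(rng.integers(*config.founder_year_range))
        records.append(
            VarietyRecord(
                unique_id=uid,
                display_name=name,
                year=year,
                country=str(rng.choice(_COUNTRIES)),
            )
        )
        names_in_use.append(name)
        generation[uid] = 0
        child_count[uid] = 0
        layers[0].append(uid)

    rec_by_uid = {r.unique_id: r for r in records}

    for g in range(1, config.n_generations + 1):
        layer: list[str] = []
        if g in donor_by_generation:
            # an introgression donor enters the pedigree as a parentless
            # wild accession (like a collected clone), not as a cross
            block_id = donor_by_generation[g]
            name = fresh_name()
            uid = uid_for(name)
            rec = VarietyRecord(
                unique_id=uid,
                display_name=name,
                year=config.base_year + g * config.generation_spacing,
                country=str(rng.choice(_COUNTRIES)),
                species_tag="vrn",
            )
            records.append(rec)
            rec_by_uid[uid] = rec
            names_in_use.append(name)
            generation[uid] = g
            child_count[uid] = 0
            donors[block_id] = uid
            donor_descendants.add(uid)
            layer.append(uid)
        pool: list[str] = []
        for back in range(1, 4):
            if g - back >= 0:
                pool.extend(layers[g - back])
        weights = np.array(
            [
                (1.0 + child_count[u])
                * (
                    config.donor_usage_boost
                    if u in donors.values()
                    else config.carrier_selection_boost
                    if u in donor_descendants
                    else 1.0
                )
                for u in pool
            ]
        )
        weights = weights / weights.sum()
        for _ in range(config.crosses_per_generation):
            p1 = str(rng.choice(pool, p=weights))
            if rng.random() < config.p_self_cross:
                p2 = p1
            else:
                p2 = str(rng.choice(pool, p=weights))
            parent_ids = [p1, p2]
            parent_names = [
                rec_by_uid[p1].display_name,
                rec_by_uid[p2].display_name,
            ]
            if rng.random() < config.p_missing_parent:
                drop = int(rng.integers(2))
                parent_ids.pop(drop)
                parent_names[drop] = ""
            name = fresh_name()
            uid = uid_for(name)
            year = config.base_year + g * config.generation_spacing + int(
                rng.integers(-config.year_jitter, config.year_jitter + 1)
            )
            country = (
                rec_by_uid[p1].country
                if rng.random() < 0.7
                else str(rng.choice(_COUNTRIES))
            )
            rec = VarietyRecord(
                unique_id=uid,
                display_name=name,
                parent_refs=tuple(parent_ids),
                parent_names=(
                    parent_names[0],
                    parent_names[1] if len(parent_names) > 1 else "",
                ),
                year=year,
                country=country,
            )
            records.append(rec)
            rec_by_uid[uid] = rec
            names_in_use.append(name)
            generation[uid] = g
            child_count[uid] = 0
            for p in set(parent_ids):
                child_count[p] += 1
            if p1 in donor_descendants or p2 in donor_descendants:
                donor_descendants.add(uid)
            layer.append(uid)
        layers.append(layer)

    graph = PedigreeGraph(records)
    graph.sim_generation = generation  # type: ignore[attr-defined]
    graph.sim_donors = donors  # type: ignore[attr-defined]
    graph.sim_layers = layers  # type: ignore[attr-defined]
    return graph


# ---------------------------------------------------------------------------
# Dosage transmission
# ---------------------------------------------------------------------------

def transmit_dosage(parent_dosages: tuple[int, int], rng: np.random.Generator) -> int:
    """Offspring dosage from two tetraploid parents under bivalent pairing.

    Each parent transmits ``h ~ Hypergeometric(population 4, successes =
    dosage, draws 2)`` copies; the offspring dosage is the sum.
    """
    total = 0
    for d in parent_dosages:
        if not 0 <= d <= 4:
            raise ValueError(f"dosage {d} outside 0..4")
        total += int(rng.hypergeometric(d, 4 - d, 2))
    return total


def _gametes(dosages: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Vectorised inverse-CDF gamete draw: copies transmitted per SNP.

    ``u`` uniforms shared across SNPs yield perfectly coupled (linked)
    transmission; independent uniforms yield independent assortment.
    """
    cdf = _GAMETE_CDF[dosages.astype(int)]
    return (u[:, None] > cdf).sum(axis=1)


def plant_introgression(
    graph: PedigreeGraph, config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[DosageMatrix, TruthSet]:
    """Simulate dosages over the pedigree and plant the configured blocks.

    Founders carry dosage 0 at block SNPs; each block's donor variety is
    set to the configured donor dosage, and the derived alleles then
    descend by gamete sampling, with probability ``co_transmission`` of a
    fully linked (shared-uniform) gamete per meiosis. Background SNPs
    start from founder frequencies and are redrawn until polymorphic
    among historical genotyped varieties, so they can never masquerade as
    modern introgressions. A missing parent contributes reference gametes
    at block SNPs and population-frequency gametes at background SNPs.

    Returns the genotyped subset as a :class:`DosageMatrix` (missing
    calls injected at ``p_missing_dosage``) and the :class:`TruthSet`
    over all varieties.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    generation = graph.sim_generation  # type: ignore[attr-defined]
    donors = graph.sim_donors  # type: ignore[attr-defined]
    order = sorted(graph.records, key=lambda u: (generation[u], u))
    n_all = len(order)
    idx = {u: i for i, u in enumerate(order)}

    # genotyped subset (sampled over all varieties)
    n_geno = max(1, int(round(config.genotyped_fraction * n_all)))
    genotyped = sorted(rng.choice(order, size=n_geno, replace=False))
    hist_geno = [
        u for u in genotyped
        if graph.records[u].year is not None
        and graph.records[u].year < config.historical_cutoff
    ]

    snp_ids: list[str] = []
    annot_rows: list[dict] = []
    columns: dict[str, np.ndarray] = {}

    # --- background SNPs --------------------------------------------------
    def simulate_background(freqs: np.ndarray) -> np.ndarray:
        """Simulate all background columns at once (variety-major loop)."""
        k = len(freqs)
        dos = np.zeros((n_all, k), dtype=int)
        for u in order:
            i = idx[u]
            if generation[u] == 0:
                dos[i] = rng.binomial(4, freqs)
                continue
            parents = graph.parents(u)
            h = np.zeros(k, dtype=int)
            for p in parents:
                h += _gametes(dos[idx[p]], rng.random(k))
            for _ in range(2 - len(parents)):
                h += rng.binomial(2, freqs)
            dos[i] = h
        return dos

    n_bg = config.n_background_snps
    if n_bg:
        bg = simulate_background(rng.uniform(0.15, 0.85, size=n_bg))
        hist_idx = [idx[u] for u in hist_geno]
        for _attempt in range(30):
            if not hist_idx:
                break
            h = bg[hist_idx]
            # a column monomorphic 0 or 4 in the historical panel could be
            # mistaken for a modern introgression marker; redraw it
            bad = np.flatnonzero(
                np.logical_or((h == 0).all(axis=0), (h == 4).all(axis=0))
            )
            if not len(bad):
                break
            bg[:, bad] = simulate_background(
                rng.uniform(0.15, 0.85, size=len(bad))
            )
        for b in range(n_bg):
            sid = f"bg{b:04d}"
            snp_ids.append(sid)
            annot_rows.append(
                {
                    "snp_id": sid,
                    "chrom": str(1 + b % 12),
                    "pos": int(2_000_000 + (b // 12) * 1_000_000),
                }
            )
            columns[sid] = bg[:, b]

    # --- introgression blocks --------------------------------------------
    block_members: dict[str, tuple[str, ...]] = {}
    carriers: dict[str, set[str]] = {}
    edges: dict[str, list[tuple[str, str]]] = {}
    for bi, block in enumerate(config.blocks):
        block_id = f"block{bi}"
        donor = donors[block_id]
        members = tuple(f"blk{bi}_{j}" for j in range(block.n_snps))
        block_members[block_id] = members
        for j, sid in enumerate(members):
            annot_rows.append(
                {
                    "snp_id": sid,
                    "chrom": block.chrom,
                    "pos": block.start_bp + j * block.spacing_bp,
                }
            )
            snp_ids.append(sid)
        dos = np.zeros((n_all, block.n_snps), dtype=int)
        trans: list[tuple[str, str]] = []
        donor_gen = generation[donor]
        for u in order:
            i = idx[u]
            if u == donor:
                dos[i, :] = block.donor_dosage
                continue
            if generation[u] == 0:
                continue
            total = np.zeros(block.n_snps, dtype=int)
            for p in graph.parents(u):
                pd_ = dos[idx[p]]
                if not pd_.any():
                    continue
                if rng.random() < block.co_transmission:
                    u_draw = np.full(block.n_snps, rng.random())
                else:
                    u_draw = rng.random(block.n_snps)
                h = _gametes(pd_, u_draw)
                if h.any():
                    trans.append((u, p))
                total += h
            dos[i] = np.minimum(total, 4)
        carriers[block_id] = {u for u in order if dos[idx[u]].any()}
        # the donor's own ancestry never carried the block
        assert donor_gen > 0
        edges[block_id] = trans
        for j, sid in enumerate(members):
            columns[sid] = dos[:, j]

    data = np.column_stack([columns[s] for s in snp_ids]).astype(float)
    full = pd.DataFrame(data, index=order, columns=snp_ids)
    geno = full.loc[genotyped].copy()
    if config.p_missing_dosage > 0:
        mask = rng.random(geno.shape) < config.p_missing_dosage
        geno = geno.mask(mask)
    annotation = pd.DataFrame(annot_rows).set_index("snp_id")
    matrix = DosageMatrix(geno, annotation)
    truth = TruthSet(
        block_members=block_members,
        donors=dict(donors),
        carriers=carriers,
        transmission_edges=edges,
    )
    return matrix, truth


def planted_block_matrix(
    rng: np.random.Generator,
    n_samples: int = 200,
    block_sizes: Sequence[int] = (8, 8),
    n_background: int = 50,
    carrier_frac: float = 0.1,
    block_dosage: float = 2.0,
) -> tuple[DosageMatrix, dict[str, str]]:
    """Dosage matrix with perfectly co-segregating planted blocks.

    Each block is carried (at ``block_dosage``) by an independent random
    ``carrier_frac`` subset of samples; background SNPs are rare
    singletons present in 1-5 random samples each. Returns the matrix and
    the true label per SNP ("block<i>" or "noise") for
    partition-recovery benchmarks of the co-occurrence clustering.
    """
    cols: dict[str, np.ndarray] = {}
    annot_rows = []
    truth: dict[str, str] = {}
    for b, size in enumerate(block_sizes):
        carriers = rng.random(n_samples) < carrier_frac
        for j in range(size):
            sid = f"b{b}_{j}"
            cols[sid] = np.where(carriers, block_dosage, 0.0)
            annot_rows.append(
                {"snp_id": sid, "chrom": str(b + 1), "pos": 10_000 + j * 1_000}
            )
            truth[sid] = f"block{b}"
    for k in range(n_background):
        sid = f"bg{k}"
        v = np.zeros(n_samples)
        idx = rng.choice(n_samples, int(rng.integers(1, 6)), replace=False)
        v[idx] = rng.integers(1, 5)
        cols[sid] = v
        annot_rows.append(
            {"snp_id": sid, "chrom": str(1 + k % 12), "pos": 900_000 + k * 1_000}
        )
        truth[sid] = "noise"
    samples = [f"S{i}" for i in range(n_samples)]
    dosage = pd.DataFrame(cols, index=samples)
    annotation = pd.DataFrame(annot_rows).set_index("snp_id")
    return DosageMatrix(dosage, annotation), truth


def partition_recovery_ari(
    clusters, truth_labels: dict[str, str], snp_ids: Sequence[str]
) -> float:
    """Adjusted Rand index between recovered clusters and planted blocks.

    The truth side partitions SNPs into planted blocks plus one
    background class. On the recovered side, clusters containing no
    planted SNP are folded into the background class: the planted truth
    says nothing about co-occurrence structure *within* the background,
    so sub-structure there is not an error, whereas any split, merge or
    background contamination of a planted block lowers the index.
    """
    from sklearn.metrics import adjusted_rand_score

    planted = {s for s, lab in truth_labels.items() if lab != "noise"}
    pred: dict[str, str] = {s: "noise" for s in snp_ids}
    for c in clusters:
        label = c.cluster_id if set(c.members) & planted else "noise"
        for s in c.members:
            pred[s] = label
    return float(
        adjusted_rand_score(
            [truth_labels[s] for s in snp_ids], [pred[s] for s in snp_ids]
        )
    )


# ---------------------------------------------------------------------------
# File emission (the exact formats the analysis modules consume)
# ---------------------------------------------------------------------------

def write_raw_pedigree(graph: PedigreeGraph, path: str | Path) -> None:
    """Write the simulated pedigree in the raw input-table schema.

    Parents are written as display names (as a historical table would),
    so re-parsing exercises the full curation pipeline including
    duplicate-name resolution.
    """
    rows = []
    for rec in graph.records.values():
        names = [
            graph.records[p].display_name for p in rec.parent_refs
        ] + ["", ""]
        rows.append(
            {
                "name": rec.display_name,
                "female_parent": names[0],
                "male_parent": names[1],
                "year": "" if rec.year is None else rec.year,
                "country": rec.country or "",
                "breeder": rec.breeder or "",
                "species_tag": rec.species_tag or "",
                "synonyms": "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_dataset(
    outdir: str | Path,
    graph: PedigreeGraph,
    matrix: DosageMatrix,
    truth: TruthSet,
    config: SimConfig | None = None,
) -> dict[str, Path]:
    """Emit the complete file set consumed by the pipeline CLI."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": outdir / "pedigree.tsv",
        "curated": outdir / "curated_graph.tsv",
        "dosage": outdir / "dosage.tsv",
        "annotation": outdir / "snp_annotation.tsv",
        "sample_map": outdir / "sample_map.tsv",
        "truth": outdir / "truth.json",
    }
    write_raw_pedigree(graph, paths["pedigree"])
    graph.to_tsv(paths["curated"])
    matrix.to_tsv(paths["dosage"], paths["annotation"])
    pd.DataFrame(
        {
            "sample_id": matrix.samples,
            "pedigree_name": matrix.samples,
        }
    ).to_csv(paths["sample_map"], sep="\t", index=False)
    truth.to_json(paths["truth"])
    if config is not None:
        (outdir / "sim_config.json").write_text(
            json.dumps(asdict(config), default=list, indent=1)
        )
    return paths
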