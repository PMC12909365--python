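"""Curation and graph representation of crop breeding pedigrees.

A pedigree table lists one variety per row with up to two named parents.
Historical records are messy: the same display name can denote several
distinct cultivars, parents may be recorded only as "seedling of X" or
"unknown", and intermediate hybrids appear as "A x B". Curation resolves
duplicate parent names by release date where possible, routes unresolvable
references to dummy placeholder nodes (``NAME_?``), and drops
non-variety names from the node set.

The curated pedigree is a directed acyclic multigraph with edges pointing
child -> parent (the direction in which contribution scores flow). A
self-cross is recorded as a parallel edge pair to the same parent.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "VarietyRecord",
    "PedigreeGraph",
    "PedigreeError",
    "CycleError",
    "FocalSelection",
    "CountryStats",
    "parse_pedigree",
    "select_focal_set",
    "missing_parentage_by_period",
    "recent_ancestor_country_stats",
    "normalize_country",
    "EUROPEAN_COUNTRIES",
]


class PedigreeError(ValueError):
    """Malformed pedigree input."""


class CycleError(PedigreeError):
    """The pedigree contains a directed cycle (a variety is its own ancestor)."""


#: Substrings that mark a name as a non-variety placeholder. " x " denotes an
#: undocumented intermediate hybrid between two varieties.
_EXCLUDED_SUBSTRINGS = ("unknown", "seedling")
_HYBRID_RE = re.compile(r" x( |$)", re.IGNORECASE)

#: Parent-name substrings counted as unknown parentage in the missing-data census.
_UNKNOWN_PARENT_SUBSTRINGS = ("unknown", "?", "variety", "seedling")


def _is_excluded_name(name: str) -> bool:
    low = name.lower()
    if any(s in low for s in _EXCLUDED_SUBSTRINGS):
        return True
    return bool(_HYBRID_RE.search(name))


def _is_unknown_parent_name(name: str) -> bool:
    low = name.lower()
    return any(s in low for s in _UNKNOWN_PARENT_SUBSTRINGS)


@dataclass(frozen=True)
class VarietyRecord:
    """One curated pedigree entry.

    ``parent_refs`` holds the resolved parent unique ids with multiplicity
    (a self-cross lists the same id twice); unresolved slots are simply
    absent. ``parent_names`` preserves the raw strings from the input table,
    which the missing-parentage census needs.
    """

    unique_id: str
    display_name: str
    parent_refs: tuple[str, ...] = ()
    parent_names: tuple[str, str] = ("", "")
    year: int | None = None
    country: str | None = None
    breeder: str | None = None
    species_tag: str | None = None
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(self.parent_refs) > 2:
            raise PedigreeError(
                f"{self.unique_id}: more than two parent references"
            )
        if "dummy" in self.flags and self.parent_refs:
            raise PedigreeError(f"dummy node {self.unique_id} cannot have parents")

    @property
    def is_dummy(self) -> bool:
        return "dummy" in self.flags


class PedigreeGraph:
    """Directed child->parent multigraph over curated :class:`VarietyRecord` s."""

    def __init__(self, records: Iterable[VarietyRecord]):
        self.records: dict[str, VarietyRecord] = {}
        self.graph = nx.MultiDiGraph()
        for rec in records:
            if rec.unique_id in self.records:
                raise PedigreeError(f"duplicate unique_id {rec.unique_id}")
            self.records[rec.unique_id] = rec
            self.graph.add_node(rec.unique_id)
        for rec in self.records.values():
            for p in rec.parent_refs:
                if p not in self.records:
                    raise PedigreeError(
                        f"{rec.unique_id}: parent {p} is not a graph node"
                    )
                self.graph.add_edge(rec.unique_id, p)
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise CycleError(
                f"pedigree contains a cycle through {cycle[0][0]}"
            )

    # -- basic accessors ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, unique_id: str) -> bool:
        return unique_id in self.records

    def __iter__(self):
        return iter(self.records)

    def parents(self, unique_id: str) -> list[str]:
        """Parent ids with multiplicity (self-cross appears twice)."""
        return [p for _, p in self.graph.out_edges(unique_id)]

    def children(self, unique_id: str) -> list[str]:
        """Distinct immediate descendants."""
        return sorted({c for c, _ in self.graph.in_edges(unique_id)})

    def n_offspring(self, unique_id: str) -> int:
        return len(self.children(unique_id))

    def topological_order(self) -> list[str]:
        """Nodes ordered children before parents (score-flow order).

        Lexicographic tie-breaking keeps the order independent of
        insertion order.
        """
        return list(nx.lexicographical_topological_sort(self.graph))

    @property
    def dummy_ids(self) -> set[str]:
        return {u for u, r in self.records.items() if r.is_dummy}

    def by_name(self, display_name: str) -> list[VarietyRecord]:
        return [r for r in self.records.values() if r.display_name == display_name]

    # -- serialization -----------------------------------------------------
    _TSV_COLUMNS = [
        "unique_id",
        "name",
        "female_parent",
        "male_parent",
        "year",
        "country",
        "breeder",
        "species_tag",
        "flags",
        "raw_female_parent",
        "raw_male_parent",
    ]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records.values():
            refs = list(rec.parent_refs) + [None, None]
            rows.append(
                {
                    "unique_id": rec.unique_id,
                    "name": rec.display_name,
                    "female_parent": refs[0] or "",
                    "male_parent": refs[1] or "",
                    "year": "" if rec.year is None else rec.year,
                    "country": rec.country or "",
                    "breeder": rec.breeder or "",
                    "species_tag": rec.species_tag or "",
                    "flags": ";".join(sorted(rec.flags)),
                    "raw_female_parent": rec.parent_names[0],
                    "raw_male_parent": rec.parent_names[1],
                }
            )
        return pd.DataFrame(rows, columns=self._TSV_COLUMNS)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PedigreeGraph":
        """Load a previously exported curated graph verbatim (no re-curation)."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        records = []
        for _, row in df.iterrows():
            refs = tuple(p for p in (row["female_parent"], row["male_parent"]) if p)
            records.append(
                VarietyRecord(
                    unique_id=row["unique_id"],
                    display_name=row["name"],
                    parent_refs=refs,
                    parent_names=(
                        row.get("raw_female_parent", ""),
                        row.get("raw_male_parent", ""),
                    ),
                    year=int(row["year"]) if row["year"] else None,
                    country=row["country"] or None,
                    breeder=row["breeder"] or None,
                    species_tag=row["species_tag"] or None,
                    flags=frozenset(f for f in row["flags"].split(";") if f),
                )
            )
        return cls(records)

    def to_dot(self, path: str | Path, node_ids: set[str] | None = None) -> None:
        """Write a DOT rendering of the graph (or an induced subgraph)."""
        sub = self.graph if node_ids is None else self.graph.subgraph(node_ids)
        lines = ["digraph pedigree {"]
        for n in sub.nodes:
            rec = self.records[n]
            shape = "box" if rec.is_dummy else "ellipse"
            lines.append(f'  "{n}" [label="{rec.display_name}", shape={shape}];')
        for u, v in sub.edges():
            lines.append(f'  "{u}" -> "{v}";')
        lines.append("}")
        Path(path).write_text("\n".join(lines) + "\n")

    def to_graphml(self, path: str | Path, node_ids: set[str] | None = None) -> None:
        sub = self.graph if node_ids is None else self.graph.subgraph(node_ids)
        g = nx.MultiDiGraph()
        for n in sub.nodes:
            rec = self.records[n]
            g.add_node(
                n,
                name=rec.display_name,
                year=-1 if rec.year is None else rec.year,
                dummy=rec.is_dummy,
            )
        g.add_edges_from(sub.edges())
        nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# Parsing and curation
# ---------------------------------------------------------------------------

_INPUT_COLUMNS = ("name", "female_parent", "male_parent")


def _parse_year(text: str, row_no: int, errors: list[str]) -> int | None:
    text = text.strip()
    if not text:
        return None
    # tolerate "<1961", "ca. 1900" style annotations
    m = re.search(r"(\d{4})", text)
    if m is None:
        errors.append(f"row {row_no}: unparseable year {text!r}")
        return None
    return int(m.group(1))


def parse_pedigree(
    path: str | Path,
    synonym_table: Mapping[str, str] | None = None,
) -> PedigreeGraph:
    """Parse and curate a raw pedigree table into a :class:`PedigreeGraph`.

    The input is a UTF-8 TSV with columns ``name, female_parent,
    male_parent, year, country, breeder, species_tag, synonyms`` (header
    required; blank fields mean unknown; ``synonyms`` is
    semicolon-separated). Curation applies, in order:

    1. synonym collapse (explicit ``synonym_table`` plus the ``synonyms``
       column) to canonical names;
    2. exclusion of placeholder names containing ``unknown``, ``seedling``
       or the hybrid marker `` x`` — such varieties are dropped from the
       node set and, as parents, treated as missing;
    3. duplicate display names kept as distinct records under unique ids
       ``<NAME>_<n>`` (``n`` = file order);
    4. parent resolution: a unique name resolves directly; among duplicate
       candidates only those released no later than the child are
       admissible, and a unique admissible candidate resolves, otherwise
       the slot points at a dummy ``<NAME>_?`` node;
    5. parents never listed as rows become implicit founder records.

    Cycles are a hard error. Row-level problems are collected on the
    returned graph as ``graph.curation_log`` rather than aborting the parse.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "name" not in reader.fieldnames:
            raise PedigreeError(f"{path}: missing header with 'name' column")
        raw_rows = list(reader)

    errors: list[str] = []
    synonyms: dict[str, str] = dict(synonym_table or {})
    rows: list[dict] = []
    for i, row in enumerate(raw_rows, start=2):  # header is line 1
        if row.get("name") is None or not row["name"].strip():
            errors.append(f"row {i}: blank variety name")
            continue
        if None in row.values():
            errors.append(f"row {i}: too few columns")
            continue
        name = row["name"].strip()
        for syn in (row.get("synonyms") or "").split(";"):
            syn = syn.strip()
            if syn and syn != name:
                synonyms[syn] = name
        rows.append({**row, "_row_no": i, "name": name})

    def canon(name: str) -> str:
        seen = {name}
        while name in synonyms and synonyms[name] not in seen:
            name = synonyms[name]
            seen.add(name)
        return name

    # First pass: materialise records (excluded names flagged, not nodes).
    serial = 0
    by_name: dict[str, list[dict]] = {}
    entries: list[dict] = []
    for row in rows:
        name = canon(row["name"])
        serial += 1
        entry = {
            "unique_id": f"{name.upper()}_{serial}",
            "name": name,
            "row": row,
            "year": _parse_year(row.get("year", ""), row["_row_no"], errors),
            "excluded": _is_excluded_name(name),
        }
        entries.append(entry)
        by_name.setdefault(name, []).append(entry)

    duplicate_names = {n for n, es in by_name.items() if len(es) > 1}

    dummy_records: dict[str, VarietyRecord] = {}
    implicit: dict[str, dict] = {}
    curation_log: list[str] = list(errors)

    def dummy_for(name: str) -> str:
        uid = f"{name.upper()}_?"
        if uid not in dummy_records:
            dummy_records[uid] = VarietyRecord(
                unique_id=uid,
                display_name=f"{name}_?",
                flags=frozenset({"dummy", "unresolved_duplicate"}),
            )
            curation_log.append(f"created dummy node {uid}")
        return uid

    def implicit_founder(name: str) -> str:
        if name not in implicit:
            nonlocal serial
            serial += 1
            implicit[name] = {
                "unique_id": f"{name.upper()}_{serial}",
                "name": name,
            }
        return implicit[name]["unique_id"]

    def resolve_parent(raw: str, child: dict) -> str | None:
        raw = raw.strip()
        if not raw:
            return None
        name = canon(raw)
        if _is_excluded_name(name):
            return None  # placeholder parent -> missing slot
        candidates = by_name.get(name, ())
        candidates = [c for c in candidates if not c["excluded"]]
        if not candidates:
            return implicit_founder(name)
        if len(candidates) == 1:
            return candidates[0]["unique_id"]
        admissible = candidates
        if child["year"] is not None:
            dated = [
                c for c in candidates
                if c["year"] is not None and c["year"] <= child["year"]
            ]
            if dated:
                admissible = dated
        if len(admissible) == 1:
            curation_log.append(
                f"{child['unique_id']}: parent {name!r} resolved to "
                f"{admissible[0]['unique_id']} by release date"
            )
            return admissible[0]["unique_id"]
        return dummy_for(name)

    records: list[VarietyRecord] = []
    for entry in entries:
        if entry["excluded"]:
            curation_log.append(
                f"excluded {entry['unique_id']} (placeholder name)"
            )
            continue
        row = entry["row"]
        raw_f = (row.get("female_parent") or "").strip()
        raw_m = (row.get("male_parent") or "").strip()
        refs = tuple(
            r for r in (resolve_parent(raw_f, entry), resolve_parent(raw_m, entry))
            if r is not None
        )
        flags = set()
        if entry["name"] in duplicate_names:
            flags.add("unresolved_duplicate")
        records.append(
            VarietyRecord(
                unique_id=entry["unique_id"],
                display_name=entry["name"],
                parent_refs=refs,
                parent_names=(raw_f, raw_m),
                year=entry["year"],
                country=(row.get("country") or "").strip() or None,
                breeder=(row.get("breeder") or "").strip() or None,
                species_tag=(row.get("species_tag") or "").strip() or None,
                flags=frozenset(flags),
            )
        )

    for name, info in implicit.items():
        records.append(
            VarietyRecord(unique_id=info["unique_id"], display_name=name)
        )
        curation_log.append(f"implicit founder {info['unique_id']}")
    records.extend(dummy_records.values())

    graph = PedigreeGraph(records)
    graph.curation_log = curation_log  # type: ignore[attr-defined]
    return graph


# ---------------------------------------------------------------------------
# Focal-set selection
# ---------------------------------------------------------------------------

@dataclass
class FocalSelection:
    """Result of matching a catalogue of variety names against the pedigree."""

    ids: set[str]
    matched: list[str]
    unmatched: list[str]
    dropped_duplicates: list[str]
    dropped_synonyms: list[str]

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(self.ids)


def select_focal_set(
    graph: PedigreeGraph,
    catalogue_names: Sequence[str],
    drop_duplicates: bool = True,
    synonym_drops: Sequence[str] = (),
) -> FocalSelection:
    """Match catalogue names to pedigree records to form the focal variety set.

    Names matching several records (unresolved duplications) are dropped
    when ``drop_duplicates`` is set, as are names listed in
    ``synonym_drops`` (catalogue entries known to be synonyms of another
    catalogue entry).
    """
    if not catalogue_names:
        raise PedigreeError("catalogue_names must be nonempty")
    drops = set(synonym_drops)
    index: dict[str, list[VarietyRecord]] = {}
    for rec in graph.records.values():
        if rec.is_dummy:
            continue
        index.setdefault(rec.display_name, []).append(rec)

    ids: set[str] = set()
    matched, unmatched, dup_dropped, syn_dropped = [], [], [], []
    for name in catalogue_names:
        if name in drops:
            syn_dropped.append(name)
            continue
        hits = index.get(name, [])
        if not hits:
            unmatched.append(name)
        elif len(hits) > 1 and drop_duplicates:
            dup_dropped.append(name)
        else:
            ids.add(hits[0].unique_id)
            matched.append(name)
    if not ids:
        import warnings

        warnings.warn("no catalogue names matched the pedigree", stacklevel=2)
    return FocalSelection(ids, matched, unmatched, dup_dropped, syn_dropped)


# ---------------------------------------------------------------------------
# Missing-parentage census
# ---------------------------------------------------------------------------

def missing_parentage_by_period(
    graph: PedigreeGraph, bin_width: int = 20
) -> pd.DataFrame:
    """Count unknown parent slots per release-year period.

    A parent slot is unknown if the raw recorded name contains "unknown",
    "?", "variety" or "seedling"; a record with entirely blank parentage
    contributes two unknown slots, and a single blank slot one. Records
    without a release year are pooled into their own row (period = NA).
    """
    if bin_width <= 0:
        raise PedigreeError("bin_width must be positive")
    rows: dict[object, list[int]] = {}
    for rec in graph.records.values():
        if rec.is_dummy:
            continue
        period: object
        if rec.year is None:
            period = pd.NA
        else:
            period = (rec.year // bin_width) * bin_width
        f, m = rec.parent_names
        if not f.strip() and not m.strip():
            unknown = 2
        else:
            unknown = sum(
                1
                for raw in (f, m)
                if not raw.strip() or _is_unknown_parent_name(raw)
            )
        bucket = rows.setdefault(period, [0, 0])
        bucket[0] += 1
        bucket[1] += unknown

    def sort_key(p):
        return (1, 0) if p is pd.NA else (0, p)

    out = pd.DataFrame(
        [
            {"period_start": p, "n_records": v[0], "unknown_parent_slots": v[1]}
            for p, v in sorted(rows.items(), key=lambda kv: sort_key(kv[0]))
        ]
    )
    return out


# ---------------------------------------------------------------------------
# Country-of-origin ancestor statistics
# ---------------------------------------------------------------------------

#: Raw country codes normalised to one label. Germany appears in the sources
#: under pre- and post-reunification codes.
COUNTRY_ALIASES: dict[str, str] = {
    "BDR": "Germany",
    "DDR": "Germany",
    "GER": "Germany",
    "DEU": "Germany",
    "DE": "Germany",
    "NL": "Netherlands",
    "NLD": "Netherlands",
    "GB": "Great Britain",
    "GBR": "Great Britain",
    "UK": "Great Britain",
    "IRL": "Ireland",
    "FRA": "France",
    "FR": "France",
    "USA": "USA",
    "US": "USA",
    "RUS": "Russia",
    "POL": "Poland",
    "CZE": "Czechia",
    "AUT": "Austria",
    "CHE": "Switzerland",
    "DNK": "Denmark",
    "SWE": "Sweden",
    "ESP": "Spain",
    "ITA": "Italy",
    "BEL": "Belgium",
    "HUN": "Hungary",
}

#: Continental Europe + British Isles + Russia.
EUROPEAN_COUNTRIES: frozenset[str] = frozenset(
    {
        "Germany", "Netherlands", "Great Britain", "Ireland", "France",
        "Russia", "Poland", "Czechia", "Austria", "Switzerland", "Denmark",
        "Sweden", "Norway", "Finland", "Spain", "Italy", "Belgium",
        "Hungary", "Portugal", "Estonia", "Latvia", "Lithuania", "Slovakia",
        "Slovenia", "Romania", "Bulgaria", "Greece", "Croatia", "Ukraine",
        "Belarus",
    }
)


def normalize_country(code: str | None) -> str | None:
    if code is None:
        return None
    code = code.strip()
    if not code:
        return None
    return COUNTRY_ALIASES.get(code, code)


_DIGIT_RE = re.compile(r"\d")

#: Marketed cultivars whose names contain digits but are not breeding lines.
DIGIT_NAME_EXCEPTIONS = frozenset({"7 FOUR 7"})


def _is_breeding_line_name(name: str) -> bool:
    return bool(_DIGIT_RE.search(name)) and name not in DIGIT_NAME_EXCEPTIONS


@dataclass
class CountryStats:
    """Per-slot ancestor records and their per-country summary.

    ``slots`` has one row per counted recent-ancestor slot (parent or
    grandparent, multiplicity included); ``by_country`` aggregates to
    same-country fractions per focal country.
    """

    slots: pd.DataFrame
    by_country: pd.DataFrame

    def european_fraction(self) -> float:
        """Fraction of counted ancestor slots of European focal varieties
        that are themselves European."""
        s = self.slots[self.slots["focal_country"].isin(EUROPEAN_COUNTRIES)]
        if s.empty:
            return float("nan")
        return float(s["ancestor_country"].isin(EUROPEAN_COUNTRIES).mean())


def recent_ancestor_country_stats(
    graph: PedigreeGraph,
    focal_filter: Callable[[VarietyRecord], bool] | None = None,
    min_year: int = 1900,
    exclude_digit_names: bool = True,
) -> CountryStats:
    """Same-country fractions of recent ancestors (parents + grandparents).

    The default focal set is every non-dummy variety released after
    ``min_year`` with a known country and a name free of digits (breeding
    lines use coded names); digit-named ancestors are likewise skipped.
    Each focal variety contributes up to six slots — two parents and four
    grandparents, multiplicity counted — restricted to ancestors with a
    known country. ``exclude_digit_names=False`` disables the
    breeding-line heuristic for datasets whose names are all coded.
    """

    def default_filter(rec: VarietyRecord) -> bool:
        return (
            not rec.is_dummy
            and rec.year is not None
            and rec.year > min_year
            and rec.country is not None
            and not (
                exclude_digit_names
                and _is_breeding_line_name(rec.display_name)
            )
        )

    focal_filter = focal_filter or default_filter
    slot_rows = []
    for rec in graph.records.values():
        if not focal_filter(rec):
            continue
        fc = normalize_country(rec.country)
        if fc is None:
            continue
        ancestors: list[tuple[str, int]] = []  # (ancestor id, degree)
        for p in graph.parents(rec.unique_id):
            ancestors.append((p, 1))
            for gp in graph.parents(p):
                ancestors.append((gp, 2))
        for aid, degree in ancestors:
            arec = graph.records[aid]
            if arec.is_dummy or (
                exclude_digit_names
                and _is_breeding_line_name(arec.display_name)
            ):
                continue
            ac = normalize_country(arec.country)
            if ac is None:
                continue
            slot_rows.append(
                {
                    "focal_id": rec.unique_id,
                    "focal_country": fc,
                    "ancestor_id": aid,
                    "ancestor_country": ac,
                    "degree": degree,
                }
            )
    slots = pd.DataFrame(
        slot_rows,
        columns=["focal_id", "focal_country", "ancestor_id", "ancestor_country", "degree"],
    )
    if slots.empty:
        by_country = pd.DataFrame(
            columns=["country", "slots_total", "slots_same_country", "fraction"]
        )
    else:
        grouped = slots.assign(
            same=slots["focal_country"] == slots["ancestor_country"]
        ).groupby("focal_country")
        by_country = (
            grouped["same"]
            .agg(slots_total="size", slots_same_country="sum")
            .reset_index()
            .rename(columns={"focal_country": "country"})
        )
        by_country["fraction"] = (
            by_country["slots_same_country"] / by_country["slots_total"]
        )
        by_country = by_country.sort_values(
            "slots_total", ascending=False, ignore_index=True
        )
    return CountryStats(slots=slots, by_country=by_country)
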