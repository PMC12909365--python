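"""Curation rules, focal-set selection and descriptive pedigree statistics."""

from __future__ import annotations

import textwrap

import networkx as nx
import pandas as pd
import pytest

from mcatrace.pedigree import (
    CycleError,
    PedigreeGraph,
    parse_pedigree,
    select_focal_set,
    missing_parentage_by_period,
    recent_ancestor_country_stats,
    normalize_country,
)

from conftest import make_graph


HEADER = "name\tfemale_parent\tmale_parent\tyear\tcountry\tbreeder\tspecies_tag\tsynonyms"


def write_pedigree(tmp_path, rows: list[str]):
    path = tmp_path / "pedigree.tsv"
    path.write_text(HEADER + "\n" + "\n".join(rows) + "\n")
    return path


class TestParseCuration:
    def test_simple_trio(self, tmp_path):
        path = write_pedigree(
            tmp_path,
            ["A\tB\tC\t1950\t\t\t\t", "B\t\t\t1920\t\t\t\t", "C\t\t\t1930\t\t\t\t"],
        )
        g = parse_pedigree(path)
        assert len(g) == 3
        assert g.graph.number_of_edges() == 2
        (a,) = g.by_name("A")
        assert {g.records[p].display_name for p in a.parent_refs} == {"B", "C"}

    def test_duplicate_parent_resolved_by_release_date(self, tmp_path):
        # two records share the name Vera; the child's release year admits
        # only the older one
        path = write_pedigree(
            tmp_path,
            [
                "Vera\t\t\t1943\t\t\t\t",
                "Ada\tSaskia\tVera\t1962\t\t\t\t",
                "Vera\t\t\t1995\t\t\t\t",
                "Saskia\t\t\t1946\t\t\t\t",
            ],
        )
        g = parse_pedigree(path)
        (ada,) = g.by_name("Ada")
        resolved = {g.records[p].display_name for p in ada.parent_refs}
        assert resolved == {"Saskia", "Vera"}
        vera_parent = next(
            p for p in ada.parent_refs if g.records[p].display_name == "Vera"
        )
        assert g.records[vera_parent].year == 1943

    def test_unresolvable_duplicate_parent_goes_to_dummy(self, tmp_path):
        path = write_pedigree(
            tmp_path,
            [
                "White Rose\t\t\t1871\t\t\t\t",
                "White Rose\t\t\t1893\t\t\t\t",
                "Child\tWhite Rose\t\t1990\t\t\t\t",
            ],
        )
        g = parse_pedigree(path)
        (child,) = g.by_name("Child")
        (ref,) = child.parent_refs
        assert ref == "WHITE ROSE_?"
        rec = g.records[ref]
        assert rec.is_dummy
        assert "unresolved_duplicate" in rec.flags
        assert not rec.parent_refs
        assert g.children(ref) == [child.unique_id]

    @pytest.mark.parametrize(
        "bad_name",
        ["unknown variety", "seedling of Katahdin", "Alpha x Beta", "Trailing x"],
    )
    def test_placeholder_names_excluded(self, tmp_path, bad_name):
        path = write_pedigree(
            tmp_path,
            [f"A\t{bad_name}\tB\t1950\t\t\t\t", "B\t\t\t1920\t\t\t\t"],
        )
        g = parse_pedigree(path)
        assert not g.by_name(bad_name)
        (a,) = g.by_name("A")
        # the placeholder parent slot is simply missing
        assert [g.records[p].display_name for p in a.parent_refs] == ["B"]

    def test_x_exclusion_needs_word_boundary(self, tmp_path):
        path = write_pedigree(tmp_path, ["Axminster\t\t\t1950\t\t\t\t"])
        g = parse_pedigree(path)
        assert g.by_name("Axminster")

    def test_synonyms_collapse_to_canonical(self, tmp_path):
        path = write_pedigree(
            tmp_path,
            [
                "Alpha\t\t\t1950\t\t\t\tAlfa;Alpha One",
                "Child\tAlfa\t\t1980\t\t\t\t",
            ],
        )
        g = parse_pedigree(path)
        (child,) = g.by_name("Child")
        (ref,) = child.parent_refs
        assert g.records[ref].display_name == "Alpha"

    def test_unlisted_parent_becomes_implicit_founder(self, tmp_path):
        path = write_pedigree(tmp_path, ["A\tGhost\t\t1950\t\t\t\t"])
        g = parse_pedigree(path)
        (ghost,) = g.by_name("Ghost")
        assert not ghost.parent_refs

    def test_cycle_is_hard_error(self, tmp_path):
        path = write_pedigree(
            tmp_path,
            ["A\tB\t\t\t\t\t\t", "B\tA\t\t\t\t\t\t"],
        )
        with pytest.raises(CycleError):
            parse_pedigree(path)

    def test_malformed_row_logged_not_fatal(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text(HEADER + "\n\tB\tC\t1950\t\t\t\t\nB\t\t\t1920\t\t\t\t\n")
        g = parse_pedigree(path)
        assert any("row 2" in e for e in g.curation_log)
        assert g.by_name("B")

    def test_serialized_graph_round_trips(self, tmp_path):
        path = write_pedigree(
            tmp_path,
            [
                "Vera\t\t\t1943\t\t\t\t",
                "Vera\t\t\t1995\t\t\t\t",
                "Ada\tSaskia\tVera\t1962\tNL\t\t\t",
                "Saskia\tAda x B\tunknown\t1946\tNL\t\t\t",
            ],
        )
        g = parse_pedigree(path)
        out = tmp_path / "curated.tsv"
        g.to_tsv(out)
        g2 = PedigreeGraph.from_tsv(out)
        assert set(g2.records) == set(g.records)
        assert g2.records == g.records
        out2 = tmp_path / "curated2.tsv"
        g2.to_tsv(out2)
        assert out.read_text() == out2.read_text()


class TestGraphInvariants:
    def test_curated_graph_is_dag_and_dummies_are_leaf_parents(self, sim_dataset):
        _, graph, _, _ = sim_dataset
        assert nx.is_directed_acyclic_graph(graph.graph)
        for d in graph.dummy_ids:
            assert not graph.parents(d)
            assert graph.children(d)

    def test_simulated_pedigree_parses_cleanly(self, tmp_path, sim_dataset):
        from mcatrace.simulate import write_raw_pedigree

        _, graph, _, _ = sim_dataset
        path = tmp_path / "raw.tsv"
        write_raw_pedigree(graph, path)
        g2 = parse_pedigree(path)
        assert nx.is_directed_acyclic_graph(g2.graph)
        # same number of non-dummy varieties survives curation
        real = [r for r in g2.records.values() if not r.is_dummy]
        assert len(real) == len(graph)
        assert not any("row" in e for e in g2.curation_log)


class TestFocalSelection:
    def test_matching_and_duplicate_drop(self, tmp_path):
        path = write_pedigree(
            tmp_path,
            [
                "Kata\t\t\t1930\t\t\t\t",
                "Dup\t\t\t1940\t\t\t\t",
                "Dup\t\t\t1960\t\t\t\t",
            ],
        )
        g = parse_pedigree(path)
        sel = select_focal_set(g, ["Kata", "Dup", "Absent"])
        assert len(sel.ids) == 1
        assert sel.matched == ["Kata"]
        assert sel.unmatched == ["Absent"]
        assert sel.dropped_duplicates == ["Dup"]

    def test_synonym_drops_removed(self, tmp_path):
        path = write_pedigree(tmp_path, ["Kata\t\t\t1930\t\t\t\t"])
        g = parse_pedigree(path)
        with pytest.warns(UserWarning):
            sel = select_focal_set(g, ["Kata"], synonym_drops=["Kata"])
        assert not sel.ids and sel.dropped_synonyms == ["Kata"]

    def test_no_match_warns_and_returns_empty(self, tmp_path):
        path = write_pedigree(tmp_path, ["Kata\t\t\t1930\t\t\t\t"])
        g = parse_pedigree(path)
        with pytest.warns(UserWarning):
            sel = select_focal_set(g, ["Nothing"])
        assert not sel.ids


class TestMissingParentage:
    def test_slot_counting(self, tmp_path):
        path = write_pedigree(
            tmp_path,
            [
                "A\t\t\t1905\t\t\t\t",  # blank parentage -> 2 unknown
                "B\tSaskia\tunknown seedling\t1910\t\t\t\t",  # 1 unknown
                "C\tSaskia\tKata\t1912\t\t\t\t",  # 0 unknown
                "Saskia\t\t\t1880\t\t\t\t",
                "Kata\t\t\t1880\t\t\t\t",
            ],
        )
        g = parse_pedigree(path)
        table = missing_parentage_by_period(g, bin_width=20)
        row1900 = table[table["period_start"] == 1900].iloc[0]
        assert row1900["n_records"] == 3
        assert row1900["unknown_parent_slots"] == 3
        row1880 = table[table["period_start"] == 1880].iloc[0]
        assert row1880["unknown_parent_slots"] == 4

    def test_unknown_year_records_form_own_bin(self, tmp_path):
        path = write_pedigree(tmp_path, ["A\t\t\t\t\t\t\t"])
        g = parse_pedigree(path)
        table = missing_parentage_by_period(g)
        assert len(table) == 1
        assert pd.isna(table["period_start"].iloc[0])

    def test_bin_width_must_be_positive(self, sim_dataset):
        _, graph, _, _ = sim_dataset
        with pytest.raises(Exception):
            missing_parentage_by_period(graph, bin_width=0)


class TestCountryStats:
    def test_same_country_parents(self):
        g = make_graph(
            {"A": ("Pa", "Pb"), "Pa": (), "Pb": ()},
            years={"A": 1950, "Pa": 1900, "Pb": 1900},
            countries={"A": "Germany", "Pa": "Germany", "Pb": "Germany"},
        )
        stats = recent_ancestor_country_stats(g)
        row = stats.by_country.iloc[0]
        assert row["country"] == "Germany"
        assert row["slots_total"] == 2
        assert row["fraction"] == 1.0

    def test_breeding_line_names_excluded(self):
        g = make_graph(
            {"AM 66-42": ("P1",), "P1": ()},
            years={"AM 66-42": 1966, "P1": 1900},
            countries={"AM 66-42": "Netherlands", "P1": "Netherlands"},
        )
        stats = recent_ancestor_country_stats(g)
        assert stats.slots.empty

    def test_country_aliases_normalize_to_germany(self):
        assert normalize_country("BDR") == "Germany"
        assert normalize_country("DDR") == "Germany"
        assert normalize_country("GER") == "Germany"

    def test_slots_partition_no_double_count(self, sim_dataset):
        _, graph, _, _ = sim_dataset
        # simulated names are coded, so disable the digit heuristic
        stats = recent_ancestor_country_stats(graph, exclude_digit_names=False)
        assert len(stats.slots) > 0
        assert stats.by_country["slots_total"].sum() == len(stats.slots)
        # at most 2 parent + 4 grandparent slots per focal variety
        per_focal = stats.slots.groupby("focal_id").size()
        assert (per_focal <= 6).all()
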