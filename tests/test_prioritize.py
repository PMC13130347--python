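"""Category solving, priority levelling (5 - k rule) and coverage audit."""

from __future__ import annotations

import pytest

from covergap.model import AnalysisConfig, IncidencePair
from covergap.prioritize import (
    CATEGORIES,
    category_subsets,
    coverage_audit,
    priority_levels,
    solve_categories,
)
from tests.conftest import make_species


def test_category_subsets_partition_by_flags(toy_species):
    subs = category_subsets(toy_species)
    assert subs["all"] == {"A", "B", "C"}
    assert subs["endemic"] == {"A"}
    assert subs["threatened"] == {"A", "B"}
    assert subs["protected"] == {"C"}


class TestPriorityLevels:
    def test_four_identical_lists_all_level_one(self, config):
        sols = {c: [10, 11] for c in CATEGORIES}
        df = priority_levels(sols, config)
        assert (df["k"] == 4).all()
        assert (df["raw_level"] == 1).all()
        assert (df["display_level"] == 1).all()

    def test_membership_counts_and_relabel(self, config):
        sols = {"all": [1], "endemic": [1], "threatened": [1, 2], "protected": [3]}
        df = priority_levels(sols, config)
        assert df.loc[1, "k"] == 3 and df.loc[2, "k"] == 1 and df.loc[3, "k"] == 1
        # raw 5-k levels: 2, 4, 4; relabeled to consecutive display levels 1, 2, 2
        assert df["raw_level"].tolist() == [2, 4, 4]
        assert df["display_level"].tolist() == [1, 2, 2]
        assert df.loc[1, "categories"] == "all|endemic|threatened"

    def test_raw_levels_kept_without_relabel(self):
        cfg = AnalysisConfig(level_relabel=False)
        sols = {"all": [1], "endemic": [1], "threatened": [2], "protected": [2]}
        df = priority_levels(sols, cfg)
        assert df["display_level"].tolist() == df["raw_level"].tolist() == [3, 3]

    def test_relabeled_levels_order_isomorphic(self, config):
        sols = {"all": [1, 2, 3], "endemic": [1, 2], "threatened": [1], "protected": [9]}
        df = priority_levels(sols, config)
        by_raw = df.sort_values(["raw_level", "display_level"])
        assert by_raw["display_level"].is_monotonic_increasing

    def test_union_size_is_sum_over_levels(self, config):
        sols = {"all": [1, 2], "endemic": [2, 3], "threatened": [4], "protected": [1]}
        df = priority_levels(sols, config)
        assert len(df) == len({1, 2, 3, 4})
        assert df["display_level"].value_counts().sum() == len(df)

    def test_empty_solutions(self, config):
        assert priority_levels({c: [] for c in CATEGORIES}, config).empty


class TestSolveCategories:
    @pytest.fixture
    def tiny_world(self):
        species = [
            make_species("A", endemic=True, threat="VU", protection="II"),
            make_species("B", endemic=True),
            make_species("C", threat="EN"),
            make_species("D", protection="I"),
        ]
        pairs = [
            IncidencePair("A", 1),
            IncidencePair("B", 1),
            IncidencePair("B", 2),
            IncidencePair("C", 2),
            IncidencePair("D", 3),
        ]
        return species, pairs

    def test_all_categories_certified(self, tiny_world, config):
        species, pairs = tiny_world
        res = solve_categories(pairs, species, config)
        assert set(res) == set(CATEGORIES)
        assert all(r.solution.optimal_certified for r in res.values())

    def test_single_species_category_is_its_cell(self, config):
        species = [
            make_species("A", endemic=True, threat="VU", protection="I"),
            make_species("B"),
        ]
        pairs = [IncidencePair("A", 7), IncidencePair("B", 8)]
        res = solve_categories(pairs, species, config)
        assert res["endemic"].solution.selected == (7,)
        assert res["all"].solution.selected == (7, 8)

    def test_empty_universe_category_is_error(self, config):
        species = [make_species("A")]  # nothing endemic/threatened/protected
        with pytest.raises(ValueError, match="endemic|threatened|protected"):
            solve_categories([IncidencePair("A", 1)], species, config)

    def test_audit_partitions_species(self, tiny_world, config):
        species, pairs = tiny_world
        species = species + [make_species("E")]  # no records at all
        res = solve_categories(pairs, species, config)
        report = coverage_audit(res, pairs, species)
        assert all(report.per_category_verified.values())
        covered = set(report.covered_species)
        excluded = set(report.excluded_species)
        assert excluded == {"E"}
        assert covered | excluded == {s.species_id for s in species}
        assert report.excluded_species["E"] == "no records in retained cells"

    def test_union_contains_each_category_list(self, tiny_world, config):
        species, pairs = tiny_world
        res = solve_categories(pairs, species, config)
        df = priority_levels({c: r.solution.selected for c, r in res.items()}, config)
        union = set(df.index)
        for r in res.values():
            assert set(r.solution.selected) <= union
        assert len(union) <= sum(len(r.solution.selected) for r in res.values())
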