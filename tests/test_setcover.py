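"""Set-cover core: greedy, reductions, exact solver vs. brute-force oracle."""

from __future__ import annotations

import math

import pytest

from covergap.model import IncidencePair, TieBreak
from covergap.setcover import (
    CoverInstance,
    brute_force_cover,
    exact_cover,
    greedy_cover,
    make_instance,
    reduce_instance,
    verify_cover,
)
from covergap.synthetic import gen_cover_instance, gen_planted_instance


def inst(universe, sets):
    return CoverInstance(frozenset(universe), {k: frozenset(v) for k, v in sets.items()})


# The classical instance where greedy overshoots: the big set S={1,2,3,4}
# looks best first, but the optimum is the two sets T1, T2.
GREEDY_TRAP = inst(
    "123456", {0: "1234", 1: "125", 2: "346"}
)


class TestInstanceBuilding:
    def test_uncoverable_species_split_out(self):
        pairs = [IncidencePair("A", 1), IncidencePair("B", 2)]
        instance, uncoverable = make_instance(pairs, {"A", "B", "C"})
        assert instance.universe == {"A", "B"}
        assert uncoverable == {"C"}

    def test_recordless_species_uncoverable(self):
        instance, uncoverable = make_instance([], {"X"})
        assert uncoverable == {"X"} and not instance.universe

    def test_invalid_instances_rejected(self):
        with pytest.raises(ValueError, match="uncoverable"):
            inst("ab", {0: "a"})
        with pytest.raises(ValueError, match="non-universe"):
            inst("a", {0: "ab"})

    def test_verify_cover(self):
        assert verify_cover(GREEDY_TRAP, [0, 1, 2])
        assert verify_cover(GREEDY_TRAP, [1, 2])
        assert not verify_cover(GREEDY_TRAP, [])
        assert not verify_cover(GREEDY_TRAP, [0])
        with pytest.raises(KeyError):
            verify_cover(GREEDY_TRAP, [99])


class TestGreedy:
    def test_single_set_instance(self):
        sol = greedy_cover(inst("ab", {5: "ab"}))
        assert sol.selected == (5,) and sol.is_cover

    def test_trap_instance_takes_three_sets(self):
        sol = greedy_cover(GREEDY_TRAP)
        assert sol.selected == (0, 1, 2)
        assert sol.newly_covered == (4, 1, 1)
        assert len(brute_force_cover(GREEDY_TRAP).selected) == 2

    def test_lowest_id_tie_break(self):
        i = inst("ab", {3: "ab", 1: "ab", 2: "a"})
        assert greedy_cover(i, TieBreak.LOWEST_ID).selected == (1,)

    def test_richness_tie_break(self):
        # sets 1 and 2 both add one uncovered element; set 2 is richer overall
        i = inst("abc", {0: "ab", 1: "c", 2: "bc"})
        sol = greedy_cover(i, TieBreak.HIGHEST_RICHNESS_THEN_LOWEST_ID)
        assert sol.selected == (0, 2)

    @pytest.mark.parametrize("seed", range(40))
    def test_greedy_always_covers_and_bounds_hold(self, seed):
        instance = gen_cover_instance(12, 10, 0.3, seed)
        g = greedy_cover(instance)
        b = brute_force_cover(instance)
        assert verify_cover(instance, g.selected)
        assert len(b.selected) <= len(g.selected)
        hmax = max(len(s) for s in instance.sets.values())
        harmonic = sum(1 / k for k in range(1, hmax + 1))
        assert len(g.selected) <= harmonic * len(b.selected) + 1e-9


class TestReductions:
    def test_essential_set_forced(self):
        i = inst("ab", {0: "a", 1: "ab"})
        reduced, forced, removed = reduce_instance(i)
        # only set 1 covers b after domination; in fact {a} is dominated first
        assert forced == {1}
        assert not reduced.universe

    def test_dominated_set_removed(self):
        i = inst("ab", {0: "a", 1: "ab", 2: "b"})
        reduced, forced, removed = reduce_instance(i)
        assert 0 in removed and 2 in removed
        assert forced == {1} and not reduced.universe

    def test_dominated_element_removed(self):
        # element b is covered by every set covering a (and more)
        i = inst("abc", {0: "ab", 1: "b", 2: "bc"})
        reduced, forced, removed = reduce_instance(i)
        total = len(forced) + len(brute_force_cover(reduced).selected) if reduced.universe else len(forced)
        assert total == len(brute_force_cover(i).selected)

    @pytest.mark.parametrize("seed", range(60))
    def test_reduction_preserves_optimum(self, seed):
        instance = gen_cover_instance(10, 9, 0.3, seed)
        reduced, forced, _ = reduce_instance(instance)
        opt_original = len(brute_force_cover(instance).selected)
        opt_reduced = (
            len(brute_force_cover(reduced).selected) if reduced.universe else 0
        )
        assert opt_original == len(forced) + opt_reduced


class TestExact:
    def test_empty_universe(self):
        sol = exact_cover(CoverInstance(frozenset(), {}))
        assert sol.selected == () and sol.optimal_certified

    def test_trap_instance_certified_two(self):
        sol = exact_cover(GREEDY_TRAP)
        assert sol.selected == (1, 2)
        assert sol.optimal_certified and sol.lower_bound == 2

    def test_canonical_lexicographic_choice(self):
        # two optima of size 1: sets 4 and 7 both equal the universe
        i = inst("ab", {7: "ab", 4: "ab"})
        assert exact_cover(i).selected == (4,)

    @pytest.mark.parametrize("backend", ["bnb", "milp"])
    @pytest.mark.parametrize("seed", range(30))
    def test_backends_match_brute_force(self, backend, seed):
        instance = gen_cover_instance(12, 10, 0.35, seed)
        e = exact_cover(instance, backend=backend)
        b = brute_force_cover(instance)
        assert e.optimal_certified
        assert verify_cover(instance, e.selected)
        assert len(e.selected) == len(b.selected)

    @pytest.mark.parametrize("seed", range(10))
    def test_deterministic_selection(self, seed):
        instance = gen_cover_instance(14, 12, 0.3, seed)
        assert exact_cover(instance).selected == exact_cover(instance).selected

    def test_budget_exhaustion_returns_uncertified_cover(self):
        instance = gen_cover_instance(30, 40, 0.15, 3)
        sol = exact_cover(instance, node_budget=1, backend="bnb")
        assert verify_cover(instance, sol.selected)
        assert not sol.optimal_certified

    def test_relabeling_invariance(self):
        instance = gen_cover_instance(10, 8, 0.35, 5)
        relabeled = CoverInstance(
            frozenset(f"x{e}" for e in instance.universe),
            {sid + 100: frozenset(f"x{e}" for e in m) for sid, m in instance.sets.items()},
        )
        assert len(exact_cover(instance).selected) == len(exact_cover(relabeled).selected)

    def test_monotone_under_set_removal(self):
        instance = gen_cover_instance(10, 8, 0.5, 2)
        full_opt = len(exact_cover(instance).selected)
        victim = max(
            instance.sets,
            key=lambda sid: len(instance.sets[sid]),
        )
        remaining = {k: v for k, v in instance.sets.items() if k != victim}
        still_covered = set().union(*remaining.values()) == set(instance.universe)
        if still_covered:
            smaller = CoverInstance(instance.universe, remaining)
            assert len(exact_cover(smaller).selected) >= full_opt


class TestPlanted:
    def test_single_planted_set(self):
        instance, planted = gen_planted_instance(1, 6, 3, 0)
        sol = exact_cover(instance)
        assert len(sol.selected) == 1 and sol.optimal_certified

    @pytest.mark.parametrize("seed", range(20))
    def test_planted_size_recovered(self, seed):
        instance, planted = gen_planted_instance(3, 12, 6, seed)
        e = exact_cover(instance)
        b = brute_force_cover(instance)
        assert e.optimal_certified
        assert len(e.selected) == len(b.selected) == 3

    @pytest.mark.parametrize("seed", range(10))
    def test_greedy_never_beats_exact_on_planted(self, seed):
        instance, _ = gen_planted_instance(4, 16, 8, seed)
        assert len(greedy_cover(instance).selected) >= len(exact_cover(instance).selected)


class TestBrute:
    def test_single_set(self):
        sol = brute_force_cover(inst("a", {3: "a"}))
        assert sol.selected == (3,) and sol.optimal_certified

    def test_size_limit(self):
        big = gen_cover_instance(5, 26, 0.9, 0)
        with pytest.raises(ValueError, match="exceeds"):
            brute_force_cover(big)
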