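"""Category-wise cover solving, priority levelling, and coverage auditing.

Four species categories are analysed: all species, endemics, threatened
species (CR/EN/VU) and nationally key protected species (class I/II). Each
category gets its own certified minimum set cover; the union of the four
optimal cell lists is the priority conservation area. A cell selected by k of
the four lists receives raw level ``5 - k``; because the top stratum can be
empty (no cell on all four lists), non-empty strata are additionally
renumbered consecutively from Level 1 (the display level), which is how the
levels are usually reported.

Minimum covers are generally non-unique: the four cardinalities are
reproducible, the particular cells (and hence the per-level counts) are only
guaranteed when the very same optimal lists are supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Set

import pandas as pd

from .model import AnalysisConfig, IncidencePair, Species
from .setcover import (
    CoverInstance,
    CoverSolution,
    exact_cover,
    greedy_cover,
    make_instance,
    verify_cover,
)

log = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "category_subsets",
    "CategoryResult",
    "solve_categories",
    "priority_levels",
    "coverage_audit",
    "CoverageReport",
]

CATEGORIES = ("all", "endemic", "threatened", "protected")


def category_subsets(species: Sequence[Species]) -> Dict[str, Set[str]]:
    """Species-id subsets for the four conservation categories."""
    return {
        "all": {s.species_id for s in species},
        "endemic": {s.species_id for s in species if s.is_endemic},
        "threatened": {s.species_id for s in species if s.is_threatened},
        "protected": {s.species_id for s in species if s.is_protected},
    }


@dataclass
class CategoryResult:
    category: str
    solution: CoverSolution
    instance: CoverInstance
    uncoverable: FrozenSet[str]


def solve_categories(
    pairs: Sequence[IncidencePair],
    species: Sequence[Species],
    config: AnalysisConfig,
    method: str = "exact",
    node_budget: int = 10_000_000,
) -> Dict[str, CategoryResult]:
    """One certified cover per category (``method`` = ``exact`` or ``greedy``)."""
    subsets = category_subsets(species)
    out: Dict[str, CategoryResult] = {}
    for cat in CATEGORIES:
        inst, uncoverable = make_instance(pairs, subsets[cat])
        if not inst.universe:
            raise ValueError(f"category {cat!r} has an empty coverable universe")
        if method == "exact":
            sol = exact_cover(inst, node_budget=node_budget)
        elif method == "greedy":
            sol = greedy_cover(inst, config.tie_break)
        else:
            raise ValueError(f"unknown cover method {method!r}")
        log.info(
            "solve_categories[%s]: universe %d species (%d uncoverable), %s cover of %d cells%s",
            cat,
            len(inst.universe),
            len(uncoverable),
            method,
            len(sol.selected),
            " (certified optimal)" if sol.optimal_certified else "",
        )
        out[cat] = CategoryResult(cat, sol, inst, uncoverable)
    return out


def priority_levels(
    solutions: Mapping[str, Iterable[int]], config: AnalysisConfig
) -> pd.DataFrame:
    """Combine category cell lists into priority levels.

    ``solutions`` maps category name to its selected grid ids. Returns a
    DataFrame indexed by grid_id with columns ``k`` (number of lists
    containing the cell), ``raw_level`` (= 5 - k), ``display_level``
    (non-empty strata renumbered from 1 when ``config.level_relabel``) and
    ``categories`` (pipe-joined).
    """
    membership: Dict[int, List[str]] = {}
    for cat, sel in solutions.items():
        for gid in sel:
            membership.setdefault(int(gid), []).append(cat)
    if not membership:
        return pd.DataFrame(columns=["k", "raw_level", "display_level", "categories"])

    rows = []
    for gid in sorted(membership):
        cats = sorted(set(membership[gid]))
        rows.append({"grid_id": gid, "k": len(cats), "categories": "|".join(cats)})
    df = pd.DataFrame(rows).set_index("grid_id")
    df["raw_level"] = 5 - df["k"]

    if config.level_relabel:
        strata = sorted(df["k"].unique(), reverse=True)  # highest k -> Level 1
        relabel = {k: i + 1 for i, k in enumerate(strata)}
        df["display_level"] = df["k"].map(relabel)
    else:
        df["display_level"] = df["raw_level"]
    return df[["k", "raw_level", "display_level", "categories"]]


@dataclass
class CoverageReport:
    per_category_verified: Dict[str, bool]
    covered_species: FrozenSet[str]
    excluded_species: Dict[str, str]  # species_id -> reason

    @property
    def n_covered(self) -> int:
        return len(self.covered_species)


def coverage_audit(
    results: Mapping[str, CategoryResult],
    pairs: Sequence[IncidencePair],
    species: Sequence[Species],
) -> CoverageReport:
    """Verify each category's cover and account for every species.

    Raises if any category's selection fails verification (a solver bug).
    Species never appearing in retained cells are listed with the reason.
    """
    verified: Dict[str, bool] = {}
    for cat, res in results.items():
        ok = verify_cover(res.instance, res.solution.selected)
        verified[cat] = ok
        if not ok:
            raise RuntimeError(f"category {cat!r}: selected cells do not cover its universe")

    union_cells = {gid for res in results.values() for gid in res.solution.selected}
    present_in_union = {p.species_id for p in pairs if p.grid_id in union_cells}
    present_anywhere = {p.species_id for p in pairs}

    excluded: Dict[str, str] = {}
    for s in species:
        if s.species_id not in present_anywhere:
            excluded[s.species_id] = "no records in retained cells"
    covered = frozenset(
        s.species_id for s in species if s.species_id in present_in_union
    )
    return CoverageReport(verified, covered, excluded)
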