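"""Per-cell species richness and per-species occupancy.

Richness of a cell is the number of distinct species of the chosen category
recorded in it; occupancy of a species is the number of distinct retained
cells it occupies. Both are plain marginals of the deduplicated incidence
table, so their grand totals coincide with the pair count.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence, Set

import pandas as pd

from .model import IncidencePair

__all__ = ["richness_per_cell", "occupancy", "occupied_cell_count"]


def _restrict(pairs: Sequence[IncidencePair], subset: Iterable[str]) -> list:
    ids: Set[str] = set(subset)
    return [p for p in pairs if p.species_id in ids]


def richness_per_cell(
    pairs: Sequence[IncidencePair],
    subset: Iterable[str],
    cell_ids: Optional[Iterable[int]] = None,
    label: str = "all",
) -> pd.Series:
    """Distinct-species count per cell for a category subset.

    When ``cell_ids`` is given (the retained cells of the grid), cells with no
    incidence are reported with count 0. Returned as an int Series indexed by
    grid_id, named by the category label.
    """
    sub = _restrict(pairs, subset)
    counts: dict = {}
    for p in sub:
        counts[p.grid_id] = counts.get(p.grid_id, 0) + 1
    if cell_ids is not None:
        counts = {gid: counts.get(gid, 0) for gid in cell_ids}
    ser = pd.Series(counts, dtype="int64", name=label).sort_index()
    return ser


def occupancy(
    pairs: Sequence[IncidencePair], subset: Iterable[str], label: str = "all"
) -> pd.Series:
    """Distinct-cell count per species, sorted descending (ties by id)."""
    sub = _restrict(pairs, subset)
    counts = {sid: 0 for sid in subset}
    for p in sub:
        counts[p.species_id] += 1
    ser = pd.Series(counts, dtype="int64", name=label).sort_index()
    return ser.sort_values(ascending=False, kind="stable")  # ties stay id-sorted


def occupied_cell_count(pairs: Sequence[IncidencePair], subset: Iterable[str]) -> int:
    """Number of retained cells holding at least one species of the subset."""
    return len({p.grid_id for p in _restrict(pairs, subset)})
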