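"""Protected-area overlay and conservation-gap classification.

A priority cell counts as protected when its intersection with the dissolved
protected-area layer has strictly positive area — a reserve merely touching a
cell edge does not protect it. Cells without such overlap are conservation
gaps and inherit their priority display level. An optional minimum-fraction
parameter tightens "any overlap" to "at least this fraction of the cell".
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, Mapping, Sequence

import pandas as pd
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union
from shapely.validation import make_valid

from .grid import GridCell

log = logging.getLogger(__name__)

__all__ = ["overlay_protection", "gap_levels"]

_AREA_EPS = 1e-12  # relative to cell area; boundary-contact intersections are exact 0


def overlay_protection(
    priority_cells: Sequence[GridCell],
    protected: Iterable[BaseGeometry],
    min_fraction: float = 0.0,
) -> Dict[int, bool]:
    """Flag each cell protected iff it positively overlaps the reserve union."""
    if not (0.0 <= min_fraction <= 1.0):
        raise ValueError("min_fraction must be in [0, 1]")
    geoms = []
    for g in protected:
        if not g.is_valid:
            g = make_valid(g)
            if not g.is_valid:
                raise ValueError("invalid protected-area geometry (repair failed)")
        if not g.is_empty:
            geoms.append(g)
    union = unary_union(geoms) if geoms else None

    flags: Dict[int, bool] = {}
    for cell in priority_cells:
        if union is None or union.is_empty:
            flags[cell.grid_id] = False
            continue
        inter = cell.polygon.intersection(union).area
        cell_area = cell.polygon.area
        threshold = max(min_fraction * cell_area, _AREA_EPS * cell_area)
        flags[cell.grid_id] = inter >= threshold if min_fraction > 0 else inter > _AREA_EPS * cell_area
    n_prot = sum(flags.values())
    log.info(
        "overlay_protection: %d / %d priority cells overlap protected areas",
        n_prot,
        len(flags),
    )
    return flags


def gap_levels(priority: pd.DataFrame, flags: Mapping[int, bool]) -> pd.DataFrame:
    """Gap table: unprotected priority cells with their display level.

    ``priority`` is the table from :func:`covergap.prioritize.priority_levels`;
    ``flags`` must cover every priority cell.
    """
    missing = [gid for gid in priority.index if gid not in flags]
    if missing:
        raise ValueError(f"protection flags missing for priority cells {missing}")
    gap_ids = [gid for gid in priority.index if not flags[gid]]
    gaps = priority.loc[gap_ids, ["display_level"]].copy()
    gaps["gap_level"] = gaps.pop("display_level")
    by_level = gaps["gap_level"].value_counts().sort_index()
    log.info(
        "gap_levels: %d gap cell(s); per level: %s",
        len(gaps),
        {int(k): int(v) for k, v in by_level.items()},
    )
    return gaps
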