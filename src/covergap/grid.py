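"""Equal-area gridding of a study region and projection of point records.

The study boundary's bounding box is tiled with axis-aligned square cells of
edge ``cell_size_m``, numbered row-major from the north-west corner. Cells
whose area inside the boundary is less than half the cell area (configurable)
are flagged non-retained and excluded from every downstream stage; a fraction
exactly at the threshold is kept, since only cells strictly below it are
removed.

Point-to-cell assignment uses half-open intervals
``[x0 + i*s, x0 + (i+1)*s) x (y0 - (j+1)*s, y0 - j*s]`` so a point on a shared
edge belongs to exactly one cell.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from shapely.geometry import box
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

from .model import AnalysisConfig, IncidencePair, OccurrenceRecord

log = logging.getLogger(__name__)

__all__ = ["GridCell", "GridLayer", "build_grid", "assign_to_grid"]

# guards against float noise in area ratios computed from exact tilings
_FRACTION_EPS = 1e-9


@dataclass(frozen=True)
class GridCell:
    grid_id: int
    polygon: BaseGeometry
    area_fraction: float
    retained: bool
    row: int
    col: int


@dataclass
class GridLayer:
    cells: List[GridCell]
    origin: Tuple[float, float]  # north-west corner (x0, y0)
    n_rows: int
    n_cols: int
    cell_size_m: float
    crs_spec: str = ""
    _by_id: Dict[int, GridCell] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {c.grid_id: c for c in self.cells}

    def __len__(self) -> int:
        return len(self.cells)

    def cell(self, grid_id: int) -> GridCell:
        return self._by_id[grid_id]

    @property
    def retained_cells(self) -> List[GridCell]:
        return [c for c in self.cells if c.retained]

    @property
    def retained_ids(self) -> List[int]:
        return [c.grid_id for c in self.cells if c.retained]

    def locate(self, x: float, y: float) -> Optional[int]:
        """grid_id of the cell containing (x, y) under the half-open rule."""
        x0, y0 = self.origin
        s = self.cell_size_m
        col = math.floor((x - x0) / s)
        row = math.floor((y0 - y) / s)
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return row * self.n_cols + col
        return None


def build_grid(boundary: BaseGeometry, config: AnalysisConfig) -> GridLayer:
    """Tile the boundary's bounding box and apply the area-retention rule."""
    if boundary is None or boundary.is_empty:
        raise ValueError("boundary geometry is empty")
    if not boundary.is_valid:
        boundary = make_valid(boundary)
    if boundary.area <= 0:
        raise ValueError("boundary geometry has zero area")

    s = config.cell_size_m
    minx, miny, maxx, maxy = boundary.bounds
    n_cols = max(1, math.ceil((maxx - minx) / s - _FRACTION_EPS))
    n_rows = max(1, math.ceil((maxy - miny) / s - _FRACTION_EPS))
    x0, y0 = minx, maxy
    cell_area = s * s

    cells: List[GridCell] = []
    prepared = boundary  # shapely 2: intersection on the raw geometry is fine
    for row in range(n_rows):
        top = y0 - row * s
        for col in range(n_cols):
            left = x0 + col * s
            poly = box(left, top - s, left + s, top)
            frac = poly.intersection(prepared).area / cell_area
            frac = min(max(frac, 0.0), 1.0)
            retained = frac >= config.area_fraction_threshold - _FRACTION_EPS
            cells.append(
                GridCell(
                    grid_id=row * n_cols + col,
                    polygon=poly,
                    area_fraction=frac,
                    retained=retained,
                    row=row,
                    col=col,
                )
            )
    layer = GridLayer(cells, (x0, y0), n_rows, n_cols, s, config.crs_spec)
    log.info(
        "build_grid: %d cells (%d x %d), %d retained at threshold %.2f",
        len(cells),
        n_rows,
        n_cols,
        len(layer.retained_ids),
        config.area_fraction_threshold,
    )
    return layer


def assign_to_grid(
    records: Sequence[OccurrenceRecord], grid: GridLayer
) -> List[IncidencePair]:
    """Project point records onto retained cells, one pair per species x cell.

    Records falling outside the grid extent or in non-retained cells are
    dropped (counted, not an error); multiple records of one species in one
    cell collapse to a single incidence pair.
    """
    n_outside = 0
    n_nonretained = 0
    seen = set()
    for r in records:
        gid = grid.locate(r.x, r.y)
        if gid is None:
            n_outside += 1
            continue
        if not grid.cell(gid).retained:
            n_nonretained += 1
            continue
        seen.add(IncidencePair(r.species_id, gid))
    pairs = sorted(seen)
    n_dup = len(records) - n_outside - n_nonretained - len(pairs)
    log.info(
        "assign_to_grid: %d records in, %d outside grid, %d in non-retained cells,"
        " %d duplicates merged, %d pairs out",
        len(records),
        n_outside,
        n_nonretained,
        n_dup,
        len(pairs),
    )
    return pairs
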