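"""End-to-end orchestration: gridding -> richness -> covers -> levels -> gaps.

Two explicit ingestion modes (never guessed from file content):

* pre-gridded — a long-format incidence CSV (species_id, grid_id);
* raw records — an occurrences CSV plus a boundary GeoJSON, which are
  gridded and deduplicated first.

Every run writes a manifest (config snapshot, SHA-256 input digests, stage
timings, output inventory) so identical inputs and configuration can be
shown to produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import __version__
from . import io as cio
from .association import Severity, chi_square, classify_severity, contingency
from .grid import GridLayer, assign_to_grid, build_grid
from .model import AnalysisConfig
from .prioritize import (
    CATEGORIES,
    category_subsets,
    coverage_audit,
    priority_levels,
    solve_categories,
)
from .gaps import gap_levels, overlay_protection
from .richness import occupancy, occupied_cell_count, richness_per_cell

log = logging.getLogger(__name__)

__all__ = ["RunInputs", "RunManifest", "run_all"]


@dataclass
class RunInputs:
    species: Path
    incidence: Optional[Path] = None
    occurrences: Optional[Path] = None
    boundary: Optional[Path] = None
    protected: Optional[Path] = None

    def validate(self) -> None:
        if self.incidence is None and (self.occurrences is None or self.boundary is None):
            raise ValueError(
                "inputs must provide either an incidence file or occurrences + boundary"
            )
        if self.incidence is not None and self.occurrences is not None:
            raise ValueError("give either pre-gridded incidence or raw occurrences, not both")
        for name in ("species", "incidence", "occurrences", "boundary", "protected"):
            p = getattr(self, name)
            if p is not None and not Path(p).is_file():
                raise FileNotFoundError(f"{name} input not found: {p}")


@dataclass
class RunManifest:
    tool_version: str
    config: Dict
    input_digests: Dict[str, str]
    stage_seconds: Dict[str, float]
    outputs: List[str] = field(default_factory=list)

    def write(self, path: Path) -> None:
        payload = {
            "tool_version": self.tool_version,
            "config": self.config,
            "input_digests": self.input_digests,
            "stage_seconds": {k: round(v, 3) for k, v in self.stage_seconds.items()},
            "outputs": sorted(self.outputs),
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_all(config: AnalysisConfig, inputs: RunInputs, out_dir: str | Path) -> RunManifest:
    """Execute every applicable stage and write the standard outputs."""
    inputs.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: Dict[str, float] = {}
    outputs: List[str] = []
    digests = {
        name: _sha256(p)
        for name in ("species", "incidence", "occurrences", "boundary", "protected")
        if (p := getattr(inputs, name)) is not None
    }

    def stage(name: str):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                log.info("[%s] start", name)
                return self_

            def __exit__(self_, *exc):
                timings[name] = time.perf_counter() - self_.t0
                log.info("[%s] done in %.2fs", name, timings[name])

        return _T()

    def emit(path: Path):
        outputs.append(str(path.relative_to(out)))

    species = cio.read_species_table(inputs.species)
    subsets = category_subsets(species)

    grid: Optional[GridLayer] = None
    with stage("ingest"):
        if inputs.incidence is not None:
            pairs = cio.read_incidence(inputs.incidence)
            cio.check_species_ids(pairs, species, what="incidence pairs")
        else:
            records = cio.read_occurrences(inputs.occurrences)
            cio.check_species_ids(records, species, what="occurrence records")
            boundary = cio.read_boundary_geojson(inputs.boundary)
            grid = build_grid(boundary, config)
            pairs = assign_to_grid(records, grid)
            cio.write_cells_geojson(grid.cells, None, out / "grid.geojson")
            emit(out / "grid.geojson")
        cio.write_incidence(pairs, out / "incidence.csv")
        emit(out / "incidence.csv")

    with stage("richness"):
        cell_ids = grid.retained_ids if grid is not None else None
        frames = []
        for cat in CATEGORIES:
            ser = richness_per_cell(pairs, subsets[cat], cell_ids, label=cat)
            frames.append(
                pd.DataFrame(
                    {"grid_id": ser.index, "category": cat, "count": ser.values}
                )
            )
        rich = pd.concat(frames, ignore_index=True)
        rich.to_csv(out / "richness.csv", index=False)
        emit(out / "richness.csv")
        occ_frames = []
        for cat in CATEGORIES:
            ser = occupancy(pairs, subsets[cat], label=cat)
            occ_frames.append(
                pd.DataFrame(
                    {"species_id": ser.index, "category": cat, "n_cells": ser.values}
                )
            )
        pd.concat(occ_frames, ignore_index=True).to_csv(out / "occupancy.csv", index=False)
        emit(out / "occupancy.csv")

    with stage("cover"):
        greedy = solve_categories(pairs, species, config, method="greedy")
        exact = solve_categories(pairs, species, config, method="exact")
        for cat in CATEGORIES:
            cio.write_solution_csv(greedy[cat].solution, out / f"cover_greedy_{cat}.csv")
            emit(out / f"cover_greedy_{cat}.csv")
            cio.write_solution_csv(exact[cat].solution, out / f"cover_exact_{cat}.csv")
            emit(out / f"cover_exact_{cat}.csv")

    with stage("levels"):
        priority = priority_levels(
            {cat: exact[cat].solution.selected for cat in CATEGORIES}, config
        )
        priority.to_csv(out / "priority.csv")
        emit(out / "priority.csv")
        audit = coverage_audit(exact, pairs, species)
        audit_rows = [
            {"species_id": sid, "status": "excluded", "reason": reason}
            for sid, reason in sorted(audit.excluded_species.items())
        ]
        audit_rows += [
            {"species_id": sid, "status": "covered", "reason": ""}
            for sid in sorted(audit.covered_species)
        ]
        pd.DataFrame(audit_rows, columns=["species_id", "status", "reason"]).to_csv(
            out / "coverage_audit.csv", index=False
        )
        emit(out / "coverage_audit.csv")

    if inputs.protected is not None:
        if grid is None:
            log.warning(
                "gap stage skipped: pre-gridded incidence carries no cell geometry; "
                "supply occurrences + boundary to enable the overlay"
            )
        else:
            with stage("gaps"):
                reserves = cio.read_polygons_geojson(inputs.protected)
                cells = [grid.cell(gid) for gid in priority.index]
                flags = overlay_protection(cells, reserves)
                gaps = gap_levels(priority, flags)
                gaps.to_csv(out / "gaps.csv")
                emit(out / "gaps.csv")
                attrs = {
                    gid: {
                        "display_level": int(priority.loc[gid, "display_level"]),
                        "protected": bool(flags[gid]),
                        "gap": not flags[gid],
                    }
                    for gid in priority.index
                }
                cio.write_cells_geojson(cells, attrs, out / "gaps.geojson")
                emit(out / "gaps.geojson")
    elif grid is not None:
        log.warning("gap stage skipped: no protected-area layer supplied")

    with stage("association"):
        t1 = contingency(
            species,
            row=lambda s: s.is_threatened,
            col=lambda s: classify_severity(s) is Severity.FATAL,
            row_labels=("threatened", "non-threatened"),
            col_labels=("fatal", "non-fatal"),
        )
        r1 = chi_square(t1, yates=config.yates_correction)
        t2 = contingency(
            species,
            row=lambda s: s.is_endemic,
            col=lambda s: s.is_threatened,
            row_labels=("endemic", "non-endemic"),
            col_labels=("threatened", "non-threatened"),
        )
        r2 = chi_square(t2, yates=config.yates_correction)
        rows = []
        for name, tab, res in (
            ("threat_x_severity", t1, r1),
            ("endemism_x_threat", t2, r2),
        ):
            (a, b), (c, d) = tab.counts
            rows.append(
                {
                    "test": name,
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                    "statistic": f"{res.statistic:.6f}",
                    "df": res.df,
                    "p_value": f"{res.p_value:.6f}",
                    "yates": res.corrected,
                }
            )
        pd.DataFrame(rows).to_csv(out / "association.csv", index=False)
        emit(out / "association.csv")

    manifest = RunManifest(
        tool_version=__version__,
        config=config.as_dict(),
        input_digests=digests,
        stage_seconds=timings,
        outputs=outputs,
    )
    manifest.write(out / "manifest.json")
    return manifest
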