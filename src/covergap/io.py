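"""Readers and writers for the package's plain-text interchange formats.

CSV files are UTF-8 with a header row; columns are matched by name, never by
position. Polygon layers use RFC 7946 GeoJSON, read and written with
:mod:`json` plus :mod:`shapely`. All readers validate the schema and reject
violations with informative errors instead of coercing silently.

Schemas
-------
species.csv
    ``species_id,name,family,genus,endemic,threat,protection,parts`` —
    ``parts`` is a pipe-joined token list such as ``"I|III"``.
incidence.csv
    ``species_id,grid_id`` (long-format, one presence per row).
occurrences.csv
    ``species_id,x,y[,source_tag]`` (projected coordinates).
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Iterable, List, Mapping, Optional, Sequence

import pandas as pd
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .model import (
    IncidencePair,
    OccurrenceRecord,
    PartCategory,
    ProtectionLevel,
    Species,
    ThreatCategory,
    parse_bool,
)

log = logging.getLogger(__name__)

__all__ = [
    "read_species_table",
    "write_species_table",
    "read_incidence",
    "write_incidence",
    "read_occurrences",
    "write_occurrences",
    "write_solution_csv",
    "write_cells_geojson",
    "read_cells_geojson",
    "read_polygons_geojson",
    "read_boundary_geojson",
    "write_polygons_geojson",
    "check_species_ids",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _enum_or_none(enum_cls, token, none_value, row, path):
    t = str(token).strip()
    if t in ("", "nan", "NONE", "none"):
        return none_value
    try:
        return enum_cls(t)
    except ValueError:
        raise ValueError(
            f"{path}: row {row}: unknown {enum_cls.__name__} token {token!r}"
        ) from None


def read_species_table(path: str | Path) -> List[Species]:
    """Read the species master table; hard error on duplicates or bad tokens."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(
        df,
        ["species_id", "name", "family", "genus", "endemic", "threat", "protection", "parts"],
        path,
    )
    dupes = df["species_id"][df["species_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate species_id(s): {dupes}")
    out: List[Species] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        parts_raw = [t for t in str(row.parts).split("|") if t.strip()]
        if not parts_raw:
            raise ValueError(f"{path}: row {i}: empty medicinal-part list")
        try:
            parts = frozenset(PartCategory(t.strip()) for t in parts_raw)
        except ValueError:
            raise ValueError(
                f"{path}: row {i}: unknown part-category token in {row.parts!r}"
            ) from None
        out.append(
            Species(
                species_id=row.species_id,
                name=row.name,
                family=row.family,
                genus=row.genus,
                is_endemic=parse_bool(row.endemic, context=f" ({path}: row {i})"),
                threat_category=_enum_or_none(
                    ThreatCategory, row.threat, ThreatCategory.NONE, i, path
                ),
                protection_level=_enum_or_none(
                    ProtectionLevel, row.protection, ProtectionLevel.NONE, i, path
                ),
                part_categories=parts,
            )
        )
    log.info("read %d species from %s", len(out), path)
    return out


def write_species_table(species: Iterable[Species], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["species_id", "name", "family", "genus", "endemic", "threat", "protection", "parts"]
        )
        for s in species:
            w.writerow(
                [
                    s.species_id,
                    s.name,
                    s.family,
                    s.genus,
                    str(s.is_endemic).lower(),
                    s.threat_category.value,
                    s.protection_level.value,
                    "|".join(sorted(p.value for p in s.part_categories)),
                ]
            )


def read_incidence(path: str | Path) -> List[IncidencePair]:
    """Read long-format (species_id, grid_id) presences, deduplicated."""
    df = pd.read_csv(path, dtype={"species_id": str})
    _require_columns(df, ["species_id", "grid_id"], path)
    n_raw = len(df)
    pairs = sorted(
        {IncidencePair(str(r.species_id), int(r.grid_id)) for r in df.itertuples(index=False)}
    )
    n_dup = n_raw - len(pairs)
    if n_dup:
        log.info("read_incidence(%s): %d duplicate pair(s) merged", path, n_dup)
    log.info("read %d incidence pairs from %s", len(pairs), path)
    return pairs


def write_incidence(pairs: Iterable[IncidencePair], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["species_id", "grid_id"])
        for p in sorted(set(pairs)):
            w.writerow([p.species_id, p.grid_id])


def read_occurrences(path: str | Path) -> List[OccurrenceRecord]:
    df = pd.read_csv(path, dtype={"species_id": str})
    _require_columns(df, ["species_id", "x", "y"], path)
    has_tag = "source_tag" in df.columns
    out = []
    for r in df.itertuples(index=False):
        tag = getattr(r, "source_tag", None) if has_tag else None
        if tag is not None and (pd.isna(tag) or tag == ""):
            tag = None
        out.append(OccurrenceRecord(str(r.species_id), float(r.x), float(r.y), tag))
    log.info("read %d occurrence records from %s", len(out), path)
    return out


def write_occurrences(records: Iterable[OccurrenceRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["species_id", "x", "y", "source_tag"])
        for r in records:
            w.writerow([r.species_id, repr(float(r.x)), repr(float(r.y)), r.source_tag or ""])


def check_species_ids(
    items: Iterable, species: Iterable[Species], *, what: str = "records"
) -> None:
    """Hard error when occurrence/incidence species are absent from the table."""
    known = {s.species_id for s in species}
    unknown = sorted({it.species_id for it in items} - known)
    if unknown:
        raise ValueError(f"{what} reference species absent from the species table: {unknown}")


def write_solution_csv(solution, path: str | Path) -> None:
    """Write a set-cover solution with a header comment carrying the certificate."""
    method = getattr(solution.method, "value", str(solution.method))
    with open(path, "w", newline="") as fh:
        fh.write(
            f"# method={method} cardinality={len(solution.selected)}"
            f" certified={str(solution.optimal_certified).lower()}"
            f" lower_bound={solution.lower_bound}\n"
        )
        w = csv.writer(fh)
        if getattr(solution, "newly_covered", None) is not None:
            w.writerow(["rank", "set_id", "newly_covered"])
            for rank, (sid, new) in enumerate(
                zip(solution.selected, solution.newly_covered), start=1
            ):
                w.writerow([rank, sid, new])
        else:
            w.writerow(["set_id"])
            for sid in solution.selected:
                w.writerow([sid])


# GeoJSON ----------------------------------------------------------------------

def write_cells_geojson(
    cells,
    attributes: Optional[Mapping[int, Mapping[str, object]]],
    path: str | Path,
) -> None:
    """Write grid cells as a GeoJSON FeatureCollection.

    Every feature carries ``grid_id``, ``area_fraction`` and ``retained``;
    extra per-cell attributes (richness, level, gap ...) are merged from
    ``attributes`` keyed by grid_id.
    """
    features = []
    for c in cells:
        props = {
            "grid_id": c.grid_id,
            "area_fraction": round(float(c.area_fraction), 6),
            "retained": bool(c.retained),
        }
        if attributes and c.grid_id in attributes:
            props.update(attributes[c.grid_id])
        features.append(
            {
                "type": "Feature",
                "geometry": shapely_mapping(c.polygon),
                "properties": props,
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, sort_keys=True)
    )


def read_cells_geojson(path: str | Path):
    """Read grid cells back from a FeatureCollection written by this package."""
    from .grid import GridCell

    obj = json.loads(Path(path).read_text())
    if obj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a FeatureCollection of grid cells")
    cells = []
    for f in obj["features"]:
        props = f["properties"]
        if "grid_id" not in props:
            raise ValueError(f"{path}: feature without grid_id")
        cells.append(
            GridCell(
                grid_id=int(props["grid_id"]),
                polygon=shapely_shape(f["geometry"]),
                area_fraction=float(props.get("area_fraction", 1.0)),
                retained=bool(props.get("retained", True)),
                row=-1,
                col=-1,
            )
        )
    return sorted(cells, key=lambda c: c.grid_id)


def read_polygons_geojson(path: str | Path) -> List[BaseGeometry]:
    """Read all (multi)polygon geometries from a GeoJSON file."""
    obj = json.loads(Path(path).read_text())
    if obj.get("type") == "FeatureCollection":
        geoms = [shapely_shape(f["geometry"]) for f in obj["features"]]
    elif obj.get("type") == "Feature":
        geoms = [shapely_shape(obj["geometry"])]
    else:
        geoms = [shapely_shape(obj)]
    for g in geoms:
        if g.is_empty:
            raise ValueError(f"{path}: empty geometry")
    return geoms


def read_boundary_geojson(path: str | Path) -> BaseGeometry:
    """Read a study-area boundary as a single dissolved (multi)polygon."""
    geom = unary_union(read_polygons_geojson(path))
    if geom.is_empty or geom.area <= 0:
        raise ValueError(f"{path}: boundary has no area")
    return geom


def write_polygons_geojson(geoms: Iterable[BaseGeometry], path: str | Path) -> None:
    features = [
        {"type": "Feature", "geometry": shapely_mapping(g), "properties": {"id": i}}
        for i, g in enumerate(geoms)
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, sort_keys=True)
    )
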