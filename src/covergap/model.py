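"""Domain types and run configuration.

The analysis works on three kinds of records:

* :class:`Species` — one taxon with its conservation attributes: endemism,
  national red-list threat category (CR/EN/VU), national key-protection level
  (I/II) and the categories of plant parts used medicinally (I = harvest can
  kill the plant: whole plant, roots, heartwood; II = branches/leaves, resin,
  bark; III = flowers, fruits, seeds).
* :class:`OccurrenceRecord` — a point record (e.g. a county centroid) in a
  projected coordinate system.
* :class:`IncidencePair` — a deduplicated (species, grid cell) presence.

:class:`AnalysisConfig` holds the spatial constants (100 km cells, the 50 %
area-retention rule) and the reproducibility knobs shared by all stages.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import FrozenSet, Optional

__all__ = [
    "ThreatCategory",
    "ProtectionLevel",
    "PartCategory",
    "TieBreak",
    "Species",
    "OccurrenceRecord",
    "IncidencePair",
    "AnalysisConfig",
]


class ThreatCategory(str, Enum):
    """National red-list category; NONE means not listed as threatened."""

    CR = "CR"
    EN = "EN"
    VU = "VU"
    NONE = "NONE"


class ProtectionLevel(str, Enum):
    """National key-protection class; NONE means not on the protection list."""

    I = "I"
    II = "II"
    NONE = "NONE"


class PartCategory(str, Enum):
    """Severity class of a medicinal plant part (I most destructive)."""

    I = "I"
    II = "II"
    III = "III"


class TieBreak(str, Enum):
    """Tie-breaking rule for the greedy set-cover heuristic."""

    LOWEST_ID = "LOWEST_ID"
    HIGHEST_RICHNESS_THEN_LOWEST_ID = "HIGHEST_RICHNESS_THEN_LOWEST_ID"


@dataclass(frozen=True)
class Species:
    species_id: str
    name: str
    family: str
    genus: str
    is_endemic: bool
    threat_category: ThreatCategory
    protection_level: ProtectionLevel
    part_categories: FrozenSet[PartCategory]

    def __post_init__(self) -> None:
        if not self.species_id:
            raise ValueError("species_id must be non-empty")
        if not isinstance(self.threat_category, ThreatCategory):
            raise ValueError(f"invalid threat category: {self.threat_category!r}")
        if not isinstance(self.protection_level, ProtectionLevel):
            raise ValueError(f"invalid protection level: {self.protection_level!r}")
        object.__setattr__(self, "part_categories", frozenset(self.part_categories))
        for p in self.part_categories:
            if not isinstance(p, PartCategory):
                raise ValueError(f"invalid part category: {p!r}")

    @property
    def is_threatened(self) -> bool:
        return self.threat_category is not ThreatCategory.NONE

    @property
    def is_protected(self) -> bool:
        return self.protection_level is not ProtectionLevel.NONE


@dataclass(frozen=True)
class OccurrenceRecord:
    species_id: str
    x: float
    y: float
    source_tag: Optional[str] = None

    def __post_init__(self) -> None:
        import math

        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(
                f"non-finite coordinates for {self.species_id}: ({self.x}, {self.y})"
            )


@dataclass(frozen=True, order=True)
class IncidencePair:
    species_id: str
    grid_id: int


_TRUE_TOKENS = {"true", "t", "1", "yes", "y"}
_FALSE_TOKENS = {"false", "f", "0", "no", "n"}


def parse_bool(token: str, *, context: str = "") -> bool:
    """Parse a boolean flag token; unknown tokens are a hard error."""
    t = str(token).strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    raise ValueError(f"unrecognized boolean token {token!r}{context}")


# Albers equal-area conic suitable for China; documentation of the default
# projected CRS — coordinates are expected to be supplied already projected.
DEFAULT_CRS = "+proj=aea +lat_1=25 +lat_2=47 +lon_0=105 +x_0=0 +y_0=0 +units=m"


@dataclass
class AnalysisConfig:
    """Shared analysis constants.

    cell_size_m
        Edge length of the square planning units, metres (default 100 km).
    area_fraction_threshold
        A cell is retained when the fraction of its area inside the study
        boundary is >= this value; cells strictly below it are removed.
    tie_break
        Greedy set-cover tie rule.
    yates_correction
        Default continuity-correction setting for 2x2 chi-square tests.
    level_relabel
        Renumber non-empty priority strata consecutively from Level 1.
    """

    cell_size_m: float = 100_000.0
    area_fraction_threshold: float = 0.5
    tie_break: TieBreak = TieBreak.LOWEST_ID
    yates_correction: bool = True
    level_relabel: bool = True
    seed: int = 0
    crs_spec: str = DEFAULT_CRS

    def __post_init__(self) -> None:
        if isinstance(self.tie_break, str):
            self.tie_break = TieBreak(self.tie_break)
        if not self.cell_size_m > 0:
            raise ValueError("cell_size_m must be > 0")
        if not (0 < self.area_fraction_threshold <= 1):
            raise ValueError("area_fraction_threshold must be in (0, 1]")

    # flat key=value round-trip ------------------------------------------------
    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        kwargs: dict = {}
        casts = {
            "cell_size_m": float,
            "area_fraction_threshold": float,
            "tie_break": TieBreak,
            "yates_correction": parse_bool,
            "level_relabel": parse_bool,
            "seed": int,
            "crs_spec": str,
        }
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in casts:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = casts[key](value)
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, Enum):
                v = v.value
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    def as_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            out[f.name] = v.value if isinstance(v, Enum) else v
        return out
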