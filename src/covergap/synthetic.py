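"""Synthetic landscapes and set-cover instances for end-to-end testing.

The landscape generator emulates the statistical structure of a national
species-occurrence compilation gridded to ~100 km planning units:

* richness increases toward the south (configurable gradient strength);
* range sizes are heavy-tailed (lognormal: most species occupy fewer than
  ~50 cells, a few are very widespread);
* ranges are spatially cohesive — grown from a seed cell into adjacent
  cells, with occasional long-distance jumps;
* conservation categories (endemic / threatened / protected) partially
  overlap, and threat is coupled to small range size via a log-odds bias;
* reserves are squares shrunk 10 % to sit strictly inside a configurable
  fraction of cells.

Defaults mirror a study of 148 medicinal gymnosperm taxa on a ~950-cell
national grid: category prevalences 61/148 endemic, 50/148 threatened
(3 CR / 15 EN / 32 VU), 43/148 protected (16 class I / 27 class II), and a
lognormal(mu=3.0, sigma=1.1) occupancy (median ~20 cells).

All randomness flows from one integer seed through per-component child
streams (``numpy.random.SeedSequence.spawn``), so adding a component does not
perturb the others and identical specs give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
from shapely.geometry import Polygon, box

from .model import (
    OccurrenceRecord,
    PartCategory,
    ProtectionLevel,
    Species,
    ThreatCategory,
)
from .setcover import CoverInstance

__all__ = ["SyntheticSpec", "gen_landscape", "gen_cover_instance", "gen_planted_instance"]

# occupancy cap keeps cover instances non-degenerate
_OCCUPANCY_CAP_FRACTION = 0.9


@dataclass
class SyntheticSpec:
    n_species: int = 148
    n_rows: int = 30
    n_cols: int = 32
    cell_size_m: float = 100_000.0
    gradient_strength: float = 2.0
    occupancy_lognormal: Tuple[float, float] = (3.0, 1.1)
    cohesion: float = 0.9
    p_endemic: float = 61 / 148
    p_threatened: float = 50 / 148
    p_protected: float = 43 / 148
    assoc_bias: float = 0.5
    reserve_fraction: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("dimensions and species count must be positive")
        for name in ("p_endemic", "p_threatened", "p_protected", "reserve_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.gradient_strength < 0:
            raise ValueError("gradient_strength must be >= 0")
        if not (0.0 <= self.cohesion <= 1.0):
            raise ValueError("cohesion must be in [0, 1]")
        if int(_OCCUPANCY_CAP_FRACTION * self.n_rows * self.n_cols) < 1:
            raise ValueError("grid too small: occupancy cap is below one cell")


def _row_weights(spec: SyntheticSpec) -> np.ndarray:
    """Sampling weight per row; row 0 is the northern edge."""
    if spec.n_rows == 1:
        return np.ones(1)
    southness = np.arange(spec.n_rows) / (spec.n_rows - 1)
    w = np.exp(spec.gradient_strength * southness)
    return w / w.sum()


def _grow_range(
    target: int, spec: SyntheticSpec, rng: np.random.Generator
) -> Set[Tuple[int, int]]:
    """Cohesive range of `target` cells, seeded and jumped with a south bias."""
    n_rows, n_cols = spec.n_rows, spec.n_cols
    row_w = _row_weights(spec)

    def sample_cell(exclude: Set[Tuple[int, int]]) -> Tuple[int, int]:
        for _ in range(1000):
            r = int(rng.choice(n_rows, p=row_w))
            c = int(rng.integers(n_cols))
            if (r, c) not in exclude:
                return (r, c)
        # dense ranges: fall back to uniform over the complement
        free = [
            (r, c) for r in range(n_rows) for c in range(n_cols) if (r, c) not in exclude
        ]
        return free[int(rng.integers(len(free)))]

    cells: Set[Tuple[int, int]] = {sample_cell(set())}
    while len(cells) < target:
        frontier = set()
        for r, c in cells:
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nr, nc = r + dr, c + dc
                if 0 <= nr < n_rows and 0 <= nc < n_cols and (nr, nc) not in cells:
                    frontier.add((nr, nc))
        if frontier and rng.random() < spec.cohesion:
            choice = sorted(frontier)[int(rng.integers(len(frontier)))]
        else:
            choice = sample_cell(cells)
        cells.add(choice)
    return cells


def gen_landscape(
    spec: SyntheticSpec,
) -> Tuple[Polygon, List[Species], List[OccurrenceRecord], List[Polygon]]:
    """Generate (boundary, species table, occurrence records, reserves)."""
    s = spec.cell_size_m
    width, height = spec.n_cols * s, spec.n_rows * s
    boundary = box(0.0, 0.0, width, height)
    n_cells = spec.n_rows * spec.n_cols
    cap = max(1, int(_OCCUPANCY_CAP_FRACTION * n_cells))

    root = np.random.SeedSequence(spec.seed)
    ss_occ, ss_range, ss_flags, ss_reserve = root.spawn(4)
    rng_occ = np.random.default_rng(ss_occ)
    rng_range = np.random.default_rng(ss_range)
    rng_flags = np.random.default_rng(ss_flags)
    rng_res = np.random.default_rng(ss_reserve)

    mu, sigma = spec.occupancy_lognormal
    targets = np.clip(
        np.round(rng_occ.lognormal(mu, sigma, size=spec.n_species)), 1, cap
    ).astype(int)

    # ranges and occurrence points (cell centres; row 0 along the north edge)
    width_digits = len(str(spec.n_species))
    species_ids = [f"sp{i + 1:0{width_digits}d}" for i in range(spec.n_species)]
    records: List[OccurrenceRecord] = []
    occ_cells: List[Set[Tuple[int, int]]] = []
    for sid, target in zip(species_ids, targets):
        cells = _grow_range(int(target), spec, rng_range)
        occ_cells.append(cells)
        for r, c in sorted(cells):
            x = (c + 0.5) * s
            y = height - (r + 0.5) * s
            records.append(OccurrenceRecord(sid, x, y, source_tag="synthetic"))

    # category flags; threat odds shrink with log range size (assoc_bias)
    log_occ = np.log(targets.astype(float))
    centered = log_occ - log_occ.mean()
    base_logit = math.log(spec.p_threatened / (1 - spec.p_threatened)) if 0 < spec.p_threatened < 1 else None
    species: List[Species] = []
    for i, sid in enumerate(species_ids):
        endemic = bool(rng_flags.random() < spec.p_endemic)
        if base_logit is None:
            threatened = spec.p_threatened >= 1.0
        else:
            p = 1 / (1 + math.exp(-(base_logit - spec.assoc_bias * centered[i])))
            threatened = bool(rng_flags.random() < p)
        if threatened:
            threat = ThreatCategory(
                str(rng_flags.choice(["CR", "EN", "VU"], p=[3 / 50, 15 / 50, 32 / 50]))
            )
        else:
            threat = ThreatCategory.NONE
        if rng_flags.random() < spec.p_protected:
            protection = ProtectionLevel.I if rng_flags.random() < 16 / 43 else ProtectionLevel.II
        else:
            protection = ProtectionLevel.NONE
        parts = {
            cat
            for cat, p_inc in (
                (PartCategory.I, 0.34),
                (PartCategory.II, 0.80),
                (PartCategory.III, 0.50),
            )
            if rng_flags.random() < p_inc
        }
        if not parts:
            parts = {PartCategory.II}
        species.append(
            Species(
                species_id=sid,
                name=f"Synthspecies {sid}",
                family=f"Fam{i % 10 + 1}",
                genus=f"Gen{i % 35 + 1}",
                is_endemic=endemic,
                threat_category=threat,
                protection_level=protection,
                part_categories=frozenset(parts),
            )
        )

    # reserves: uniformly chosen cells, squares shrunk 10 % about the centre
    n_reserve = int(round(spec.reserve_fraction * n_cells))
    reserve_cells = rng_res.choice(n_cells, size=n_reserve, replace=False) if n_reserve else []
    reserves: List[Polygon] = []
    for flat in sorted(int(v) for v in np.asarray(reserve_cells)):
        r, c = divmod(flat, spec.n_cols)
        left, top = c * s, height - r * s
        inset = 0.05 * s  # 10 % linear shrink
        reserves.append(box(left + inset, top - s + inset, left + s - inset, top - inset))

    return boundary, species, records, reserves


def gen_cover_instance(
    n_elements: int, n_sets: int, density: float, seed: int
) -> CoverInstance:
    """Random Bernoulli-membership instance, repaired to be feasible."""
    if not (0 < density <= 1):
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    members = rng.random((n_sets, n_elements)) < density
    # feasibility repair: every element must belong to at least one set
    for j in range(n_elements):
        if not members[:, j].any():
            members[int(rng.integers(n_sets)), j] = True
    elems = [f"e{j}" for j in range(n_elements)]
    sets = {
        i: frozenset(elems[j] for j in range(n_elements) if members[i, j])
        for i in range(n_sets)
    }
    return CoverInstance(frozenset(elems), sets)


def gen_planted_instance(
    s: int, n_elements: int, n_decoys: int, seed: int
) -> Tuple[CoverInstance, frozenset]:
    """Instance whose minimum cover is exactly the ``s`` planted sets.

    The planted sets partition the universe into ``s`` blocks; each block
    carries a private element that occurs in no decoy, so every cover must
    contain all planted sets. Decoys are strict subsets of the union of the
    blocks they intersect, always omitting each intersected block's private
    element.
    """
    if s < 1:
        raise ValueError("planted size s must be >= 1")
    if n_elements < s:
        raise ValueError("need at least one element per planted block")
    rng = np.random.default_rng(seed)
    elems = [f"e{j}" for j in range(n_elements)]
    # random partition into s non-empty blocks
    order = list(rng.permutation(n_elements))
    blocks: List[List[str]] = [[elems[order[i]]] for i in range(s)]
    for idx in order[s:]:
        blocks[int(rng.integers(s))].append(elems[idx])
    private = {b: blk[0] for b, blk in enumerate(blocks)}  # first member is private

    sets: Dict[int, frozenset] = {b: frozenset(blocks[b]) for b in range(s)}
    for d in range(n_decoys):
        n_touch = int(rng.integers(1, s + 1))
        touched = rng.choice(s, size=n_touch, replace=False)
        pool: List[str] = []
        for b in sorted(int(t) for t in touched):
            pool.extend(e for e in blocks[b] if e != private[b])
        if not pool:
            # all touched blocks are singletons; decoy collapses to empty,
            # use a single non-private element from any multi-element block
            fallback = [e for blk in blocks for e in blk[1:]]
            pool = fallback[:1]
        if pool:
            size = int(rng.integers(1, len(pool) + 1))
            chosen = rng.choice(len(pool), size=size, replace=False)
            sets[s + d] = frozenset(pool[int(j)] for j in chosen)
        else:
            sets[s + d] = frozenset()  # degenerate universe of singletons
    sets = {k: v for k, v in sets.items() if v or k < s}
    inst = CoverInstance(frozenset(elems), sets)
    return inst, frozenset(range(s))
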