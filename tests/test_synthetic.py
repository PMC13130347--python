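"""Synthetic landscape generator: reproducibility and statistical structure."""

from __future__ import annotations

import numpy as np
import pytest

from covergap.grid import assign_to_grid, build_grid
from covergap.model import AnalysisConfig
from covergap.richness import richness_per_cell
from covergap.synthetic import (
    SyntheticSpec,
    gen_cover_instance,
    gen_landscape,
    gen_planted_instance,
)


def small_spec(**kw):
    base = dict(n_species=25, n_rows=10, n_cols=10, seed=3)
    base.update(kw)
    return SyntheticSpec(**base)


def mean_richness_by_row(spec):
    boundary, species, records, _ = gen_landscape(spec)
    cfg = AnalysisConfig(cell_size_m=spec.cell_size_m)
    grid = build_grid(boundary, cfg)
    pairs = assign_to_grid(records, grid)
    rich = richness_per_cell(pairs, {s.species_id for s in species}, grid.retained_ids)
    rows = np.array([grid.cell(g).row for g in rich.index])
    return rows, rich.to_numpy()


class TestReproducibility:
    def test_same_seed_identical_outputs(self):
        a = gen_landscape(small_spec())
        b = gen_landscape(small_spec())
        assert a[0].equals(b[0])
        assert a[1] == b[1]
        assert a[2] == b[2]
        assert all(x.equals(y) for x, y in zip(a[3], b[3]))

    def test_different_seed_differs(self):
        a = gen_landscape(small_spec(seed=3))
        b = gen_landscape(small_spec(seed=4))
        assert a[2] != b[2]


class TestStructure:
    def test_no_gradient_means_no_row_correlation(self):
        # averaged over seeds, row index and richness should be uncorrelated
        rs = []
        for seed in range(20):
            rows, rich = mean_richness_by_row(small_spec(gradient_strength=0.0, seed=seed))
            if rich.std() > 0:
                rs.append(np.corrcoef(rows, rich)[0, 1])
        assert abs(float(np.mean(rs))) < 0.1

    def test_strong_gradient_enriches_the_south(self):
        wins = 0
        for seed in range(20):
            rows, rich = mean_richness_by_row(small_spec(gradient_strength=5.0, seed=seed))
            south = rich[rows >= rows.max() / 2].mean()
            north = rich[rows < rows.max() / 2].mean()
            wins += south > north
        assert wins >= 19

    def test_occupancy_capped_and_positive(self):
        spec = small_spec(occupancy_lognormal=(6.0, 1.0))  # pushes against the cap
        _, species, records, _ = gen_landscape(spec)
        per_species = {}
        for r in records:
            per_species[r.species_id] = per_species.get(r.species_id, 0) + 1
        assert max(per_species.values()) <= int(0.9 * 100)
        assert min(per_species.values()) >= 1
        assert len(per_species) == spec.n_species

    def test_reserves_sit_strictly_inside_cells(self):
        spec = small_spec(reserve_fraction=0.2)
        boundary, _, _, reserves = gen_landscape(spec)
        assert len(reserves) == round(0.2 * 100)
        s = spec.cell_size_m
        for res in reserves:
            minx, miny, maxx, maxy = res.bounds
            assert (maxx - minx) == pytest.approx(0.9 * s)
            # strictly inside one cell: no bound lies on a grid line
            assert (minx / s) % 1 != 0 and (maxy / s) % 1 != 0

    def test_reserve_fraction_zero_means_everything_is_gap(self, config):
        from covergap.gaps import gap_levels, overlay_protection
        from covergap.prioritize import priority_levels, solve_categories

        spec = small_spec(reserve_fraction=0.0)
        boundary, species, records, reserves = gen_landscape(spec)
        assert reserves == []
        cfg = AnalysisConfig(cell_size_m=spec.cell_size_m)
        grid = build_grid(boundary, cfg)
        pairs = assign_to_grid(records, grid)
        res = solve_categories(pairs, species, cfg)
        priority = priority_levels(
            {c: r.solution.selected for c, r in res.items()}, cfg
        )
        flags = overlay_protection([grid.cell(g) for g in priority.index], reserves)
        gaps = gap_levels(priority, flags)
        assert set(gaps.index) == set(priority.index)

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(n_species=0)
        with pytest.raises(ValueError):
            SyntheticSpec(p_threatened=1.5)


class TestCoverInstances:
    def test_full_density_optimum_is_one(self):
        inst = gen_cover_instance(8, 5, 1.0, 0)
        from covergap.setcover import exact_cover

        assert len(exact_cover(inst).selected) == 1

    def test_feasibility_repair(self):
        # very sparse: repair must still leave every element covered
        inst = gen_cover_instance(20, 4, 0.01, 1)
        covered = set().union(*inst.sets.values())
        assert covered == set(inst.universe)

    def test_reproducible(self):
        assert gen_cover_instance(12, 10, 0.3, 5).sets == gen_cover_instance(12, 10, 0.3, 5).sets

    def test_planted_partition_covers_universe(self):
        inst, planted = gen_planted_instance(4, 14, 5, 2)
        blocks = [inst.sets[b] for b in planted]
        assert frozenset().union(*blocks) == inst.universe
        assert sum(len(b) for b in blocks) == len(inst.universe)  # disjoint
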