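# Methods

This note records the models, conventions and numerical choices behind
`covergap`, and what the synthetic tests do and do not demonstrate.

## Gridding

The study boundary (any projected (multi)polygon) is tiled from the
north-west corner of its bounding box with axis-aligned squares of edge
`cell_size_m` (default 100 000 m), numbered row-major. For each cell the
area fraction `area(cell ∩ boundary) / area(cell)` is computed with exact
polygon intersection; cells with fraction `< area_fraction_threshold`
(default 0.5) are flagged non-retained and excluded from every downstream
stage. The comparison keeps a fraction exactly at the threshold, because
the border rule removes only cells *strictly below* half area; a 1e-9
epsilon absorbs float noise in geometrically exact ratios.

Point records are assigned arithmetically to half-open intervals
`[x0 + i·s, x0 + (i+1)·s) × (y0 − (j+1)·s, y0 − j·s]`, so a point on a
shared edge belongs to exactly one cell (the cell to its east,
respectively south). Records outside the grid or in non-retained cells
are counted and dropped, never errors. The package performs no
reprojection: coordinates must already be in an equal-area projected CRS
(for China-scale work an Albers conic with standard parallels 25°N/47°N
and central meridian 105°E is the documented default, recorded in
`AnalysisConfig.crs_spec` as metadata only). Consequently cell counts
from a real national boundary depend on the caller's projection and
boundary layer and are not asserted anywhere.

## Richness and occupancy

Richness per cell and occupancy per species are the two marginals of the
deduplicated incidence table restricted to a category subset; both sum to
the pair count, which the property tests assert. Non-retained cells never
appear; retained cells with no incidence are reported as zeros when the
grid is known.

## Minimum set cover

The universe is the coverable species of a category (species whose only
records fell in removed cells are split out and reported, mirroring taxa
lost to the border rule); the sets are the retained cells' species lists.

**Greedy.** Selects the cell with the largest number of newly covered
species until the universe is covered. The tie rule is configurable:
lowest cell id (default), or largest total species list then lowest id.
Because the original greedy procedure's tie order is not specified
anywhere, heuristic list *sizes* are reproducible only up to tie-breaking;
the suite therefore asserts the greedy ≥ optimal relation and the
harmonic approximation bound `|greedy| ≤ H(max |C_j|) · |optimal|`, not
specific greedy cell lists.

**Reductions.** Applied to a fixed point before exact solving: an element
covered by exactly one set forces that set; a set whose effective content
is a subset of another's is removed (ties keep the lowest id); an element
whose covering family is a superset of another element's is removed (it
is covered for free; equal families keep the lowest element id). The
invariant `optimum(original) = |forced| + optimum(reduced)` is checked
against the brute-force oracle on seeded instances.

**Exact.** Reduced instances with ≤ 30 sets are solved by depth-first
branch-and-bound over bitmasks: branch on the uncovered element with the
fewest covering sets, candidates ordered by gain then id; prune with
`len(chosen) + max(⌈|uncovered| / max set size⌉, independent-element
packing) ≥ incumbent`. Larger reduced instances go to the HiGHS solver
(`scipy.optimize.milp`) as a 0/1 program `min Σ x_j` subject to coverage
`A x ≥ 1`. Either path ends in an explicit certificate: the optimality
proof must have finished (tree exhausted within the node budget, default
10⁷ nodes, or ILP optimal status with matching dual bound) *and* the
selection is independently re-verified to cover the universe; otherwise
the best cover found is returned with `optimal_certified=False` and a
warning — never silently non-optimal.

**Canonicalization.** Minimum covers are usually non-unique; only the
cardinality is treated as a reproducible quantity. For determinism the
branch-and-bound path returns the lexicographically smallest sorted id
list among optima *of the reduced instance* plus the forced sets
(dominated-set removal can, in edge cases, exclude a raw-instance cover
that would sort earlier; determinism is unaffected). The ILP path fixes
the proven cardinality and re-solves minimizing the sum of id ranks — a
deterministic canonical optimum independent of solver internals, though
not guaranteed lexicographically minimal.

**Brute force.** Enumeration by increasing cardinality over at most 25
sets, used purely as the independent oracle in tests and in the
acceptance script.

## Priority levels and gaps

A cell selected by `k ∈ {1..4}` of the four category optima has raw level
`5 − k`. Since the top stratum may be empty (no cell on all four lists),
non-empty strata are renumbered consecutively from Level 1
(`display_level`, default on); both labels are emitted. Level *counts*
derived from recomputed covers are not comparable across software: any
tied optimum changes the union. They are only asserted when the very same
optimal lists are supplied as input.

A priority cell is protected iff its intersection with the dissolved
reserve layer has strictly positive area — a reserve sharing only an edge
does not count, which is the literal reading of "lacking any overlap". An
optional `min_fraction` parameter (default 0) tightens this to a minimum
covered fraction. Gap cells inherit their display level. Monotonicity
(growing the reserve layer never enlarges the gap set) is property-tested.

## Association tests

A species is a *fatal-part user* iff part category I (whole plant, roots,
heartwood) appears among its recorded medicinal parts — the most severe
category wins, and each species is counted once. 2×2 tables are
cross-tabulated from boolean predicates; the chi-square test of
independence (df = 1) is computed by `scipy.stats.chi2_contingency` with
the Yates continuity correction as a per-test flag, the p-value coming
from the chi-square survival function. The published pair of tests is
numerically consistent with Yates for threat × severity (χ² = 0.35,
p = 0.555) and no correction for threat × endemism (χ² = 0.02); the
package defaults to Yates for 2×2 tables and exposes the flag. Tests
cross-check the uncorrected statistic against the closed form
`N(ad − bc)² / ((a+b)(c+d)(a+c)(b+d))` to 1e-10.

## Synthetic landscapes

`SyntheticSpec` defaults describe the study system the package was built
around: 148 species on a 30 × 32 grid (960 cells ≈ the ~943 retained
national cells), occupancy ~ lognormal(μ = 3.0, σ = 1.1) capped at 90 % of
cells (median ≈ 20 cells, most species under 50, a long tail to a few
hundred — expected incidence ≈ 5–6 k pairs), category prevalences
61/148 endemic, 50/148 threatened (CR:EN:VU = 3:15:32), 43/148 protected
(I:II = 16:27), part-category inclusion I 0.34 / II 0.80 / III 0.50,
southward gradient strength 2.0, range cohesion 0.9, reserve fraction
0.30. Ranges grow from a south-biased seed cell into adjacent cells with
probability `cohesion`, otherwise jump; threat log-odds decrease by
`assoc_bias × (log occupancy − mean)` so narrow-ranged species are more
often threatened. Reserves are uniformly chosen cells shrunk 10 %
linearly to sit strictly inside them. One root `SeedSequence` spawns
fixed child streams per component, so outputs are byte-identical per seed
and components do not perturb each other.

What the generator does *not* emulate: real coastline/border geometry
(the boundary is a rectangle, so the landscape has no non-retained
cells unless the caller supplies an irregular boundary), spatial sampling
bias, within-cell abundance, and the real system's large unoccupied
regions (generated landscapes are denser than the ~61 % occupied cells of
the real dataset). Passing synthetic tests therefore demonstrate
algorithmic correctness and pipeline determinism, not geographic
fidelity.

## Problem sizes used in routine checks

Unit and property tests use toy geometries (≤ 9 cells), random cover
instances of ≤ 20 sets (500+ seeds, checked against brute force), planted
instances of known optimum, and an 8 × 8 / 25–30-species landscape for
end-to-end runs. The acceptance script runs the full default-scale
landscape (148 species, 960 cells) with all four categories certified;
the whole script completes in seconds.

## Known limitations

* No reprojection or geodesic areas: inputs must be projected equal-area.
* Unweighted cover only; no budget-limited (maximal-coverage) variant,
  no irreplaceability scores, no simulated-annealing planners.
* Heuristic greedy lists depend on tie order across implementations.
* Exact cell identities of optima are canonical but implementation-
  specific; only cardinalities are cross-software reproducible.
* Sub-national reserves and reserve effectiveness are out of scope; the
  gap definition is binary positive-area overlap.
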