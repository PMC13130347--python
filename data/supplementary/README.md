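# Supplementary study data (not redistributed)

The original study's supplementary tables are not bundled with this
repository. To reproduce the published grid-level results, place the
following recoded CSV files here (schemas match the package's standard
formats):

* `s2_species.csv` — the 148-species master table in the `species.csv`
  schema (`species_id,name,family,genus,endemic,threat,protection,parts`),
  recoded from the published species lists (all / endemic / threatened /
  nationally protected / medicinal-part tables).
* `s7_incidence.csv` — the 6,993 grid-cell presences for all species in the
  `incidence.csv` schema (`species_id,grid_id`).
* `s11_optimal_cells.csv` — the published per-category optimal grid lists,
  long format: `category,grid_id` with category in
  `all|endemic|threatened|protected`.

When present, the tests in `tests/test_acceptance.py` that depend on these
inputs run the full computation against them.
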