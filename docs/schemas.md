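# CSV column dictionary

## Effort table (`effort.csv`) — one row per vessel-day-rectangle

| column | type | meaning |
|---|---|---|
| vessel_id | str | vessel identifier |
| year | int | calendar year of the fishing day |
| quarter | int 1–4 | calendar quarter (Q1 = Jan–Mar) |
| rectangle_code | str | ICES statistical rectangle, e.g. `39F7` |
| lon, lat | float | rectangle centroid, decimal degrees |
| ices_area | str | one of `IVb, IIIa20, IIIa21, IIIc22, IIIb23` |
| mesh_class | str | `<120 mm`, `120-200`, `>200 mm` (dominant mesh by landed weight) |
| vessel_class | str | `<8 m`, `8-10 m`, `10-12 m`, `12-15 m`, `>15 m` |
| population | str | `North Sea Population` or `Western Baltic Population`; a function of ices_area |
| soak_time_h | float > 0 | mean soak time of the net fleets that day (hours) |
| net_length_m | float > 0 | summed net-fleet length that day (metres) |
| depth_m | float > 0 | mean depth of the rectangle (metres) |
| fishing_days | int | always 1 at this resolution |
| pinger_mandatory | bool | whether deterrent use is mandatory for this row |

## EM table (`em.csv`)

All effort columns plus:

| column | type | meaning |
|---|---|---|
| bycatch_count | int ≥ 0 | porpoises bycaught on that vessel-day-rectangle |

## Raw effort input (for `fleetbycatch harmonize`) — one row per landing line

`vessel_id, date (ISO-8601), rectangle_code, mesh_size_mm, landed_weight_kg,
vessel_length_m` and optionally `soak_time_h, net_length_m`.

## Survey input (for `fleetbycatch pbr`)

`year, density (individuals/km^2), cv`.

## Run config (YAML for `fleetbycatch run --config`)

Top-level keys mirror `fleetbycatch.pipeline.RunConfig`: `outdir`, `seed`,
either `sim` + `true_params` or `effort_csv` + `em_csv`, `candidates`,
`stratified_B`, `prediction_B`, `stratified_on_missing`, `pinger_rules`,
`surveys`, `n_override`.

- `sim` keys mirror `SimConfig`: `n_vessels`, `years`,
  `n_days_per_vessel_year`, `em_fraction`, `rectangle_areas`,
  `rectangle_depths`, `mesh_probs`, `vessel_probs`, `soak_meanlog`,
  `soak_sdlog`, `net_meanlog`, `net_sdlog`.
- `true_params` keys mirror `TrueParams`: `beta` (coefficient name → value,
  names as in `fit.json`), `theta`, `sigma_vessel`, `sigma_year`, `sigma_s`,
  `rho`, `spatial_grouping`.
- each `pinger_rules` entry: `ices_areas`, `vessel_classes`, `mesh_classes`
  (optional), `quarters` (optional).

## Run outputs

- `bpue.csv`: quarter, ices_area, observed_days, observed_bycatch, bpue.
- `stratified_strata.csv`: per-stratum fleet days, BPUE and raised total.
- `model_selection.csv`: candidate, spatial_grouping, random_terms,
  n_params, loglik, aicc, delta_aicc, converged, ok.
- `fit.json`: coefficients, dispersion, variance components, convergence
  block, data hash.
- `totals.csv`: grouping columns, plugin, bias_corrected, se, scenario
  (+ ci_low, ci_high, n_bootstrap when the bootstrap is enabled).
- `standardized_effort.csv` / `standardized_bpue.csv`: axis columns, value,
  kind (relative indices; only ratios are meaningful).
- `pbr.csv`: year, density, abundance, cv, n_min, r_max and one column per
  (scheme, recovery-factor) limit.
- `assessment.csv`: per-limit verdicts against the predicted totals.
- `manifest.json`: package version, config hash, stage seeds, row counts,
  convergence flags.
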