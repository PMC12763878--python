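# ltfassay

Analysis toolkit for ex vivo live-tumor-fragment (LTF) immunotherapy
response assays. It covers the full computational pipeline around a
multiplex cytokine readout of cultured tumor fragments:

- **`ltfassay.synthetic_data`** — ground-truth generators: spatial cell
  maps (homogeneous Poisson or Thomas cluster process), specimen cohorts
  with biomarker status and hidden responder flags, and longitudinal
  cumulative-cytokine well series for cross-well and sequential designs.
- **`ltfassay.fragmentation`** — in silico tissue fragmentation: cut a
  cell map into slices or cuboid fragments, pool fragments randomly into
  wells of matched tissue area, and quantify cross-pool count variability
  (CV); closed-form cuboid and core-needle-biopsy slicing geometry.
- **`ltfassay.quantitation`** — assay-level QC: LLOQ/ULOQ censoring,
  exclusion of consistently-undetectable analytes, panel-coverage and
  replicate-CV metrics, OLS rate-of-change.
- **`ltfassay.crosswell_response`** — the resection pipeline: per-specimen
  treated-vs-control cumulative differences, MAD-trimmed modified Z-scores
  saturated to ±10, upregulation calls (Z ≥ 5), Ward clustering, and
  biomarker enrichment (Mann–Whitney U and Fisher exact).
- **`ltfassay.sequential_response`** — the biopsy pipeline: per-phase
  production-rate slopes, slope fold change (treatment/control), banded
  classification (increase > 1.5; no change 0.5–1.5; decrease < 0.5),
  replicate aggregation (max FC, any-replicate increase), cross-design
  concordance, and a RECIST percent-change helper.
- **`ltfassay.io_cli`** — tidy-CSV measurement interchange, panel and
  cell-map files, run configuration, the end-to-end pipeline runner and
  the `ltfassay` CLI.

## CLI

```bash
# simulate a synthetic cohort (measurements.csv + specimens.csv + panel.json)
ltfassay simulate --seed 1 --design crosswell --out-dir sim_out

# QC report on a measurement table
ltfassay qc --measurements sim_out/measurements.csv --out qc.json

# cross-well response pipeline (modified Z-scores, calls, clustering, enrichment)
ltfassay crosswell --measurements sim_out/measurements.csv \
    --specimens sim_out/specimens.csv --out-dir cw_out

# sequential-treatment pipeline (slope fold changes, specimen report)
ltfassay sequential --measurements seq_out/measurements.csv --out-dir sq_out

# fragmentation simulation on a cell-map CSV + mask
ltfassay fragment --points-csv pts.csv --mask mask.json --mode cuboid \
    --edge-um 300 --pool-area-mm2 0.36 --n-pools 8 --seed 1

# full pipeline from a config file
ltfassay report --config examples/demo_config.yaml
```

Measurement tables are long-format CSV/TSV with columns
`specimen_id, well_id, design, phase_start_h, phase_end_h, treatment,
t_h, analyte, conc_pg_ml, censor` (hours and pg/mL throughout).

## Notes on defaults

- Well-to-well CV scales with fragment count as `cv(n) = cv_ref * sqrt(200/n)`
  (an explicit modeling default, overridable via `KineticsSpec`).
- Measurement noise attaches to per-phase accumulation increments by
  default (`KineticsSpec.noise_on="increment"`), keeping simulated
  cumulative curves monotone; `"cumulative"` is available.
- Pools are matched by summed tissue area, not fragment number, when
  comparing fragmentation schemes — otherwise the comparison confounds
  information content.
- "Consistently below LLOQ" defaults to ≥95% of samples; the 20 h phase
  boundary sample belongs to both phase fits; ULOQ-capped points are
  excluded from slope fits.
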