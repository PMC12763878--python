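# Demo pipeline configuration: simulate a small cross-well cohort and run
# the full qc -> response -> enrichment pipeline on it.
seed: 42
design: crosswell
out_dir: demo_out
panel_path: null
measurements_path: null
specimens_path: null
simulate:
  n_specimens: 10
  n_replicates: 3
  biomarker_positive_fraction: 0.4
  responder_prob_given_positive: 0.9
  responder_prob_given_negative: 0.1
  responsive_analytes: [IFNg, CXCL10, IL-2, TNFa]
  effect_theta: 4.0
  well_cv_percent: 20.0
  measurement_cv_percent: 20.0
  ltf_count: 200
stages:
  threshold: 5.0
  saturation: 10.0
  trim_k: 2.0
log_level: WARNING
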