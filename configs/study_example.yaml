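# Example study configuration for `vaxsafety run --study ... --out ...`.
# Databases are directories written by `vaxsafety simulate` (or externally
# supplied CSV tables with the same schema). Negative-control outcome names
# are read from each database's ground_truth.csv when no outcome_definitions
# file lists them.
databases:
  db_a: data/db_a
  db_b: data/db_b
comparisons:
  - name: adeno_vs_mrna_d1
    target_brand: ChAdOx1-S
    target_dose: 1
    comparator_brand: BNT162b2
    comparator_dose: 1
outcomes:
  - thrombocytopenia
  - deep_vein_thrombosis
  - pulmonary_embolism
  - venous_thromboembolism
  - arterial_thromboembolism
tts_definitions:
  - name: any_thrombosis_tts
    thrombo_outcome: venous_thromboembolism
  - name: any_thrombosis_tts_5day
    thrombo_outcome: venous_thromboembolism
    concurrency_window_days: 5
  - name: any_thrombosis_tts_100k
    thrombo_outcome: venous_thromboembolism
    platelet_threshold: 100.0
# diagnostics thresholds (defaults shown)
smd_threshold: 0.1
mdrr_threshold: 5.0
nc_fraction_threshold: 0.20
# 20% subsample convention for very large claims databases
subsample: {}
master_seed: 1
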