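# Demonstration run: 10,000 participants, 200 proteins, ten planted effects
# (three of them subgroup-conditional) and clinical risk gradients emulating a
# middle-aged population cohort with ~4% event incidence over 15 years.
seed: 1
simulation:
  n_participants: 10000
  n_proteins: 200
  weibull_scale: 750.0
  weibull_shape: 1.0
  missing_rate_proteins: 0.01
  missing_rate_clinical: 0.02
  effects:
    # general risk proteins (hazard ratios 1.35-1.67 per SD)
    - {protein_index: 0, log_hr_per_sd: 0.513}
    - {protein_index: 1, log_hr_per_sd: 0.495}
    - {protein_index: 2, log_hr_per_sd: 0.40}
    - {protein_index: 3, log_hr_per_sd: 0.35}
    - {protein_index: 4, log_hr_per_sd: 0.30}
    # a protective marker
    - {protein_index: 5, log_hr_per_sd: -0.371}
    # subgroup-conditional effects: the heterogeneity the stratified
    # models are built to exploit
    - {protein_index: 6, log_hr_per_sd: 0.50, subgroup: female}
    - {protein_index: 7, log_hr_per_sd: 0.50, subgroup: smoking}
    - {protein_index: 8, log_hr_per_sd: 0.50, subgroup: middle_aged}
    - {protein_index: 9, log_hr_per_sd: 0.45, subgroup: non_hdl_high}
  clinical_log_hrs:
    age_per_10y: 0.45
    male: 0.65
    smoking_previous: 0.15
    smoking_current: 0.55
    sbp_per_10mmhg: 0.12
    non_hdl_per_mmol: 0.18
    diabetes: 0.50
prep:
  protein_missing_threshold: 0.25
  derivation_fraction: 0.70
  imputation_method: median
selection:
  auc_epsilon: 0.003
  plateau_length: 4
  delong_alpha: 0.05
evaluation:
  min_derivation_events: 30
  nri_threshold: 0.05
  nri_n_boot: 300
optimism:
  enabled: false
region_cv:
  enabled: false
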