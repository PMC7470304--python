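cohort:
  n_patients: 418
  seed: 0
  prop_male: 0.569
  age_mean: 65.4
  age_sd: 16.6
  comorbidity_prevalences:
    obesity: 0.177
    chf: 0.062
    crf: 0.146
    sahs: 0.081
    tobacco: 0.086
    hypertension: 0.519
    diabetes: 0.237
    copd: 0.098
    other_cardiopathy: 0.148
  baseline_severity_params:
    mean: -2.35
    sd: 1.05
    age_coef: 0.3
    comorbidity_coefs:
      obesity: 0.25
      chf: 0.45
      crf: 0.35
      sahs: 0.2
      tobacco: 0.1
      hypertension: 0.15
      diabetes: 0.2
      copd: 0.4
      other_cardiopathy: 0.2
  trajectory_params:
    drift: -0.3
    drift_sd: 0.0
    noise_sd: 0.15
    device_thresholds:
    - -1.82
    - -0.6
    - 0.19
    - 1.31
    - 2.2
    safi_noise_sd: 0.05
    target_sat_mean: 92.5
    target_sat_sd: 1.5
    vitals_offset_sd:
    - 8.0
    - 6.0
    - 7.0
    vitals_daily_sd:
    - 5.0
    - 4.0
    - 5.0
    discharge_log_base: -11.2
    discharge_severity_coef: 2.2
    death_log_base: 0.0
    death_severity_coef: 1.6
    crp_log_intercept: 3.15
    crp_severity_coef: 0.45
    crp_offset_log_sd: 0.4
    crp_log_sd: 0.25
    crp_missing_rate: 0.1
    xray_gap_min: 2
    xray_gap_max: 6
    xray_center: -2.1
    xray_scale: 0.85
    palliative_fraction_of_deaths: 0.35
  treatment_assignment:
    intercept: 0.55
    severity_coef: 0.85
    severity_ref: -2.35
    comorbidity_coefs: {}
    start_day_probs:
    - 0.55
    - 0.3
    - 0.15
    n_doses: 5
    other_drug_logits:
      interferon:
      - -2.2
      - 0.35
      tocilizumab:
      - -2.8
      - 0.8
      methylprednisolone:
      - -2.9
      - 0.7
      dexamethasone:
      - -2.0
      - 0.5
      heparin:
      - 0.9
      - 0.1
    hcq_lpv_both: 0.828
    hcq_only: 0.05
    lpv_only: 0.03
  true_effect:
    discharge_hazard_ratio: 1.0
    safi_drift: 0.0
  censor_day: 30
criteria:
  exact_binary:
  - sex
  - obesity
  age_window: 15.0
  safi_window:
  - -1.1
  - 2.0
  crp_window:
  - -6.0
  - 4.0
  cotreatment_drugs:
  - hydroxychloroquine
  - lopinavir_ritonavir
  - interferon
  - corticosteroids
  - tocilizumab
  cotreatment_lag: 3
  pool_corticosteroids: true
  ratio: 1
horizons:
- 48
- 72
- 96
welch: false
match_method: greedy
seed: 0
log_level: INFO
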