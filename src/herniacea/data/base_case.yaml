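cohort_size: 707121.0
complication_mortality: 0.2
complication_risk: 0.0056
cost_md: 123.4
cost_surgeon: 132.71
cycle_length: 1.0
disability_weights:
  mild: 0.011
  moderate: 0.114
  none: 0.0
  severe: 0.324
discount_rate: 0.03
half_cycle_correction: true
life_table: ghana2016_male_synthetic_lifetable.csv
pain_recurrent:
  mild: 0.145672
  moderate: 0.200062
  none: 0.33748
  severe: 0.316786
pain_repaired:
  mild: 0.50175
  moderate: 0.00511
  none: 0.49314
  severe: 0.0
pain_untreated:
  mild: 0.145672
  moderate: 0.200062
  none: 0.33748
  severe: 0.316786
repair_rate: 1.0
repair_recurrent: true
risk_contralateral: 0.0038
risk_premature_death: 0.0011200000000000001
risk_recurrent: 0.00376
starting_age: 50
time_horizon: 10
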