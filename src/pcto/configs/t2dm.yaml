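# Type 2 diabetes decision-point configuration.
# Index date: problem-list T2DM diagnosis, else the second of the earliest
# two consecutive HbA1c >= 6.5 readings separated by 1-365 days.  Every
# later encounter with an HbA1c >= 7.0 in the prior 365 days is a DP.
disease: T2DM
study_period: ["2008-01-01", "2018-12-31"]
dp_rule: diagnosis_then_lab
diagnosis_category: T2DM
lab_lookback_days: 365
thresholds:
  - {analyte: HBA1C, op: ge, value: 7.0}
fallback_pair_threshold: {analyte: HBA1C, op: ge, value: 6.5}
fallback_pair_max_separation_days: 365
followup:
  min_days: 90
  max_days: 365
min_age: 18
pregnancy_exclusion_days: 365
pregnancy_codes: [DX_PREGNANCY]
refill_codes: [refill]
decision_buffer_days: 14
treatment_universe:
  - RX_METFORMIN
  - RX_GLYBURIDE
  - RX_GLIPIZIDE
  - RX_GLARGINE
filter_variable_names:
  - Biguanides_Metformin_active
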