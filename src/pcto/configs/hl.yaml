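# Hyperlipidemia decision-point configuration.
# Index date: problem-list HL diagnosis (required).  Every later encounter
# with an LDL > 130 mg/dl in the prior 420 days is a DP.
disease: HL
study_period: ["2008-01-01", "2018-12-31"]
dp_rule: diagnosis_then_lab
diagnosis_category: HL
lab_lookback_days: 420
thresholds:
  - {analyte: LDL, op: gt, value: 130.0}
followup:
  min_days: 30
  max_days: 450
min_age: 18
pregnancy_exclusion_days: 365
pregnancy_codes: [DX_PREGNANCY]
refill_codes: [refill]
decision_buffer_days: 14
treatment_universe:
  - RX_SIMVASTATIN
  - RX_PRAVASTATIN
  - RX_ATORVASTATIN
  - RX_ROSUVASTATIN
filter_variable_names:
  - Statin_Simvastatin_active
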