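# Hypertension decision-point configuration.
# DP rule: the second of two consecutive uncontrolled blood-pressure
# readings (SBP >= 140 or DBP >= 90) separated by 1-365 days.
disease: HTN
study_period: ["2004-01-01", "2018-12-31"]
dp_rule: consecutive_uncontrolled_pair
pair_max_separation_days: 365
thresholds:
  - {analyte: SBP, op: ge, value: 140.0}
  - {analyte: DBP, op: ge, value: 90.0}
followup:
  # first qualifying reading between N and 365 days after the DP;
  # N = 0 when no treatment changed, 14 otherwise (same-day readings
  # never qualify, so the effective no-change window starts at day 1)
  min_days: 0
  alt_min_days: 14
  max_days: 365
min_age: 18
pregnancy_exclusion_days: 365
pregnancy_codes: [DX_PREGNANCY]
refill_codes: [refill]
decision_buffer_days: 14
treatment_universe:
  - RX_LISINOPRIL
  - RX_HYDROCHLOROTHIAZIDE
  - RX_AMLODIPINE
  - RX_METOPROLOL
filter_variable_names:
  - age_60_or_above
  - ACEI_Lisinopril_active
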