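attributes:
- name: orr
  label: Likelihood of responding to treatment
  kind: benefit
  levels:
  - 25%
  - 40%
  - 55%
  - 70%
  - 85%
  reference_index: 0
  numeric_values:
  - 25.0
  - 40.0
  - 55.0
  - 70.0
  - 85.0
- name: dor
  label: Length of time in response
  kind: benefit
  levels:
  - 3 months
  - 6 months
  - 9 months
  - 1 year
  - 1.25 years
  reference_index: 0
  numeric_values:
  - 3.0
  - 6.0
  - 9.0
  - 12.0
  - 15.0
- name: os
  label: Lifespan
  kind: benefit
  levels:
  - 6 months
  - 1 year
  - 1.5 years
  - 2 years
  reference_index: 0
  numeric_values:
  - 6.0
  - 12.0
  - 18.0
  - 24.0
- name: neuropathy
  label: Tingling or pain in hands and/or feet
  kind: risk
  levels:
  - 0%
  - 25%
  - 50%
  reference_index: 0
  numeric_values:
  - 0.0
  - 25.0
  - 50.0
- name: vision
  label: Temporary vision change
  kind: risk
  levels:
  - 0%
  - 20%
  - 40%
  - 60%
  reference_index: 0
  numeric_values:
  - 0.0
  - 20.0
  - 40.0
  - 60.0
- name: crs
  label: Inflammatory response (CRS)
  kind: risk
  levels:
  - high_risk
  - no_risk
  reference_index: 1
  numeric_values:
  - 85.0
  - 0.0
- name: diarrhea
  label: Severe diarrhea
  kind: risk
  levels:
  - 0%
  - 10%
  - 20%
  reference_index: 0
  numeric_values:
  - 0.0
  - 10.0
  - 20.0
- name: administration
  label: Administration
  kind: administration
  levels:
  - iv_sc_twice_weekly
  - iv_sc_q3w
  - iv_sc_weekly_plus_oral
  - iv_sc_monthly_plus_oral
  - car_t
  reference_index: 1
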