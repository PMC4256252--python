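base_age: 55
population_size: 1000000
n_trials: 1000
trial_size: 1000
seed: 0
strategy: screen_and_treat
quota_risk_set: original
life_table_path: null
sex_proportions_path: null
incidence:
  lambda60: 0.001
  doubling_time: 5.0
  sub60_halving_interval: 5.0
screening:
  sensitivity: 0.65
  specificity: 0.95
  horizon_years: 20
  count_censored_conversions: true
treatment:
  rrr_slope: 0.03
  rrr_ceiling: 0.5
  harm_prob: 0.001
  harm_magnitude: 0.06
  discontinuation_rate: 0.05
  prevention_mode: all_or_nothing
progression:
  initial_severity:
  - 0.6
  - 0.4
  - 0.0
  severity_transitions:
  - - 0.614
    - 0.322
    - 0.042
    - 0.021
  - - 0.0
    - 0.565
    - 0.339
    - 0.053
  - - 0.0
    - 0.0
    - 0.847
    - 0.153
  nh_entry:
  - 0.038
  - 0.11
  - 0.259
  ad_utilities:
  - - 0.37
    - 0.52
  - - 0.18
    - 0.21
  - - 0.02
    - 0.0
  no_ad_utilities:
  - 0.872
  - 0.836
  - 0.809
  - 0.775
  age_band_edges:
  - 65
  - 75
  - 85
  discount_rate: 0.03
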