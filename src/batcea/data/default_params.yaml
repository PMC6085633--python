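# Packaged default parameter configuration.
#
# Point values, one-way ranges and sampling distributions are the published
# 2013-EUR inputs of the BAT-vs-OMT cost-utility analysis; the transition
# matrices and utilities below are pre-calibration placeholders (the
# `calibrated: false` flag marks this) and are replaced by the calibration
# step before quantitative use.  Any field may be omitted; omitted fields
# fall back to these defaults.
excess_mortality_6mo:
  II:
    value: 0.04
    period_months: 6.0
    low: 0.032
    high: 0.048
    dist:
    - beta
    - 4
    - 96
  III:
    value: 0.07
    period_months: 6.0
    low: 0.056
    high: 0.084
    dist:
    - beta
    - 7
    - 93
  IV:
    value: 0.28
    period_months: 6.0
    low: 0.224
    high: 0.336
    dist:
    - beta
    - 28
    - 72
p_hosp_monthly:
  I:
    value: 0.015
    period_months: 1.0
    low: 0.008
    high: 0.023
    dist:
    - beta
    - 1.5
    - 98.5
  II:
    value: 0.024
    period_months: 1.0
    low: 0.012
    high: 0.036
    dist:
    - beta
    - 2.4
    - 97.6
  III:
    value: 0.024
    period_months: 1.0
    low: 0.012
    high: 0.036
    dist:
    - beta
    - 2.4
    - 97.6
  IV:
    value: 0.154
    period_months: 1.0
    low: 0.077
    high: 0.23
    dist:
    - beta
    - 15.4
    - 84.6
rr_mortality:
  value: 0.61
  se_log: 0.0467
  low: 0.52
  high: 0.7
rr_hosp:
  value: 0.4
  se_log: 0.18
  low: 0.34
  high: 1.05
routine_cost_yearly:
  I:
    value: 516
    low: 258
    high: 1031
    dist:
    - gamma
    - 1
    - 516
  II:
    value: 910
    low: 455
    high: 1821
    dist:
    - gamma
    - 1
    - 910
  III:
    value: 900
    low: 450
    high: 1800
    dist:
    - gamma
    - 1
    - 900
  IV:
    value: 967
    low: 484
    high: 1935
    dist:
    - gamma
    - 1
    - 967
device:
  cost_system:
    value: 21000
    low: 15000
    high: 24000
    dist:
    - gamma
    - 1
    - 21000
  cost_battery:
    value: 15000
    low: 10000
    high: 17000
    dist:
    - gamma
    - 1
    - 15000
  cost_implant_proc:
    value: 3628
    low: 1814
    high: 5442
    dist:
    - gamma
    - 1
    - 3628
  cost_replacement_proc:
    value: 1808
    low: 904
    high: 2712
    dist:
    - gamma
    - 1
    - 1808
  cost_visits:
    value: 68
    low: 34
    high: 102
    dist:
    - gamma
    - 1
    - 68
  cost_short_term_ae:
    value: 3056
    low: 1528
    high: 4584
    dist:
    - gamma
    - 1
    - 3056
  cost_long_term_ae:
    value: 0
    low: 0
    high: 100
    dist: null
  battery_life_years: 6.0
  battery_life_low: 3.0
  battery_life_high: 6.0
  p_short_term_ae:
    value: 0.07
    period_months: 1.0
    low: 0.03
    high: 0.1
    dist:
    - beta
    - 3
    - 38
  p_serious_ae_6mo:
    value: 0.033
    period_months: 6.0
    low: 0.0
    high: 0.05
    dist:
    - beta
    - 1
    - 29
  p_procedural_death: 0.0
hosp_mix:
  shares:
    icu: 0.072
    ccu: 0.256
    cabg: 0.003
    ptca: 0.002
    transplant: 0.026
    none: 0.623
  costs:
    icu: 5005.0
    ccu: 5004.0
    cabg: 15056.0
    ptca: 3793.0
    transplant: 86337.0
    none: 2740.0
transitions:
  first_cycle:
  - - 0.98
    - 0.02
    - 0.0
    - 0.0
  - - 0.06
    - 0.9199999999999999
    - 0.02
    - 0.0
  - - 0.0
    - 0.06
    - 0.9199999999999999
    - 0.02
  - - 0.0
    - 0.0
    - 0.06
    - 0.94
  subsequent:
  - - 0.98
    - 0.02
    - 0.0
    - 0.0
  - - 0.02
    - 0.96
    - 0.02
    - 0.0
  - - 0.0
    - 0.02
    - 0.96
    - 0.02
  - - 0.0
    - 0.0
    - 0.02
    - 0.98
utilities:
  u1: 0.815
  u2: 0.72
  u3: 0.59
  u4: 0.51
discount_rate_annual: 0.03
cycle_length_months: 1.0
baseline_age_mean: 63.0
baseline_age_low: 50.0
baseline_age_high: 75.0
baseline_male_share: 0.832
baseline_nyha: III
rr_on_total_rate: true
half_cycle_correction: false
calibrated: false
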