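# SYNTHETIC integer risk-score model for 1-year mortality in heart failure.
#
# This is NOT a published score: the point table of the real risk model the
# analysis relies on lives in its own publication and is deliberately not
# transcribed here.  This synthetic stand-in has the same shape (thirteen
# covariates, integer points, monotone score-to-probability link) and is
# used by the test-suite and examples; substitute a real score file with
# the same schema for applied work.
name: synthetic-hf-risk-score
link:
  type: logistic
  intercept: -4.2
  slope: 0.115
points:
  age:
    type: continuous
    bins:
      - [null, 55, 0]
      - [55, 60, 1]
      - [60, 65, 2]
      - [65, 70, 4]
      - [70, 75, 6]
      - [75, 80, 8]
      - [80, null, 10]
  lvef:
    type: continuous
    bins:
      - [null, 20, 7]
      - [20, 25, 6]
      - [25, 30, 4]
      - [30, 35, 3]
      - [35, 40, 2]
      - [40, null, 0]
  nyha:
    type: category
    map: {I: 0, II: 2, III: 5, IV: 8}
  sbp:
    type: continuous
    bins:
      - [null, 110, 4]
      - [110, 120, 3]
      - [120, 130, 2]
      - [130, 140, 1]
      - [140, null, 0]
  creatinine:
    type: continuous
    bins:
      - [null, 90, 0]
      - [90, 110, 1]
      - [110, 130, 2]
      - [130, 150, 3]
      - [150, 170, 4]
      - [170, null, 5]
  bmi:
    type: continuous
    bins:
      - [null, 20, 4]
      - [20, 25, 2]
      - [25, 30, 1]
      - [30, null, 0]
  diabetes: {type: boolean, if_true: 3, if_false: 0}
  beta_blocker: {type: boolean, if_true: 0, if_false: 2}
  acei_arb: {type: boolean, if_true: 0, if_false: 1}
  male: {type: boolean, if_true: 1, if_false: 0}
  smoker: {type: boolean, if_true: 1, if_false: 0}
  copd: {type: boolean, if_true: 2, if_false: 0}
  hf_diagnosis_lt_18mo: {type: boolean, if_true: 2, if_false: 0}
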