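# SYNTHETIC illustrative MICA-style coefficient set, for examples and tests.
# These are NOT the published Gupta MICA regression coefficients; to use the
# published model, transcribe its intercept and coefficients from the
# original source into a file of this shape.
intercept: -5.0
coefficients:
  age_years: 0.02
  asa_3_or_4: 1.0
  creatinine_elevated: 0.6
  functional_status_dependent: 0.9
  procedure_high_risk: 1.3
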