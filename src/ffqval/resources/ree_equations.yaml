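unit: MJ_per_day
equations:
- sex: male
  age_min: 18
  age_max: 30
  weight_coef: 0.0669
  intercept: 2.28
- sex: male
  age_min: 30
  age_max: 60
  weight_coef: 0.0592
  intercept: 2.48
- sex: male
  age_min: 60
  age_max: 200
  weight_coef: 0.0563
  intercept: 2.15
- sex: female
  age_min: 18
  age_max: 30
  weight_coef: 0.0546
  intercept: 2.33
- sex: female
  age_min: 30
  age_max: 60
  weight_coef: 0.0407
  intercept: 2.9
- sex: female
  age_min: 60
  age_max: 200
  weight_coef: 0.0424
  intercept: 2.38
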