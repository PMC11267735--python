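photo_levels:
  starch:
  - 100.0
  - 150.0
  - 225.0
  - 325.0
  protein:
  - 75.0
  - 110.0
  - 150.0
  - 210.0
  vegetable:
  - 50.0
  - 100.0
  - 160.0
  - 250.0
sex_factor:
  male: 1.15
  female: 0.9
age_band_factor:
  18-29: 1.05
  30-39: 1.02
  40-49: 1.0
  50-59: 0.97
  60-69: 0.94
  70+: 0.9
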