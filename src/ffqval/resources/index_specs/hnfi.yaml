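id: HNFI
description: 'Healthy Nordic food index: 6 components, 1 point for intake at or above the cohort
  median, 0 below.'
components:
- name: fish
  groups:
  - fish_seafood
  direction: +
  rule: median
  points:
  - 0
  - 1
- name: cabbages
  groups:
  - cabbages
  direction: +
  rule: median
  points:
  - 0
  - 1
- name: apples_pears
  groups:
  - apples_pears
  direction: +
  rule: median
  points:
  - 0
  - 1
- name: root_vegetables
  groups:
  - root_vegetables
  direction: +
  rule: median
  points:
  - 0
  - 1
- name: rye_wholegrain
  groups:
  - wholegrain_products
  direction: +
  rule: median
  points:
  - 0
  - 1
- name: oatmeal
  groups:
  - oatmeal
  direction: +
  rule: median
  points:
  - 0
  - 1
stratification: none
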