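id: rMED
description: 'Relative Mediterranean diet score: 9 components, tertile 0-2 points, meat and
  dairy reverse-scored, alcohol as a sex-specific moderate-range criterion (2 points inside
  the range, 0 outside).'
components:
- name: fruits_nuts
  groups:
  - fruits_berries
  - apples_pears
  - nuts_seeds
  direction: +
  rule: tertile
  points:
  - 0
  - 1
  - 2
- name: vegetables
  groups:
  - vegetables
  - root_vegetables
  - cabbages
  direction: +
  rule: tertile
  points:
  - 0
  - 1
  - 2
- name: legumes
  groups:
  - legumes
  direction: +
  rule: tertile
  points:
  - 0
  - 1
  - 2
- name: cereals
  groups:
  - wholegrain_products
  - oatmeal
  - refined_grains
  - rice_pasta_noodles
  - breakfast_cereals
  direction: +
  rule: tertile
  points:
  - 0
  - 1
  - 2
- name: fish
  groups:
  - fish_seafood
  direction: +
  rule: tertile
  points:
  - 0
  - 1
  - 2
- name: olive_oil
  groups:
  - vegetable_oils_margarine
  direction: +
  rule: tertile
  points:
  - 0
  - 1
  - 2
- name: meat
  groups:
  - red_meat
  - processed_meat_sausages
  - poultry
  direction: '-'
  rule: tertile
  points:
  - 0
  - 1
  - 2
- name: dairy
  groups:
  - milk
  - soured_milk_products
  - cheese
  direction: '-'
  rule: tertile
  points:
  - 0
  - 1
  - 2
- name: alcohol
  groups:
  - alcoholic_beverages
  rule: range
  range:
    male:
    - 0.07
    - 0.72
    female:
    - 0.04
    - 0.36
  points_in: 2
  points_out: 0
stratification: none
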