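id: PDI
description: 'Overall plant-based diet index: 18 components scored in quintiles 1-5; plant groups
  scored positively, animal groups reverse-scored.'
components:
- name: whole_grains
  groups:
  - wholegrain_products
  - oatmeal
  - breakfast_cereals
  direction: +
  rule: quintile
  points:
  - 1
  - 2
  - 3
  - 4
  - 5
- name: fruits
  groups:
  - fruits_berries
  - apples_pears
  direction: +
  rule: quintile
  points:
  - 1
  - 2
  - 3
  - 4
  - 5
- name: vegetables
  groups:
  - vegetables
  - cabbages
  direction: +
  rule: quintile
  points:
  - 1
  - 2
  - 3
  - 4
  - 5
- name: root_vegetables
  groups:
  - root_vegetables
  direction: +
  rule: quintile
  points:
  - 1
  - 2
  - 3
  - 4
  - 5
- name: nuts
  groups:
  - nuts_seeds
  direction: +
  rule: quintile
  points:
  - 1
  - 2
  - 3
  - 4
  - 5
- name: legumes
  groups:
  - legumes
  direction: +
  rule: quintile
  points:
  - 1
  - 2
  - 3
  - 4
  - 5
- name: vegetable_oils
  groups:
  - vegetable_oils_margarine
  direction: +
  rule: quintile
  points:
  - 1
  - 2
  - 3
  - 4
  - 5
- name: tea_coffee
  groups:
  - coffee_tea
  direction: +
  rule: quintile
  points:
  - 1
  - 2
  - 3
  - 4
  - 5
- name: fruit_juices
  groups:
  - fruit_juices
  direction: +
  rule: quintile
  points:
  - 1
  - 2
  - 3
  - 4
  - 5
- name: plant_based_alternatives
  groups:
  - plant_based_dairy
  - vegetarian_substitutes
  direction: +
  rule: quintile
  points:
  - 1
  - 2
  - 3
  - 4
  - 5
- name: refined_grains
  groups:
  - refined_grains
  - rice_pasta_noodles
  direction: +
  rule: quintile
  points:
  - 1
  - 2
  - 3
  - 4
  - 5
- name: potatoes
  groups:
  - potatoes
  direction: +
  rule: quintile
  points:
  - 1
  - 2
  - 3
  - 4
  - 5
- name: sugar_sweetened_beverages
  groups:
  - sugar_sweetened_beverages
  direction: +
  rule: quintile
  points:
  - 1
  - 2
  - 3
  - 4
  - 5
- name: sweets_desserts
  groups:
  - sweets_desserts
  direction: +
  rule: quintile
  points:
  - 1
  - 2
  - 3
  - 4
  - 5
- name: animal_fat
  groups:
  - butter_animal_fats
  direction: '-'
  rule: quintile
  points:
  - 1
  - 2
  - 3
  - 4
  - 5
- name: dairy
  groups:
  - milk
  - soured_milk_products
  - cheese
  direction: '-'
  rule: quintile
  points:
  - 1
  - 2
  - 3
  - 4
  - 5
- name: eggs
  groups:
  - eggs
  direction: '-'
  rule: quintile
  points:
  - 1
  - 2
  - 3
  - 4
  - 5
- name: meat_fish
  groups:
  - red_meat
  - processed_meat_sausages
  - poultry
  - fish_seafood
  direction: '-'
  rule: quintile
  points:
  - 1
  - 2
  - 3
  - 4
  - 5
stratification: none
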