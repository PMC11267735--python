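vegetables:
- veg_leafy_greens
- veg_tomatoes
- veg_cucumber
- veg_peppers
- veg_onion_garlic
- veg_avocado
- veg_sweetcorn
- veg_mixed
root_vegetables:
- root_carrots
- root_beetroot
- root_other
cabbages:
- cab_white_cabbage
- cab_broccoli
- cab_cauliflower
legumes:
- leg_beans
- leg_lentils
- leg_peas
- leg_hummus
- leg_soy_edamame
potatoes:
- pot_boiled
- pot_fried
- pot_mashed
fruits_berries:
- fruit_citrus
- fruit_banana
- fruit_berries
- fruit_grapes
- fruit_dried
- fruit_other
apples_pears:
- fruit_apple_pear
fruit_juices:
- juice_orange
- juice_other
nuts_seeds:
- nuts_mixed
- nuts_peanuts
- nuts_seeds
wholegrain_products:
- wg_crispbread
- wg_bread
- wg_pasta
- wg_rice
- wg_bulgur
oatmeal:
- oat_porridge
- oat_other_porridge
refined_grains:
- ref_white_bread
- ref_buns
- ref_crackers
- ref_pancakes
rice_pasta_noodles:
- rpn_white_rice
- rpn_pasta
- rpn_noodles
- rpn_couscous
breakfast_cereals:
- cer_flakes
- cer_muesli
milk:
- milk_whole
- milk_semi
- milk_skimmed
soured_milk_products:
- sour_filmjolk
- sour_yoghurt
- sour_flavoured
cheese:
- cheese_hard
- cheese_soft
- cheese_cottage
plant_based_dairy:
- pb_oat_drink
- pb_soy_drink
- pb_yoghurt
butter_animal_fats:
- fat_butter_bread
- fat_butter_cooking
- fat_cream
vegetable_oils_margarine:
- oil_olive
- oil_rapeseed
- oil_margarine_bread
- oil_liquid_margarine
eggs:
- egg_boiled_fried
- egg_dishes
red_meat:
- meat_beef
- meat_pork
- meat_lamb_game
- meat_minced_dishes
processed_meat_sausages:
- proc_sausages
- proc_cold_cuts
- proc_bacon
- proc_liver_pate
poultry:
- poultry_chicken
- poultry_other
fish_seafood:
- fish_fatty
- fish_lean
- fish_shellfish
- fish_dishes
- fish_tuna_canned
- fish_caviar_roe
vegetarian_substitutes:
- vsub_burgers
- vsub_soy_mince
- vsub_tofu_quorn
sweets_desserts:
- sweet_chocolate
- sweet_candy
- sweet_ice_cream
- sweet_cakes
- sweet_buns
- sweet_desserts_other
- sweet_jam_honey
sugar_sweetened_beverages:
- ssb_soft_drinks
- ssb_energy_drinks
- ssb_squash
coffee_tea:
- bev_coffee
- bev_tea
- bev_herbal_tea
alcoholic_beverages:
- alc_beer
- alc_wine
- alc_spirits
- alc_cider
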