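# Default component targets and thresholds for the six diet-quality indices.
# These constants are package defaults transcribed or adapted from the source
# instruments (Gunther DASH score with NHLBI eating-plan levels, Loma Linda
# vegetarian food-guide pyramid, HEIFA-2013, 14-item MEDAS, PREDIMED-Plus
# 17-item screener).  Every number here is overridable: pass a modified
# config to the scorers or point the CLI at an edited copy of this file.

dash:
  scale_max: 80
  lowfat_share_target: 0.75        # fraction of dairy required to be low fat
  components:
    # six 10-point proportional components; targets are serves/day at each
    # assigned calorie level (kcal)
    fruits:
      max_points: 10
      direction: forward
      tags: [fruit, fruit_juice]
      targets: {1600: 4.0, 2000: 4.5, 2600: 5.5, 3100: 6.0}
    vegetables:
      max_points: 10
      direction: forward
      tags: [vegetable, potato]
      targets: {1600: 3.5, 2000: 4.5, 2600: 5.5, 3100: 6.0}
    meat_poultry_fish_eggs:
      max_points: 10
      direction: reverse
      tags: [red_meat, processed_meat, poultry, fish, egg]
      targets: {1600: 1.75, 2000: 2.0, 2600: 2.0, 3100: 2.5}
    nuts_seeds_legumes:
      max_points: 10
      direction: forward
      tags: [nut_seed, legume, soy]
      targets: {1600: 0.43, 2000: 0.64, 2600: 1.0, 3100: 1.0}
    fats_oils:
      max_points: 10
      direction: reverse
      tags: [oil_olive, oil_vegetable, butter]
      targets: {1600: 2.0, 2000: 2.5, 2600: 3.0, 3100: 4.0}
    sweets:
      max_points: 10
      direction: reverse
      tags: [sweets]
      # NHLBI lists 0 sweets/week at 1600 kcal; a small positive limit keeps
      # reverse-proportional scoring continuous at that level
      targets: {1600: 0.43, 2000: 0.71, 2600: 2.0, 3100: 2.0}
    # four 5-point grain/dairy components
    total_dairy:
      max_points: 5
      direction: forward
      tags: [dairy]
      targets: {1600: 2.0, 2000: 2.0, 2600: 3.0, 3100: 3.0}
    lowfat_dairy_share:
      max_points: 5
      direction: share        # special rule: low-fat fraction of total dairy
      tags: [dairy_lowfat]
      targets: {1600: 1.0, 2000: 1.0, 2600: 1.0, 3100: 1.0}
    whole_grains:
      max_points: 5
      direction: forward
      tags: [wholegrain]
      targets: {1600: 3.0, 2000: 4.0, 2600: 5.0, 3100: 6.0}
    high_fibre_grains:
      max_points: 5
      direction: forward
      tags: [high_fibre_grain]
      targets: {1600: 1.5, 2000: 2.0, 2600: 2.5, 3100: 3.0}

vegetarian:
  scale_max: 14
  reference_energy_kj: 8368.0      # 2000 kcal; serves standardised to this
  diet_components:
    # forward: 1 point at >= full serves/day, 0.5 at >= half, else 0
    # reverse: 1 point at <= full limit, 0.5 at <= half limit, else 0
    whole_grains:   {direction: forward, tags: [wholegrain],                       full: 3.0,  half: 1.5}
    legumes_soy:    {direction: forward, tags: [legume, soy],                      full: 1.5,  half: 0.75}
    vegetables:     {direction: forward, tags: [vegetable],                        full: 3.0,  half: 1.5}
    fruits:         {direction: forward, tags: [fruit],                            full: 2.0,  half: 1.0}
    nuts_seeds:     {direction: forward, tags: [nut_seed],                         full: 1.0,  half: 0.5}
    vegetable_oils: {direction: forward, tags: [oil_olive, oil_vegetable],         full: 1.0,  half: 0.5}
    dairy:          {direction: reverse, tags: [dairy],                            full: 1.0,  half: 2.0}
    eggs:           {direction: reverse, tags: [egg],                              full: 0.5,  half: 1.0}
    sweets:         {direction: reverse, tags: [sweets],                           full: 0.5,  half: 1.0}
    flesh_foods:    {direction: reverse, tags: [red_meat, processed_meat, poultry, fish], full: 0.0, half: 0.5}
  water_full_fraction: 0.5
  water_half_fraction: 0.25

heifa:
  scale_max: 100
  components:
    vegetables:
      quantity_max: 5
      quantity_target: 5.0         # serves/day
      tags: [vegetable]
      variety_max: 5
      variety_target: 5            # distinct vegetable items consumed
    fruit:
      quantity_max: 5
      quantity_target: 2.0
      tags: [fruit]
      variety_max: 5
      variety_target: 2
    grains:
      quantity_max: 5
      quantity_target: 6.0
      tags: [wholegrain, refined_grain]
      wholegrain_max: 5
      wholegrain_share_target: 0.5 # >=50% of grains wholegrain for full points
      wholegrain_tags: [wholegrain]
    dairy:
      max_points: 10
      target: 2.5
      tags: [dairy]
    meat_alternatives:
      max_points: 10
      target: 2.5
      tags: [red_meat, poultry, fish, egg, legume, nut_seed, soy]
    discretionary:
      max_points: 10
      full_below: 0.5              # serves/day
      zero_at: 3.0
      tags: [discretionary]
    saturated_fat:
      max_points: 10
      full_below_pct_energy: 10.0
      zero_at_pct_energy: 15.0
    added_sugar:
      max_points: 10
      full_below_pct_energy: 15.0
      zero_at_pct_energy: 20.0
    sodium:
      max_points: 10
      full_below_mg: 920.0
      zero_at_mg: 3200.0
    water:
      max_points: 5
      full_fraction: 0.5
    alcohol:
      max_points: 5
      max_serves_day: 2.0
      tags: [alcohol]

medas:
  scale_max: 14
  criteria:
    - {name: olive_oil_main_fat,           kind: bool}
    - {name: olive_oil_tbsp_day,           kind: ge, threshold: 4}
    - {name: vegetables_serves_day,        kind: ge, threshold: 2}
    - {name: fruit_serves_day,             kind: ge, threshold: 3}
    - {name: red_processed_meat_serves_day, kind: lt, threshold: 1}
    - {name: butter_cream_serves_day,      kind: lt, threshold: 1}
    - {name: ssb_serves_day,               kind: lt, threshold: 1}
    - {name: wine_glasses_week,            kind: ge, threshold: 7}
    - {name: legumes_serves_week,          kind: ge, threshold: 3}
    - {name: fish_serves_week,             kind: ge, threshold: 3}
    - {name: commercial_sweets_week,       kind: lt, threshold: 3}
    - {name: nuts_serves_week,             kind: ge, threshold: 3}
    - {name: prefers_white_meat,           kind: bool}
    - {name: sofrito_week,                 kind: ge, threshold: 2}

ermeddiet:
  scale_max: 17
  criteria:
    # the 14-item set minus the olive-oil quantity question, plus one
    # wholegrain item, two refined-grain/white-bread items and the
    # no-added-sugar-in-tea/coffee item
    - {name: olive_oil_main_fat,           kind: bool}
    - {name: vegetables_serves_day,        kind: ge, threshold: 2}
    - {name: fruit_serves_day,             kind: ge, threshold: 3}
    - {name: red_processed_meat_serves_day, kind: lt, threshold: 1}
    - {name: butter_cream_serves_day,      kind: lt, threshold: 1}
    - {name: ssb_serves_day,               kind: lt, threshold: 1}
    - {name: wine_glasses_week,            kind: ge, threshold: 7}
    - {name: legumes_serves_week,          kind: ge, threshold: 3}
    - {name: fish_serves_week,             kind: ge, threshold: 3}
    - {name: commercial_sweets_week,       kind: lt, threshold: 3}
    - {name: nuts_serves_week,             kind: ge, threshold: 3}
    - {name: prefers_white_meat,           kind: bool}
    - {name: sofrito_week,                 kind: ge, threshold: 2}
    - {name: wholegrain_serves_day,        kind: ge, threshold: 2}
    - {name: white_bread_serves_day,       kind: lt, threshold: 1}
    - {name: refined_rice_pasta_week,      kind: lt, threshold: 3}
    - {name: no_sugar_in_tea_coffee,       kind: bool}
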