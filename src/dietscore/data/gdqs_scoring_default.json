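{
  "_comment": "Illustrative GDQS scoring table. Gram/day cut-offs define left-closed right-open consumption categories; each category maps to a point value. The structure (25 groups: 16 healthy, 7 unhealthy, 2 unhealthy-in-excess; maxima 32 + 17 = 49) is the published one; the cut-off and point values here are field-plausible placeholders that users should replace with their preferred published table.",
  "groups": [
    {"name": "dark_green_leafy_vegetables", "role": "healthy", "cutoffs": [13, 37], "points": [0, 2, 4]},
    {"name": "cruciferous_vegetables", "role": "healthy", "cutoffs": [13, 36], "points": [0, 0.5, 1]},
    {"name": "deep_orange_vegetables", "role": "healthy", "cutoffs": [9, 45], "points": [0, 0.5, 1]},
    {"name": "other_vegetables", "role": "healthy", "cutoffs": [23, 114], "points": [0, 0.5, 1]},
    {"name": "deep_orange_fruits", "role": "healthy", "cutoffs": [25, 122], "points": [0, 0.5, 1]},
    {"name": "citrus_fruits", "role": "healthy", "cutoffs": [24, 69], "points": [0, 0.5, 1]},
    {"name": "other_fruits", "role": "healthy", "cutoffs": [27, 107], "points": [0, 1, 2]},
    {"name": "legumes", "role": "healthy", "cutoffs": [9, 42], "points": [0, 2, 4]},
    {"name": "deep_orange_tubers", "role": "healthy", "cutoffs": [12, 63], "points": [0, 0.5, 1]},
    {"name": "nuts_seeds", "role": "healthy", "cutoffs": [7, 13], "points": [0, 2, 4]},
    {"name": "whole_grains", "role": "healthy", "cutoffs": [8, 13], "points": [0, 1, 2]},
    {"name": "liquid_oils", "role": "healthy", "cutoffs": [2, 7.5], "points": [0, 1, 2]},
    {"name": "fish_shellfish", "role": "healthy", "cutoffs": [14, 71], "points": [0, 1, 2]},
    {"name": "poultry_game_meat", "role": "healthy", "cutoffs": [16, 44], "points": [0, 1, 2]},
    {"name": "low_fat_dairy", "role": "healthy", "cutoffs": [33, 132], "points": [0, 1, 2]},
    {"name": "eggs", "role": "healthy", "cutoffs": [6, 32], "points": [0, 1, 2]},
    {"name": "white_roots_tubers", "role": "unhealthy", "cutoffs": [27, 107], "points": [2, 1, 0]},
    {"name": "processed_meat", "role": "unhealthy", "cutoffs": [9, 30], "points": [2, 1, 0]},
    {"name": "refined_grains_baked_goods", "role": "unhealthy", "cutoffs": [7, 33], "points": [2, 1, 0]},
    {"name": "sugar_sweetened_beverages", "role": "unhealthy", "cutoffs": [57, 180], "points": [2, 1, 0]},
    {"name": "juice", "role": "unhealthy", "cutoffs": [36, 144], "points": [2, 1, 0]},
    {"name": "sweets_ice_cream", "role": "unhealthy", "cutoffs": [13, 37], "points": [2, 1, 0]},
    {"name": "purchased_deep_fried_foods", "role": "unhealthy", "cutoffs": [9, 45], "points": [2, 1, 0]},
    {"name": "red_meat", "role": "unhealthy_excess", "cutoffs": [9, 46], "points": [1, 1.5, 0]},
    {"name": "high_fat_dairy", "role": "unhealthy_excess", "cutoffs": [35, 142], "points": [1, 1.5, 0]}
  ]
}
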