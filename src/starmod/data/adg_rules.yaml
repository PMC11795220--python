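# Core/discretionary rule set mirroring the logic of the national
# Discretionary Food List: plain category verdicts plus nutrient criteria
# for categories where the guidelines give only examples.
#
# This is a seeded, extensible configuration — the complete official list
# is licensed and must be supplied by the user for production use. The
# breakfast-cereal sugar criterion is the canonical worked example:
# discretionary at >=30 g sugars/100 g without added fruit, or
# >=35 g sugars/100 g with added fruit (inclusive thresholds).
#
# Resolution order: subcategory key first, then major_category key. Within
# a "criteria" entry, predicates are evaluated in order, first match wins,
# otherwise the declared default verdict applies. Predicate condition
# flags: require_flag / forbid_flag test product flags (e.g. added_fruit).

rules:
  # --- subcategory criteria -------------------------------------------
  breakfast cereal:
    verdict: criteria
    default: core
    criteria:
      - id: cereal_sugar_added_fruit
        require_flag: added_fruit
        nutrient: total_sugars_g
        op: ">="
        threshold: 35
        verdict: discretionary
      - id: cereal_sugar_no_added_fruit
        forbid_flag: added_fruit
        nutrient: total_sugars_g
        op: ">="
        threshold: 30
        verdict: discretionary

  # --- subcategory overrides ------------------------------------------
  cake: {verdict: always_discretionary}
  sweet biscuit: {verdict: always_discretionary}
  ice cream: {verdict: always_discretionary}
  dairy dessert: {verdict: always_discretionary}
  soft drink: {verdict: always_discretionary}
  diet soft drink: {verdict: always_discretionary}
  cordial: {verdict: always_discretionary}
  energy drink: {verdict: always_discretionary}
  potato chips: {verdict: always_discretionary}
  corn chips: {verdict: always_discretionary}
  sausages: {verdict: always_discretionary}
  bacon: {verdict: always_discretionary}
  butter: {verdict: always_discretionary}
  jam: {verdict: always_discretionary}
  mayonnaise: {verdict: always_discretionary}
  crumbed seafood: {verdict: always_discretionary}
  instant noodles: {verdict: always_discretionary}

  # --- major-category defaults ----------------------------------------
  Bread and bakery products: {verdict: always_core}
  Cereal and grain products: {verdict: always_core}
  Confectionery: {verdict: always_discretionary}
  Convenience foods: {verdict: always_core}
  Dairy: {verdict: always_core}
  Edible oils and oil emulsions: {verdict: always_core}
  Egg and egg products: {verdict: always_core}
  Foods for specific dietary use: {verdict: always_discretionary}
  Fruit, vegetables, nuts and legumes: {verdict: always_core}
  Meat and meat alternatives: {verdict: always_core}
  Non-alcoholic beverages: {verdict: always_core}
  Sauces, dressings, spreads and dips: {verdict: always_core}
  Seafood and seafood products: {verdict: always_core}
  Snack foods: {verdict: always_discretionary}
  Sugar, honey and related products: {verdict: always_discretionary}
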