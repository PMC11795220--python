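# Deterministic mapping from retail subcategory to the six-way Health Star
# Rating scoring category. Matching is case-insensitive on the trimmed
# subcategory string; an explicit per-product hsr_category always wins.
# Extend freely — unmapped subcategories raise a configuration error rather
# than guessing.
subcategories:
  nonDairyBeverage:
    - still water
    - sparkling water
    - soft drink
    - diet soft drink
    - fruit juice
    - vegetable juice
    - cordial
    - iced tea
    - energy drink
    - sports drink
    - plant-based milk
    - coffee beverage
  dairyBeverage:
    - plain milk
    - flavoured milk
    - milk-based drink
    - drinking yoghurt
  oilsAndSpreads:
    - olive oil
    - vegetable oil
    - canola oil
    - coconut oil
    - margarine
    - butter
    - dairy blend spread
  cheese:
    - cheddar cheese
    - processed cheese
    - soft cheese
    - hard cheese
    - cream cheese
  otherDairy:
    - yoghurt
    - flavoured yoghurt
    - dairy dessert
    - custard
    - cream
    - ice cream
  otherNonDairy:
    - pita bread
    - sliced bread
    - wholemeal bread
    - bread roll
    - cake
    - sweet biscuit
    - savoury biscuit
    - breakfast cereal
    - muesli
    - oats
    - rice
    - pasta
    - flour
    - chocolate
    - lollies
    - frozen meal
    - canned soup
    - instant noodles
    - eggs
    - egg product
    - protein ball
    - protein bar
    - meal replacement
    - canned vegetables
    - canned fruit
    - fresh produce
    - nuts
    - dried fruit
    - legumes
    - sausages
    - bacon
    - plant-based meat
    - fresh meat
    - tomato sauce
    - mayonnaise
    - nut butter
    - dip
    - jam
    - canned fish
    - fresh fish
    - crumbed seafood
    - potato chips
    - corn chips
    - popcorn
    - snack bar
    - sugar
    - honey
    - syrup
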