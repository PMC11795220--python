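# Marker lexicon for the ingredient-based (adapted NOVA) ultra-processing
# classifier. A product is classified ultra-processed when at least one
# ingredient-list token matches a marker term or additive code, after the
# exemption check.
#
# Seeded with the marker classes and every exemplar the rule structure
# names, plus common additive-class synonyms and ANZ/INS additive codes.
# This is an extensible starting point, not an exhaustive list: supply a
# fuller lexicon as config for production classification. Entries such as
# "natural flavour" vs "flavour" are both present and flagged for review.
#
# Matching is case-insensitive on punctuation-stripped, whitespace-collapsed
# text; a term matches when it appears as a whole-word phrase inside a
# token. Exempt terms win over marker terms on the same token.

marker_terms:
  # cosmetic additive classes
  anti caking agent: anti_caking_agent
  anticaking agent: anti_caking_agent
  firming agent: firming_agent
  glazing agent: glazing_agent
  colour: colour
  color: colour
  colours: colour
  colors: colour
  flavour: flavour
  flavor: flavour
  flavours: flavour
  flavors: flavour
  flavouring: flavour
  flavoring: flavour
  natural flavour: flavour   # review: ambiguous vs plain "flavour"
  natural flavor: flavour
  flavour enhancer: flavour
  flavor enhancer: flavour
  emulsifier: emulsifier
  emulsifiers: emulsifier
  lecithin: emulsifier
  mono and diglycerides: emulsifier
  polysorbate: emulsifier
  extract: extract
  extracts: extract
  thickener: thickener
  thickeners: thickener
  modified starch: thickener
  xanthan gum: thickener
  guar gum: thickener
  carrageenan: thickener
  pectin: thickener
  # sweeteners other than sugar, maple syrup and honey
  dextrose: non_exempt_sweetener
  fructose: non_exempt_sweetener
  glucose: non_exempt_sweetener
  glucose syrup: non_exempt_sweetener
  corn syrup: non_exempt_sweetener
  maltodextrin: non_exempt_sweetener
  maltitol: non_exempt_sweetener
  sorbitol: non_exempt_sweetener
  xylitol: non_exempt_sweetener
  mannitol: non_exempt_sweetener
  erythritol: non_exempt_sweetener
  isomalt: non_exempt_sweetener
  aspartame: non_exempt_sweetener
  sucralose: non_exempt_sweetener
  acesulfame: non_exempt_sweetener
  saccharin: non_exempt_sweetener
  stevia: non_exempt_sweetener
  steviol glycosides: non_exempt_sweetener
  # whole-food components included as isolates
  lactose: isolate
  wheat gluten: isolate
  triglycerides: isolate
  milk solids: isolate
  whey: isolate
  casein: isolate
  caseinate: isolate
  isolate: isolate
  # protein powders
  protein powder: protein_powder
  protein concentrate: protein_powder
  pea protein: protein_powder
  soy protein: protein_powder

exempt_terms:
  - sugar
  - maple syrup
  - honey
  - vitamin
  - vitamins
  - mineral
  - minerals
  - live cultures
  - cultures
  - culture
  - acid
  - acids
  - acidity regulator
  - acidity regulators

additive_code_map:
  # colours
  "100": colour
  "102": colour
  "110": colour
  "120": colour
  "122": colour
  "124": colour
  "129": colour
  "133": colour
  "150a": colour
  "150c": colour
  "150d": colour
  "155": colour
  "160a": colour
  "160b": colour
  "162": colour
  "163": colour
  "171": colour
  # flavour enhancers
  "620": flavour
  "621": flavour
  "627": flavour
  "631": flavour
  "635": flavour
  # emulsifiers
  "322": emulsifier
  "433": emulsifier
  "435": emulsifier
  "471": emulsifier
  "472e": emulsifier
  "476": emulsifier
  "481": emulsifier
  "491": emulsifier
  # thickeners and modified starches
  "407": thickener
  "410": thickener
  "412": thickener
  "414": thickener
  "415": thickener
  "440": thickener
  "460": thickener
  "461": thickener
  "464": thickener
  "466": thickener
  "1400": thickener
  "1404": thickener
  "1412": thickener
  "1414": thickener
  "1420": thickener
  "1422": thickener
  "1442": thickener
  "1450": thickener
  # non-exempt sweeteners
  "420": non_exempt_sweetener
  "950": non_exempt_sweetener
  "951": non_exempt_sweetener
  "952": non_exempt_sweetener
  "953": non_exempt_sweetener
  "954": non_exempt_sweetener
  "955": non_exempt_sweetener
  "960": non_exempt_sweetener
  "961": non_exempt_sweetener
  "965": non_exempt_sweetener
  "966": non_exempt_sweetener
  "967": non_exempt_sweetener
  "968": non_exempt_sweetener
  # anti-caking agents
  "535": anti_caking_agent
  "551": anti_caking_agent
  "552": anti_caking_agent
  "553": anti_caking_agent
  "554": anti_caking_agent
  # glazing agents
  "901": glazing_agent
  "903": glazing_agent
  "904": glazing_agent
  "914": glazing_agent
  # firming agents
  "509": firming_agent
  "516": firming_agent
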