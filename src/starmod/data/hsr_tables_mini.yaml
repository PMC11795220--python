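# Miniature scoring tables with single-digit cut-points, for hand-verifiable
# unit tests only. Not a real rating configuration.
version: "mini-test-1"

baseline:
  default:
    energy_kj: [100, 200, 300]
    sat_fat_g: [1, 2, 3]
    total_sugars_g: [5, 10, 15]
    sodium_mg: [100, 200, 300]
  overrides:
    nonDairyBeverage:
      # beverages judged on a finer energy scale in this toy config
      energy_kj: [50, 100, 150]

modifying:
  default:
    fvnl_pct: [40, 60, 80]
    protein_g: [5, 10]
    fibre_g: [2, 4]

protein_eligibility:
  baseline_cap: 4
  min_fvnl_points: 2
  exempt_categories: [cheese]

star_matrix:
  nonDairyBeverage: &mini_matrix
    - {max_score: -1, stars: 5.0}
    - {max_score: 1, stars: 4.5}
    - {max_score: 3, stars: 4.0}
    - {max_score: 5, stars: 3.5}
    - {max_score: 7, stars: 3.0}
    - {max_score: 9, stars: 2.5}
    - {max_score: 11, stars: 2.0}
    - {max_score: 13, stars: 1.5}
    - {max_score: 15, stars: 1.0}
    - {max_score: null, stars: 0.5}
  dairyBeverage: *mini_matrix
  oilsAndSpreads: *mini_matrix
  cheese: *mini_matrix
  otherDairy: *mini_matrix
  otherNonDairy: *mini_matrix
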