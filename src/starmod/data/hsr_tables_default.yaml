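# Default Health Star Rating scoring tables.
#
# RECONSTRUCTION NOTICE: these values are a reconstructed transcription of
# the publicly documented point-scoring structure of the government Health
# Star Rating calculator (NPSC-derived baseline/modifying point tables
# shared across the six scoring categories, category-specific star
# conversion matrices). They are intended for research and testing; anyone
# producing ratings for regulatory or labelling use must substitute tables
# transcribed from the current official "Guide for Industry to the Health
# Star Rating Calculator" — the engine treats this file as opaque,
# validated configuration.
#
# Semantics: for each component, points = number of cut-points the value
# STRICTLY exceeds ("more than"). Star matrix bands are inclusive upper
# bounds on the final score, in increasing order; the last band
# (max_score: null) catches everything above.
version: "starmod-default-2025 (reconstructed transcription; not the official asset)"

baseline:
  default:
    # kJ per 100 g; 1 point per 335 kJ step, 11 points maximum
    energy_kj: [335, 670, 1005, 1340, 1675, 2010, 2345, 2680, 3015, 3350, 3685]
    # g per 100 g; 30 points maximum
    sat_fat_g: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10,
                11.2, 12.5, 13.9, 15.5, 17.3, 19.3, 21.6, 24.1, 26.9, 30,
                33.5, 37.4, 41.7, 46.6, 52, 58, 64.7, 72.3, 80.6, 90]
    # g per 100 g; 22 points maximum
    total_sugars_g: [5, 8.9, 12.8, 16.8, 20.7, 24.6, 28.5, 32.4, 36.3, 40.3,
                     44.2, 48.1, 52, 55.9, 59.8, 63.8, 67.7, 71.6, 75.5, 79.4,
                     83.3, 87.3]
    # mg per 100 g; 30 points maximum
    sodium_mg: [90, 180, 270, 360, 450, 540, 630, 720, 810, 900,
                1005, 1121, 1251, 1397, 1559, 1740, 1942, 2167, 2418, 2700,
                3013, 3363, 3753, 4188, 4674, 5216, 5821, 6497, 7251, 8092]

modifying:
  default:
    # percent fruit/vegetable/nut/legume; 8 points maximum
    fvnl_pct: [25, 43, 52, 63, 67, 80, 90, 95]
    # g per 100 g; 15 points maximum
    protein_g: [1.6, 3.2, 4.8, 6.4, 8.0, 9.6, 11.6, 13.9, 16.7, 20,
                24, 28.9, 34.7, 41.6, 50]
    # g per 100 g; 15 points maximum
    fibre_g: [0.9, 1.9, 2.8, 3.7, 4.7, 5.4, 6.3, 7.3, 8.4, 9.7,
              11.2, 13, 15, 17.3, 20]

protein_eligibility:
  # with >= baseline_cap baseline points, protein points need
  # >= min_fvnl_points FVNL points; cheese is exempt from the gate
  baseline_cap: 13
  min_fvnl_points: 5
  exempt_categories: [cheese]

star_matrix:
  nonDairyBeverage:
    - {max_score: -6, stars: 5.0}
    - {max_score: -4, stars: 4.5}
    - {max_score: -2, stars: 4.0}
    - {max_score: 0, stars: 3.5}
    - {max_score: 1, stars: 3.0}
    - {max_score: 2, stars: 2.5}
    - {max_score: 3, stars: 2.0}
    - {max_score: 4, stars: 1.5}
    - {max_score: 5, stars: 1.0}
    - {max_score: null, stars: 0.5}
  dairyBeverage:
    - {max_score: -2, stars: 5.0}
    - {max_score: -1, stars: 4.5}
    - {max_score: 0, stars: 4.0}
    - {max_score: 1, stars: 3.5}
    - {max_score: 3, stars: 3.0}
    - {max_score: 5, stars: 2.5}
    - {max_score: 7, stars: 2.0}
    - {max_score: 9, stars: 1.5}
    - {max_score: 11, stars: 1.0}
    - {max_score: null, stars: 0.5}
  oilsAndSpreads:
    - {max_score: 13, stars: 5.0}
    - {max_score: 16, stars: 4.5}
    - {max_score: 20, stars: 4.0}
    - {max_score: 24, stars: 3.5}
    - {max_score: 28, stars: 3.0}
    - {max_score: 32, stars: 2.5}
    - {max_score: 36, stars: 2.0}
    - {max_score: 40, stars: 1.5}
    - {max_score: 44, stars: 1.0}
    - {max_score: null, stars: 0.5}
  cheese:
    - {max_score: 4, stars: 5.0}
    - {max_score: 8, stars: 4.5}
    - {max_score: 12, stars: 4.0}
    - {max_score: 17, stars: 3.5}
    - {max_score: 21, stars: 3.0}
    - {max_score: 25, stars: 2.5}
    - {max_score: 29, stars: 2.0}
    - {max_score: 33, stars: 1.5}
    - {max_score: 37, stars: 1.0}
    - {max_score: null, stars: 0.5}
  otherDairy:
    - {max_score: -2, stars: 5.0}
    - {max_score: 0, stars: 4.5}
    - {max_score: 2, stars: 4.0}
    - {max_score: 4, stars: 3.5}
    - {max_score: 6, stars: 3.0}
    - {max_score: 8, stars: 2.5}
    - {max_score: 10, stars: 2.0}
    - {max_score: 13, stars: 1.5}
    - {max_score: 16, stars: 1.0}
    - {max_score: null, stars: 0.5}
  otherNonDairy:
    - {max_score: -11, stars: 5.0}
    - {max_score: -7, stars: 4.5}
    - {max_score: -2, stars: 4.0}
    - {max_score: 2, stars: 3.5}
    - {max_score: 6, stars: 3.0}
    - {max_score: 10, stars: 2.5}
    - {max_score: 15, stars: 2.0}
    - {max_score: 20, stars: 1.5}
    - {max_score: 25, stars: 1.0}
    - {max_score: null, stars: 0.5}
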