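# Methods

This note documents the models and procedures `starmod` implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the design choices made where the design was genuinely open.

## Scoring model

The Health Star Rating is a points-based nutrient profile model. For a
product with nutrient panel per 100 g (or 100 mL):

- baseline points `B = Σ_c points_c(x_c)` over c ∈ {energy (kJ),
  saturated fat (g), total sugars (g), sodium (mg)};
- modifying points `M = points_FVNL + points_fibre + points_protein`,
  where protein points are dropped if `B ≥ 13` and FVNL points `< 5`
  (cheese category exempt);
- final score `S = B − M` (an integer, possibly negative);
- stars = matrix_category(S), a non-increasing step function onto
  {0.5, 1.0, …, 5.0}.

`points_c(x)` is the number of configured cut-points strictly below `x`
("more than" semantics): a value exactly on a cut-point earns nothing.
This convention had to be fixed one way; it is asserted by the
`component_points` contract and changeable only together with the config
that encodes the cut-points. Inputs are used as supplied per 100 g — no
"as prepared" or dilution transformations — and nothing is rounded
before lookup; points and scores are exact integers.

Plain bottled water and plain fruit and vegetables are automatically
rated 5.0 stars with all point fields zeroed; they bypass the
nutrition-panel eligibility requirement.

### Scoring tables

All cut-points and the six star matrices live in versioned YAML
(`data/hsr_tables_default.yaml`), validated against structural
invariants (strictly increasing cut-points; star matrices total over the
integers, non-increasing, on the half-star lattice). The bundled default
is a *reconstructed transcription* of the public calculator's structure:
one shared set of baseline/modifying point tables across the six
categories (as in pre-2020 calculator guides) and category-specific star
matrices. The star matrices were sanity-checked against published
worked behaviours (a non-ultra-processed wholemeal-bread profile rates
4.0–4.5; the same profile with a 5-point penalty rates 3.5–4.0; a
brownie-style profile rates ≤2.0; a +5-point penalty moves typical
products by roughly 1–1.5 stars). Anyone needing regulatory-grade
ratings must substitute tables transcribed from the current official
guide; the engine treats the file as opaque config. A deliberately tiny
table (`hsr_tables_mini.yaml`) with single-digit cut-points backs
hand-verifiable unit tests.

### Missing favourable nutrients

Fibre and FVNL are frequently undeclared on real labels and are
estimated externally in database studies. The engine does not hide that
substitution: missing fibre/FVNL contribute 0 points under the default
`missing_policy="zero"` and emit a warning; `missing_policy="error"`
refuses instead. Missing baseline nutrients are never defaulted — such
products are excluded upstream by the eligibility filter, which logs
every exclusion under exactly one rule (category exclusion checked
before panel checks, so sequential accounting is unambiguous).

## Ultra-processing classification

The classifier is an adapted NOVA proxy: ingredient text is tokenized
(commas split at the current nesting depth; parenthesised sub-ingredient
groups become child tokens one level deeper; percentages are retained),
and each token is matched against a marker lexicon. Exemptions run
first: a token matching sugar, maple syrup, honey,
vitamins/minerals/live cultures, or acids/acidity regulators can never
yield a marker. Otherwise marker terms match as whole-word phrases with
longest-match preference ("natural flavour" wins over "flavour"), and
bare numeric tokens are resolved through an additive-code map (a
trailing `%` disqualifies a token as a code, so "45%" is never additive
45x). One marker suffices for an ultra-processed verdict; all matches
are reported for audit. A "colour (160b)" pair reports the class token
and the code as separate matches — the verdict needs only ≥1, and the
counts are transparency, not scoring.

The shipped lexicon seeds every marker class with its canonical
exemplars plus common synonyms and ANZ/INS codes; it is deliberately
extensible data, not code. Ambiguous entries (e.g. "natural flavour")
are flagged for review in the file. The classifier's accuracy on real
ingredient lists is bounded by lexicon coverage; the tests quantify
recovery only on synthetic lists built from this lexicon (see below).

## Core/discretionary rule engine

Verdicts resolve by subcategory key first, then major category; plain
`always_core`/`always_discretionary` rules return directly, and
`criteria` rules evaluate ordered nutrient predicates (first match wins,
declared default otherwise). Thresholds are inclusive (≥), matching the
published phrasing of the cereal criterion: breakfast cereals are
discretionary at ≥30 g sugars/100 g without added fruit, ≥35 g with.
Every verdict carries the id of the rule that fired. The shipped rule
file covers the 15 major categories and a handful of subcategory
overrides; it is a seeded example of the format, not the licensed
official list, which users must supply for substantive classification.

## Modifications (m-HSR 1–4)

Parameters with defaults: `penalty_points=5` (sensitivity alternatives 2
and 10 are supported), `cap_stars=3.0`, `hybrid_threshold=10`. Rules:

- M1: ultra-processed products get `B + 5`, and stars are recomputed
  through the category star matrix (a fixed star decrement would be
  wrong because the score→star mapping is category-specific).
- M2: stars := min(stars, 3.0).
- M3/M4: as M1/M2 but only when the *pre-penalty* baseline points are
  ≥10 — the gate reads "existing" baseline points, so it is evaluated
  before any penalty. For the same reason the protein-eligibility gate
  inside the engine is evaluated against the nutritional baseline, not
  the penalised one: the penalty is applied at the score level. This was
  a genuinely open choice; the alternative (re-running the protein gate
  with the inflated baseline) would make the penalty occasionally worth
  more than 5 points, which the "five additional points" framing does
  not suggest.

Non-ultra-processed products are never altered. Automatically rated
products pass through unchanged; the marker rules cannot flag plain
water or plain produce, and the test suite asserts this rather than
assuming it. `penalised` records whether a variant's rule was applied:
for inclusion variants the penalty counts as applied even when the star
outcome happens not to change; for capping variants the rule only bites
when it lowers the stars.

## Alignment and summaries

A rating is dichotomised at `star_cutoff` (default 3.5; 2.5 supported as
a stricter sensitivity setting, no code change required). Alignment
holds when stars `<` cutoff pairs with NOVA 4 / discretionary, or stars
`≥` cutoff pairs with NOVA 1–3 / core. Products missing the relevant
reference label are excluded and tallied. Percentages are kept at one
decimal and additionally rounded to integers for table-style output
(numpy's round-half-even; both precisions are in the output because the
rounding convention of published integer percentages is generally
unknowable). Distribution summaries use midpoint-interpolated quantiles
— a fixed, documented convention chosen for determinism; midpoints of
half-star values land on the quarter-star grid. Shift counts report
ultra-processed products whose modified rating is strictly lower.

## Synthetic generator

The generator emulates the *structure* of a national packaged-food
audit, not any real product database: 15 major categories with sampling
weights proportional to published category sizes (n = 25 486 total);
per-category nutrient draws from truncated log-normal distributions
(median and log-scale sigma per component, clipped at physical bounds,
masses rounded to 0.1 g and energy/sodium to integers); per-category
ultra-processing probabilities; and core/discretionary ground truth
sampled per category (independently of the rule engine, so reference
labels cannot trivially echo it). NOVA groups are 4 exactly for
ultra-processed ground truth and uniform over 1–3 otherwise, since the
pipeline consumes only the 4 vs 1–3 dichotomy. Small fractions of plain
bottled water (4% of beverages) and plain produce (5% of the
fruit/vegetable category) exercise the automatic-rating path.

Only two category prevalences are published in text (5% of egg
products, 96% of confectionery); the other 13 are stated assumptions in
the config comments, chosen once so the weighted overall prevalence is
≈64%. Nutrient parameters were likewise calibrated once so that a
default draw's overall median rating sits near 3.0 stars (a published
anchor used as a calibration target, not a validation claim); with the
bundled tables a 10 000-product draw gives median 3.0, IQR 1.5–4.0.

Ultra-processed products receive 1–4 markers sampled from the lexicon
and spliced among 3–8 base ingredients; the base pool is validated at
load to produce no marker match (it intentionally contains exempt terms
such as "citric acid" to exercise exemption precedence). Consequently
the classifier's 100% recovery of injected labels is a *construction
check* — it demonstrates parser/matcher/exemption correctness, not
classifier performance on real labels, where vocabulary coverage and
free-text noise dominate. Similarly, category-level nutrient draws
ignore subcategory structure (a "plain milk" row draws from the Dairy
distribution), correlations between nutrients, and any dependence of
nutrient profiles on ultra-processing status; alignment percentages on
synthetic draws therefore track the direction and rough magnitude of
real-data effects, not their published values.

Everything is driven by a single integer seed through one PRNG stream:
identical seeds give byte-identical fixture CSVs.

## Problem sizes and numerics

Tests run the full pipeline at 10 000 products (one seeded draw shared
across the suite) plus two 4 000-product draws for the
direction-of-effect check; property tests use 100–200 examples per
invariant, derandomised. Prevalence checks use a 3-standard-error
binomial band around the configured rate. All scoring arithmetic is
integer; no floating-point tolerances are needed anywhere except star
values, which are exact binary fractions on the half-star lattice.

## Known limitations

- The bundled scoring tables are a reconstruction; category 1/1D
  beverage treatment in the current official calculator differs in
  structure (post-2020 revisions), and regulatory use requires the
  official asset.
- The marker lexicon and rule list are seeds of the published rule
  *structure*; full coverage of a real supplementary term list or the
  licensed discretionary food list must come from user config.
- The tokenizer handles commas, two bracket styles and nesting, but not
  "and/or" conjunctions, typos or OCR noise common in scraped labels.
- The generator draws nutrients independently within category; it makes
  no attempt to reproduce the joint nutrient distribution or brand
  structure of a real food supply.
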