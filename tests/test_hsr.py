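"""Scoring engine: points, category assignment, star conversion, invariants."""

from __future__ import annotations

import warnings

import pytest
from hypothesis import given, settings, strategies as st

import starmod as sm
from starmod.errors import ConfigurationError, InputError
from starmod.hsr import (
    HSRCategory,
    STAR_LATTICE,
    baseline_points,
    component_points,
    modifying_points_breakdown,
    stars_from_score,
)
from starmod.product_io import NutrientPanel

from conftest import build_product

CUTPOINT_LISTS = st.lists(
    st.floats(min_value=0.1, max_value=5000, allow_nan=False),
    min_size=1,
    max_size=12,
    unique=True,
).map(sorted)


class TestComponentPoints:
    def test_below_first_cutpoint_scores_zero(self):
        assert component_points(0.0, [5, 10]) == 0
        assert component_points(4.9, [5, 10]) == 0

    def test_above_all_cutpoints_scores_full_count(self):
        assert component_points(11.0, [5, 10]) == 2

    def test_value_equal_to_cutpoint_earns_nothing(self):
        # "more than" semantics at the boundary
        assert component_points(5.0, [5, 10]) == 0
        assert component_points(10.0, [5, 10]) == 1

    def test_negative_value_rejected(self):
        with pytest.raises(InputError):
            component_points(-0.1, [5, 10])

    def test_non_increasing_cutpoints_rejected(self):
        with pytest.raises(InputError):
            component_points(1.0, [5, 5])

    @settings(max_examples=200, derandomize=True)
    @given(
        value=st.floats(min_value=0, max_value=6000, allow_nan=False),
        cuts=CUTPOINT_LISTS,
    )
    def test_equals_linear_scan_oracle(self, value, cuts):
        assert component_points(value, cuts) == sum(1 for c in cuts if value > c)


class TestBaselinePoints:
    def test_all_zero_panel_scores_zero(self, tables):
        panel = NutrientPanel(energy_kj=0, sat_fat_g=0, total_sugars_g=0, sodium_mg=0)
        assert baseline_points(panel, HSRCategory.otherNonDairy, tables) == 0

    def test_each_component_between_second_and_third_cutpoints_gives_eight(
        self, tables
    ):
        panel = NutrientPanel(
            energy_kj=800,  # between 670 and 1005
            sat_fat_g=2.5,  # between 2 and 3
            total_sugars_g=10,  # between 8.9 and 12.8
            sodium_mg=250,  # between 180 and 270
        )
        assert baseline_points(panel, HSRCategory.otherNonDairy, tables) == 8

    def test_missing_component_raises(self, tables):
        panel = NutrientPanel(energy_kj=100, sat_fat_g=1, total_sugars_g=1)
        with pytest.raises(InputError, match="sodium_mg"):
            baseline_points(panel, HSRCategory.otherNonDairy, tables)

    @settings(max_examples=100, derandomize=True)
    @given(
        energy=st.floats(0, 4000),
        satfat=st.floats(0, 100),
        sugars=st.floats(0, 100),
        sodium=st.floats(0, 9000),
        cat=st.sampled_from(list(HSRCategory)),
    )
    def test_randomised_panels_equal_componentwise_sum(
        self, tables, energy, satfat, sugars, sodium, cat
    ):
        panel = NutrientPanel(
            energy_kj=energy, sat_fat_g=satfat, total_sugars_g=sugars, sodium_mg=sodium
        )
        expected = sum(
            sum(1 for c in tables.baseline[cat][comp] if getattr(panel, comp) > c)
            for comp in ("energy_kj", "sat_fat_g", "total_sugars_g", "sodium_mg")
        )
        assert baseline_points(panel, cat, tables) == expected


class TestModifyingPoints:
    def test_zero_favourable_nutrients_score_zero(self, tables):
        panel = NutrientPanel(
            energy_kj=0, sat_fat_g=0, total_sugars_g=0, sodium_mg=0,
            protein_g=0, fibre_g=0, fvnl_pct=0,
        )
        assert sm.modifying_points(panel, HSRCategory.otherNonDairy, 0, tables) == 0

    def test_full_fvnl_hits_top_bin(self, tables):
        panel = NutrientPanel(
            energy_kj=0, sat_fat_g=0, total_sugars_g=0, sodium_mg=0,
            protein_g=0, fibre_g=0, fvnl_pct=100,
        )
        bd = modifying_points_breakdown(panel, HSRCategory.otherNonDairy, 0, tables)
        assert bd["fvnl"] == len(tables.modifying[HSRCategory.otherNonDairy]["fvnl_pct"])

    def test_protein_gate_blocks_protein_when_baseline_high_and_fvnl_low(
        self, tables
    ):
        panel = NutrientPanel(
            energy_kj=0, sat_fat_g=0, total_sugars_g=0, sodium_mg=0,
            protein_g=25, fibre_g=0, fvnl_pct=0,
        )
        gated = modifying_points_breakdown(
            panel, HSRCategory.otherNonDairy, baseline=13, tables=tables
        )
        assert gated["protein"] == 0
        open_ = modifying_points_breakdown(
            panel, HSRCategory.otherNonDairy, baseline=12, tables=tables
        )
        assert open_["protein"] > 0

    def test_high_fvnl_reopens_protein_points(self, tables):
        panel = NutrientPanel(
            energy_kj=0, sat_fat_g=0, total_sugars_g=0, sodium_mg=0,
            protein_g=25, fibre_g=0, fvnl_pct=90,  # 7 FVNL points >= 5
        )
        bd = modifying_points_breakdown(
            panel, HSRCategory.otherNonDairy, baseline=20, tables=tables
        )
        assert bd["protein"] > 0

    def test_cheese_exempt_from_protein_gate(self, tables):
        panel = NutrientPanel(
            energy_kj=1700, sat_fat_g=21, total_sugars_g=0.1, sodium_mg=700,
            protein_g=25, fibre_g=0, fvnl_pct=0,
        )
        bd = modifying_points_breakdown(
            panel, HSRCategory.cheese, baseline=28, tables=tables
        )
        assert bd["protein"] > 0

    def test_missing_fibre_contributes_zero_with_warning(self, tables):
        panel = NutrientPanel(
            energy_kj=0, sat_fat_g=0, total_sugars_g=0, sodium_mg=0,
            protein_g=0, fibre_g=None, fvnl_pct=0,
        )
        with pytest.warns(UserWarning, match="fibre_g"):
            total = sm.modifying_points(panel, HSRCategory.otherNonDairy, 0, tables)
        assert total == 0

    def test_missing_policy_error_raises(self, tables):
        panel = NutrientPanel(
            energy_kj=0, sat_fat_g=0, total_sugars_g=0, sodium_mg=0,
            protein_g=0, fibre_g=None, fvnl_pct=0,
        )
        with pytest.raises(InputError):
            sm.modifying_points(
                panel, HSRCategory.otherNonDairy, 0, tables, missing_policy="error"
            )


class TestCategoryAssignment:
    def test_explicit_category_wins(self):
        product = build_product(hsr_category="cheese", subcategory="pita bread")
        assert sm.assign_hsr_category(product) is HSRCategory.cheese

    @pytest.mark.parametrize(
        "subcategory,expected",
        [
            ("pita bread", HSRCategory.otherNonDairy),
            ("plain milk", HSRCategory.dairyBeverage),
            ("olive oil", HSRCategory.oilsAndSpreads),
            ("cheddar cheese", HSRCategory.cheese),
            ("yoghurt", HSRCategory.otherDairy),
            ("soft drink", HSRCategory.nonDairyBeverage),
        ],
    )
    def test_shipped_mapping(self, subcategory, expected):
        product = build_product(subcategory=subcategory)
        assert sm.assign_hsr_category(product) is expected

    def test_unmapped_subcategory_raises_naming_it(self):
        product = build_product(subcategory="mystery goo")
        with pytest.raises(ConfigurationError, match="mystery goo"):
            sm.assign_hsr_category(product)


class TestComputeHSR:
    def test_plain_water_scores_five_stars_automatically(self, tables):
        water = build_product(
            product_id="W",
            major_category="Non-alcoholic beverages",
            subcategory="still water",
            energy_kj=None, sat_fat_g=None, total_sugars_g=None,
            sodium_mg=None, protein_g=None, fibre_g=None, fvnl_pct=None,
            flags=frozenset({"plain_water", "no_nutrition_panel"}),
        )
        result = sm.compute_hsr(water, tables)
        assert result.stars == 5.0
        assert result.automatic
        assert result.baseline_points == result.modifying_points == 0

    def test_final_score_is_baseline_minus_modifying(self, tables):
        product = build_product()
        result = sm.compute_hsr(product, tables)
        assert not result.automatic
        assert result.final_score == result.baseline_points - result.modifying_points

    def test_hand_checked_product_on_mini_tables(self, mini_tables):
        # energy 250 -> 2, satfat 2.5 -> 2, sugars 12 -> 2, sodium 250 -> 2
        # baseline 8; fvnl 65 -> 2, protein 7 -> 1 (baseline >= cap 4 but
        # fvnl points 2 >= min 2 so allowed), fibre 3 -> 1 => modifying 4
        # final 4 -> 3.5 stars in the mini matrix
        product = build_product(
            energy_kj=250, sat_fat_g=2.5, total_sugars_g=12, sodium_mg=250,
            protein_g=7, fibre_g=3, fvnl_pct=65,
        )
        result = sm.compute_hsr(product, mini_tables)
        assert result.baseline_points == 8
        assert result.modifying_breakdown == {"fvnl": 2, "protein": 1, "fibre": 1}
        assert result.final_score == 4
        assert result.stars == 3.5

    def test_engine_is_pure(self, tables):
        product = build_product()
        assert sm.compute_hsr(product, tables) == sm.compute_hsr(product, tables)

    @settings(max_examples=150, derandomize=True)
    @given(
        energy=st.floats(0, 4000),
        satfat=st.floats(0, 100),
        sugars=st.floats(0, 100),
        sodium=st.floats(0, 9000),
        protein=st.floats(0, 100),
        fibre=st.floats(0, 100),
        fvnl=st.floats(0, 100),
        cat=st.sampled_from(list(HSRCategory)),
    )
    def test_stars_always_on_half_star_lattice_and_identity_holds(
        self, tables, energy, satfat, sugars, sodium, protein, fibre, fvnl, cat
    ):
        product = build_product(
            energy_kj=energy, sat_fat_g=satfat, total_sugars_g=sugars,
            sodium_mg=sodium, protein_g=protein, fibre_g=fibre, fvnl_pct=fvnl,
        )
        result = sm.compute_hsr(product, tables, category=cat)
        assert result.stars in STAR_LATTICE
        assert result.final_score == result.baseline_points - result.modifying_points

    @settings(max_examples=100, derandomize=True)
    @given(
        sodium=st.floats(0, 4000),
        delta=st.floats(0.1, 4000),
        cat=st.sampled_from(list(HSRCategory)),
    )
    def test_more_sodium_never_raises_stars(self, tables, sodium, delta, cat):
        low = build_product(sodium_mg=sodium)
        high = build_product(sodium_mg=sodium + delta)
        assert (
            sm.compute_hsr(high, tables, category=cat).stars
            <= sm.compute_hsr(low, tables, category=cat).stars
        )

    @settings(max_examples=100, derandomize=True)
    @given(
        fvnl=st.floats(0, 99),
        delta=st.floats(0.1, 100),
        cat=st.sampled_from(list(HSRCategory)),
    )
    def test_more_fvnl_never_lowers_stars(self, tables, fvnl, delta, cat):
        low = build_product(fvnl_pct=fvnl)
        high = build_product(fvnl_pct=min(fvnl + delta, 100.0))
        assert (
            sm.compute_hsr(high, tables, category=cat).stars
            >= sm.compute_hsr(low, tables, category=cat).stars
        )


class TestScoringTablesValidation:
    def test_star_matrix_totality(self, tables):
        for cat in HSRCategory:
            for score in range(-40, 120):
                assert stars_from_score(score, cat, tables) in STAR_LATTICE

    def test_decreasing_cutpoints_rejected(self, tables):
        raw = {
            "version": "bad",
            "baseline": {"default": {
                "energy_kj": [10, 5],
                "sat_fat_g": [1], "total_sugars_g": [1], "sodium_mg": [1],
            }},
            "modifying": {"default": {
                "fvnl_pct": [1], "protein_g": [1], "fibre_g": [1],
            }},
            "star_matrix": {
                c.value: [{"max_score": 0, "stars": 5.0},
                          {"max_score": None, "stars": 0.5}]
                for c in HSRCategory
            },
        }
        with pytest.raises(ConfigurationError, match="strictly increasing"):
            sm.ScoringTables.from_dict(raw)

    def test_star_matrix_must_end_with_catch_all(self):
        raw = {
            "version": "bad",
            "baseline": {"default": {
                "energy_kj": [1], "sat_fat_g": [1],
                "total_sugars_g": [1], "sodium_mg": [1],
            }},
            "modifying": {"default": {
                "fvnl_pct": [1], "protein_g": [1], "fibre_g": [1],
            }},
            "star_matrix": {
                c.value: [{"max_score": 0, "stars": 5.0}] for c in HSRCategory
            },
        }
        with pytest.raises(ConfigurationError, match="catch-all"):
            sm.ScoringTables.from_dict(raw)
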