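"""Shared fixtures: scoring tables, lexicon, rules, a product factory and a
session-scoped synthetic fixture with everything precomputed once."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pytest

import starmod as sm
from starmod.product_io import NutrientPanel, Product, ReferenceLabels


@pytest.fixture(scope="session")
def tables() -> sm.ScoringTables:
    return sm.load_default_tables()


@pytest.fixture(scope="session")
def mini_tables() -> sm.ScoringTables:
    return sm.load_mini_tables()


@pytest.fixture(scope="session")
def lexicon() -> sm.MarkerLexicon:
    return sm.load_default_lexicon()


@pytest.fixture(scope="session")
def adg_rules() -> sm.ADGRuleSet:
    return sm.load_default_rules()


def build_product(
    product_id: str = "P1",
    name: str = "test product",
    major_category: str = "Bread and bakery products",
    subcategory: str = "sliced bread",
    hsr_category: str | None = None,
    energy_kj: float | None = 1000.0,
    sat_fat_g: float | None = 1.0,
    total_sugars_g: float | None = 5.0,
    sodium_mg: float | None = 300.0,
    protein_g: float | None = 8.0,
    fibre_g: float | None = 3.0,
    fvnl_pct: float | None = 0.0,
    ingredient_text: str = "wheat flour, water, salt",
    flags: frozenset[str] = frozenset(),
    nova_group: int | None = None,
    adg: str | None = None,
) -> Product:
    return Product(
        product_id=product_id,
        name=name,
        major_category=major_category,
        subcategory=subcategory,
        hsr_category=hsr_category,
        nutrients=NutrientPanel(
            energy_kj=energy_kj,
            sat_fat_g=sat_fat_g,
            total_sugars_g=total_sugars_g,
            sodium_mg=sodium_mg,
            protein_g=protein_g,
            fibre_g=fibre_g,
            fvnl_pct=fvnl_pct,
        ),
        ingredient_text=ingredient_text,
        flags=flags,
        reference_labels=ReferenceLabels(nova_group=nova_group, adg=adg),
    )


@pytest.fixture
def make_product():
    return build_product


@dataclass
class SyntheticRun:
    """A 10 000-product seeded draw with all pipeline stages precomputed."""

    config: sm.GeneratorConfig
    products: sm.ProductSet
    truth: sm.GroundTruth
    eligible: sm.ProductSet
    annotations: list[sm.UPFAnnotation]
    results: list[sm.HSRResult]

    @property
    def upf_flags(self) -> list[bool]:
        return [a.is_upf for a in self.annotations]

    @property
    def stars(self) -> list[float]:
        return [r.stars for r in self.results]


def run_pipeline(n: int, seed: int) -> SyntheticRun:
    config = sm.GeneratorConfig.default(n_products=n, seed=seed)
    products, truth = sm.generate_products(config)
    eligible = sm.filter_eligible(products)
    lexicon = sm.load_default_lexicon()
    annotations = sm.classify_upf_batch(eligible, lexicon)
    scoring = sm.load_default_tables()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # missing fibre/FVNL draws are intended
        results = [sm.compute_hsr(p, scoring) for p in eligible]
    return SyntheticRun(
        config=config,
        products=products,
        truth=truth,
        eligible=eligible,
        annotations=annotations,
        results=results,
    )


@pytest.fixture(scope="session")
def synthetic_run() -> SyntheticRun:
    return run_pipeline(n=10000, seed=42)
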