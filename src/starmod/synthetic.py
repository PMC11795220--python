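"""Seeded synthetic food-supply generator.

Real supermarket audit datasets are licensed; this module generates
product sets with the same *structure* so that every pipeline stage —
I/O, scoring, ultra-processing classification, modification and
alignment — is exercisable and testable end to end.  Each product gets a
major category (weights proportional to published category sizes),
nutrients from truncated per-category log-normal distributions, an
ultra-processing coin flip (category-specific probabilities anchored to
the published 5%–96% range, ~64% overall), a grammatically assembled
ingredient list, and reference labels derived from the ground truth
(NOVA group 4 exactly for the ultra-processed, uniform 1–3 otherwise;
core/discretionary sampled per category).

Ultra-processed products carry 1–4 injected marker ingredients drawn
from the marker lexicon; every other ingredient comes from a base pool
validated to be marker-free, so the classifier's recovery of the ground
truth is exact by construction — a label-recovery test, not a claim
about real ingredient lists.

Everything is driven by one integer seed: same seed, same byte-level CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .product_io import (
    MAJOR_CATEGORIES,
    NutrientPanel,
    Product,
    ProductSet,
    ReferenceLabels,
    write_products,
)
from .upf import IngredientToken, MarkerLexicon, load_default_lexicon, match_marker

_MASS_FIELDS = ("sat_fat_g", "total_sugars_g", "protein_g", "fibre_g")


@dataclass(frozen=True)
class NutrientSpec:
    """Truncated log-normal: median and sigma on the log scale."""

    median: float
    sigma: float
    p_missing: float = 0.0


@dataclass(frozen=True)
class FVNLSpec:
    p_zero: float
    low: float
    high: float


@dataclass(frozen=True)
class CategorySpec:
    name: str
    weight: float
    upf_probability: float
    discretionary_probability: float
    subcategories: tuple[tuple[str, float], ...]
    nutrients: dict[str, NutrientSpec]
    fvnl: FVNLSpec
    added_fruit_probability: float = 0.0
    auto_fraction: float = 0.0
    auto_flag: Optional[str] = None
    auto_subcategory: Optional[str] = None

    def __post_init__(self) -> None:
        for p, label in (
            (self.upf_probability, "upf_probability"),
            (self.discretionary_probability, "discretionary_probability"),
            (self.added_fruit_probability, "added_fruit_probability"),
            (self.auto_fraction, "auto_fraction"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{self.name}: {label} outside [0,1]")
        if self.weight <= 0:
            raise ConfigurationError(f"{self.name}: weight must be positive")
        if self.auto_fraction > 0 and not (self.auto_flag and self.auto_subcategory):
            raise ConfigurationError(
                f"{self.name}: auto_fraction needs auto_flag and auto_subcategory"
            )


@dataclass
class GeneratorConfig:
    n_products: int
    seed: int
    categories: dict[str, CategorySpec]
    base_pool: tuple[str, ...]
    marker_pool: tuple[str, ...] = ()  # filled from the lexicon when empty

    def __post_init__(self) -> None:
        if self.n_products < 0:
            raise ConfigurationError("n_products must be >= 0")
        unknown = set(self.categories) - set(MAJOR_CATEGORIES)
        if unknown:
            raise ConfigurationError(f"unknown categories: {sorted(unknown)}")

    @property
    def weights(self) -> np.ndarray:
        w = np.array([c.weight for c in self.categories.values()], dtype=float)
        return w / w.sum()

    def expected_upf_prevalence(self) -> float:
        """Configured overall ultra-processed fraction (auto-rated rows
        can never be ultra-processed, hence the (1 - auto_fraction))."""
        w = self.weights
        p = np.array(
            [
                (1.0 - c.auto_fraction) * c.upf_probability
                for c in self.categories.values()
            ]
        )
        return float(np.sum(w * p))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        cats: dict[str, CategorySpec] = {}
        for name, body in (raw.get("categories") or {}).items():
            nutr = {}
            fvnl = None
            for comp, spec in (body.get("nutrients") or {}).items():
                if comp == "fvnl_pct":
                    fvnl = FVNLSpec(
                        p_zero=float(spec["p_zero"]),
                        low=float(spec["low"]),
                        high=float(spec["high"]),
                    )
                else:
                    nutr[comp] = NutrientSpec(
                        median=float(spec["median"]),
                        sigma=float(spec["sigma"]),
                        p_missing=float(spec.get("p_missing", 0.0)),
                    )
            if fvnl is None:
                raise ConfigurationError(f"{name}: missing fvnl_pct spec")
            subs = tuple(
                (str(s), float(w)) for s, w in (body.get("subcategories") or {}).items()
            )
            if not subs:
                raise ConfigurationError(f"{name}: no subcategories")
            cats[name] = CategorySpec(
                name=name,
                weight=float(body["weight"]),
                upf_probability=float(body["upf_probability"]),
                discretionary_probability=float(body["discretionary_probability"]),
                added_fruit_probability=float(body.get("added_fruit_probability", 0.0)),
                auto_fraction=float(body.get("auto_fraction", 0.0)),
                auto_flag=body.get("auto_flag"),
                auto_subcategory=body.get("auto_subcategory"),
                subcategories=subs,
                nutrients=nutr,
                fvnl=fvnl,
            )
        return cls(
            n_products=int(raw.get("n_products", 10000)),
            seed=int(raw.get("seed", 42)),
            categories=cats,
            base_pool=tuple(str(x) for x in raw.get("base_pool") or ()),
        )

    @classmethod
    def default(cls, n_products: Optional[int] = None,
                seed: Optional[int] = None) -> "GeneratorConfig":
        ref = resources.files("starmod.data").joinpath("generator_default.yaml")
        with resources.as_file(ref) as path:
            cfg = cls.from_yaml(path)
        if n_products is not None:
            cfg.n_products = n_products
        if seed is not None:
            cfg.seed = seed
        return cfg


@dataclass
class GroundTruth:
    """Per-product ground truth written alongside each fixture."""

    table: pd.DataFrame  # product_id, true_upf, injected_markers, true_adg

    def __len__(self) -> int:
        return len(self.table)


def _validate_pools(config: GeneratorConfig, lexicon: MarkerLexicon) -> None:
    """The base pool must never trigger a marker match."""
    for ingredient in config.base_pool:
        if match_marker(IngredientToken(ingredient, 0), lexicon):
            raise ConfigurationError(
                f"base-pool ingredient {ingredient!r} matches the marker lexicon"
            )


def _marker_pool(config: GeneratorConfig, lexicon: MarkerLexicon) -> list[str]:
    if config.marker_pool:
        return list(config.marker_pool)
    return sorted(lexicon.marker_terms)


def _render_marker(term: str, lexicon: MarkerLexicon, rng: np.random.Generator) -> str:
    """Render an injected marker, sometimes as 'class (code)'."""
    cls = lexicon.marker_terms[term]
    codes = [c for c, k in lexicon.additive_code_map.items() if k == cls]
    if codes and term in ("thickener", "emulsifier", "colour", "flavour") and rng.random() < 0.5:
        return f"{term} ({rng.choice(codes)})"
    return term


def _assemble_ingredients(
    base: list[str],
    markers: list[str],
    lexicon: MarkerLexicon,
    rng: np.random.Generator,
) -> str:
    parts = list(base)
    for term in markers:
        parts.insert(int(rng.integers(0, len(parts) + 1)), _render_marker(term, lexicon, rng))
    # occasional leading percentage and a parenthetical sub-ingredient
    if parts and rng.random() < 0.3:
        parts[0] = f"{parts[0]} ({int(rng.integers(20, 96))}%)"
    if len(parts) > 2 and rng.random() < 0.2:
        sub = ", ".join(rng.choice(base, size=2, replace=False))
        parts.append(f"vegetable mix ({sub})")
    return ", ".join(parts)


def generate_products(
    config: Optional[GeneratorConfig] = None,
    lexicon: Optional[MarkerLexicon] = None,
) -> tuple[ProductSet, GroundTruth]:
    """Generate a seeded synthetic product set with ground truth.

    Deterministic given ``config.seed``.  Returns a :class:`ProductSet`
    (which round-trips through the CSV schema) and a :class:`GroundTruth`
    table with one row per product.
    """
    if config is None:
        config = GeneratorConfig.default()
    if lexicon is None:
        lexicon = load_default_lexicon()
    _validate_pools(config, lexicon)
    markers_available = _marker_pool(config, lexicon)

    rng = np.random.default_rng(config.seed)
    cat_names = list(config.categories)
    cat_idx = rng.choice(len(cat_names), size=config.n_products, p=config.weights)

    products: list[Product] = []
    truth_rows: list[dict] = []
    for i in range(config.n_products):
        spec = config.categories[cat_names[int(cat_idx[i])]]
        pid = f"SYN-{i:06d}"
        is_auto = rng.random() < spec.auto_fraction
        if is_auto:
            sub = spec.auto_subcategory or ""
            product = Product(
                product_id=pid,
                name=f"{sub} {i}",
                major_category=spec.name,
                subcategory=sub,
                nutrients=NutrientPanel(),
                ingredient_text="",
                flags=frozenset({spec.auto_flag or "", "no_nutrition_panel"} - {""}),
                reference_labels=ReferenceLabels(nova_group=1, adg="core"),
            )
            products.append(product)
            truth_rows.append(
                {"product_id": pid, "true_upf": False,
                 "injected_markers": "", "true_adg": "core"}
            )
            continue

        sub_names = [s for s, _ in spec.subcategories]
        sub_w = np.array([w for _, w in spec.subcategories], dtype=float)
        sub = str(rng.choice(sub_names, p=sub_w / sub_w.sum()))

        def draw(ns: NutrientSpec, integer: bool = False, cap: Optional[float] = None):
            if ns.p_missing and rng.random() < ns.p_missing:
                return None
            v = ns.median * float(np.exp(ns.sigma * rng.standard_normal()))
            if cap is not None:
                v = min(v, cap)
            return float(int(round(v))) if integer else round(v, 1)

        panel = NutrientPanel(
            energy_kj=draw(spec.nutrients["energy_kj"], integer=True),
            sat_fat_g=draw(spec.nutrients["sat_fat_g"], cap=100.0),
            total_sugars_g=draw(spec.nutrients["total_sugars_g"], cap=100.0),
            sodium_mg=draw(spec.nutrients["sodium_mg"], integer=True),
            protein_g=draw(spec.nutrients["protein_g"], cap=100.0),
            fibre_g=draw(spec.nutrients["fibre_g"], cap=100.0),
            fvnl_pct=(
                0.0
                if rng.random() < spec.fvnl.p_zero
                else float(int(rng.integers(int(spec.fvnl.low), int(spec.fvnl.high) + 1)))
            ),
        )

        is_upf = rng.random() < spec.upf_probability
        n_base = int(rng.integers(3, 9))
        base = [str(x) for x in rng.choice(config.base_pool, size=n_base, replace=False)]
        injected: list[str] = []
        if is_upf:
            k = int(rng.integers(1, 5))
            injected = [
                str(t) for t in rng.choice(markers_available, size=k, replace=False)
            ]
        text = _assemble_ingredients(base, injected, lexicon, rng)

        flags: set[str] = set()
        if spec.added_fruit_probability and rng.random() < spec.added_fruit_probability:
            flags.add("added_fruit")

        adg = (
            "discretionary"
            if rng.random() < spec.discretionary_probability
            else "core"
        )
        nova = 4 if is_upf else int(rng.integers(1, 4))
        products.append(
            Product(
                product_id=pid,
                name=f"{sub} {i}",
                major_category=spec.name,
                subcategory=sub,
                nutrients=panel,
                ingredient_text=text,
                flags=frozenset(flags),
                reference_labels=ReferenceLabels(nova_group=nova, adg=adg),
            )
        )
        truth_rows.append(
            {"product_id": pid, "true_upf": bool(is_upf),
             "injected_markers": ";".join(injected), "true_adg": adg}
        )

    truth = GroundTruth(
        pd.DataFrame(
            truth_rows,
            columns=["product_id", "true_upf", "injected_markers", "true_adg"],
        )
    )
    pset = ProductSet(
        products,
        provenance={
            "source": "starmod.synthetic",
            "seed": config.seed,
            "n_products": config.n_products,
        },
    )
    return pset, truth


def write_fixture(
    products: ProductSet, ground_truth: GroundTruth, directory: str | Path
) -> tuple[Path, Path]:
    """Write products.csv and ground_truth.csv into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    products_path = write_products(products, directory / "products.csv")
    truth_path = directory / "ground_truth.csv"
    ground_truth.table.to_csv(truth_path, index=False)
    return products_path, truth_path
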