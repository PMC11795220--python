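"""Health Star Rating scoring engine.

The rating is a points-based nutrient profile score.  Every eligible
product is assigned to one of six scoring categories:

* ``nonDairyBeverage`` — waters, juices, soft drinks;
* ``dairyBeverage`` — milks and milk-based drinks;
* ``oilsAndSpreads`` — edible oils, margarine, butter;
* ``cheese`` — cheese and processed cheese;
* ``otherDairy`` — yoghurts, dairy desserts;
* ``otherNonDairy`` — everything else.

Baseline (negative) points accrue from energy (kJ), saturated fat (g),
total sugars (g) and sodium (mg) per 100 g; modifying (positive) points
from FVNL percentage, protein (g) and fibre (g).  For each component the
points equal the number of configured cut-points the value *strictly
exceeds* ("more than" semantics).  The final score is baseline minus
modifying points; a category-specific matrix converts the score to a star
rating on the half-star lattice 0.5–5.0, non-increasing in the score.
Plain bottled water and plain fruit and vegetables receive an automatic
5.0 stars without scoring.

Protein points are gated: once a product accrues at least
``protein_eligibility.baseline_cap`` baseline points (default 13) its
protein points only count if it also earns at least
``protein_eligibility.min_fvnl_points`` FVNL points (default 5); the
cheese category is exempt from the gate.

All thresholds live in a versioned YAML asset (:func:`load_default_tables`).
The bundled default is a *reconstruction* of the public calculator's
point-scoring structure — see the file header of
``data/hsr_tables_default.yaml`` — and is treated as replaceable,
validated config, never as code.
"""

from __future__ import annotations

import enum
import warnings
from bisect import bisect_left
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from .errors import ConfigurationError, InputError
from .product_io import NutrientPanel, Product

BASELINE_COMPONENTS = ("energy_kj", "sat_fat_g", "total_sugars_g", "sodium_mg")
MODIFYING_COMPONENTS = ("fvnl_pct", "protein_g", "fibre_g")

#: Valid star values: 0.5, 1.0, ..., 5.0.
STAR_LATTICE = tuple(x / 2 for x in range(1, 11))


class HSRCategory(str, enum.Enum):
    nonDairyBeverage = "nonDairyBeverage"
    dairyBeverage = "dairyBeverage"
    oilsAndSpreads = "oilsAndSpreads"
    cheese = "cheese"
    otherDairy = "otherDairy"
    otherNonDairy = "otherNonDairy"


@dataclass(frozen=True)
class ProteinEligibility:
    """Parameters of the protein-point gate."""

    baseline_cap: int = 13
    min_fvnl_points: int = 5
    exempt_categories: frozenset[HSRCategory] = frozenset({HSRCategory.cheese})

    def allows_protein(
        self, category: HSRCategory, baseline: int, fvnl_points: int
    ) -> bool:
        if category in self.exempt_categories:
            return True
        if baseline < self.baseline_cap:
            return True
        return fvnl_points >= self.min_fvnl_points


# star matrix entry: (inclusive upper score bound or None for +inf, stars)
StarBand = tuple[Optional[int], float]


@dataclass(frozen=True)
class ScoringTables:
    """Versioned scoring configuration.

    ``baseline`` and ``modifying`` map category -> component -> strictly
    increasing cut-point tuple.  ``star_matrix`` maps category -> ordered
    bands ``(upper_bound, stars)`` with strictly increasing bounds, a final
    catch-all band (``upper_bound=None``) and non-increasing stars.
    """

    version: str
    baseline: Mapping[HSRCategory, Mapping[str, tuple[float, ...]]]
    modifying: Mapping[HSRCategory, Mapping[str, tuple[float, ...]]]
    protein_eligibility: ProteinEligibility
    star_matrix: Mapping[HSRCategory, tuple[StarBand, ...]]

    def __post_init__(self) -> None:
        for cat in HSRCategory:
            for table, comps in (
                (self.baseline, BASELINE_COMPONENTS),
                (self.modifying, MODIFYING_COMPONENTS),
            ):
                if cat not in table:
                    raise ConfigurationError(f"no tables for category {cat.value}")
                for comp in comps:
                    cuts = table[cat].get(comp)
                    if not cuts:
                        raise ConfigurationError(
                            f"{cat.value}: missing cut-points for {comp}"
                        )
                    if any(b <= a for a, b in zip(cuts, cuts[1:])):
                        raise ConfigurationError(
                            f"{cat.value}/{comp}: cut-points not strictly increasing"
                        )
            bands = self.star_matrix.get(cat)
            if not bands:
                raise ConfigurationError(f"no star matrix for {cat.value}")
            if bands[-1][0] is not None:
                raise ConfigurationError(
                    f"{cat.value}: star matrix must end with a catch-all band"
                )
            bounds = [b for b, _ in bands[:-1]]
            if any(b is None for b in bounds):
                raise ConfigurationError(
                    f"{cat.value}: only the last band may be unbounded"
                )
            if any(y <= x for x, y in zip(bounds, bounds[1:])):  # type: ignore[operator]
                raise ConfigurationError(
                    f"{cat.value}: star matrix bounds must strictly increase"
                )
            stars = [s for _, s in bands]
            if any(s not in STAR_LATTICE for s in stars):
                raise ConfigurationError(
                    f"{cat.value}: star values must lie on the half-star lattice"
                )
            if any(y > x for x, y in zip(stars, stars[1:])):
                raise ConfigurationError(
                    f"{cat.value}: stars must be non-increasing in score"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScoringTables":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ScoringTables":
        def expand(section: dict, comps: Sequence[str]) -> dict:
            default = section.get("default", {})
            overrides = section.get("overrides", {}) or {}
            out = {}
            for cat in HSRCategory:
                per = dict(default)
                per.update(overrides.get(cat.value, {}))
                out[cat] = {c: tuple(float(x) for x in per.get(c, ())) for c in comps}
            return out

        pe_raw = raw.get("protein_eligibility", {})
        pe = ProteinEligibility(
            baseline_cap=int(pe_raw.get("baseline_cap", 13)),
            min_fvnl_points=int(pe_raw.get("min_fvnl_points", 5)),
            exempt_categories=frozenset(
                HSRCategory(c) for c in pe_raw.get("exempt_categories", [])
            ),
        )
        matrix: dict[HSRCategory, tuple[StarBand, ...]] = {}
        for cat_name, bands in raw.get("star_matrix", {}).items():
            cat = HSRCategory(cat_name)
            parsed: list[StarBand] = []
            for band in bands:
                bound = band["max_score"]
                parsed.append(
                    (None if bound is None else int(bound), float(band["stars"]))
                )
            matrix[cat] = tuple(parsed)
        return cls(
            version=str(raw.get("version", "unversioned")),
            baseline=expand(raw.get("baseline", {}), BASELINE_COMPONENTS),
            modifying=expand(raw.get("modifying", {}), MODIFYING_COMPONENTS),
            protein_eligibility=pe,
            star_matrix=matrix,
        )


def _load_asset(name: str) -> ScoringTables:
    ref = resources.files("starmod.data").joinpath(name)
    with resources.as_file(ref) as path:
        return ScoringTables.from_yaml(path)


def load_default_tables() -> ScoringTables:
    """The bundled full-scale tables (reconstructed transcription)."""
    return _load_asset("hsr_tables_default.yaml")


def load_mini_tables() -> ScoringTables:
    """A miniature table with single-digit cut-points for hand-checked tests."""
    return _load_asset("hsr_tables_mini.yaml")


# ---------------------------------------------------------------------------
# category assignment

def _load_subcategory_map() -> dict[str, HSRCategory]:
    ref = resources.files("starmod.data").joinpath("hsr_subcategories.yaml")
    with resources.as_file(ref) as path:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    return {
        str(sub).strip().lower(): HSRCategory(cat)
        for cat, subs in raw["subcategories"].items()
        for sub in subs
    }


_SUBCATEGORY_MAP: Optional[dict[str, HSRCategory]] = None


def assign_hsr_category(
    product: Product, mapping: Optional[Mapping[str, HSRCategory]] = None
) -> HSRCategory:
    """Resolve the six-way scoring category for a product.

    An explicit ``product.hsr_category`` wins; otherwise the shipped
    subcategory mapping decides.  Unmappable products raise
    :class:`ConfigurationError` naming the subcategory.
    """
    if product.hsr_category is not None:
        try:
            return HSRCategory(product.hsr_category)
        except ValueError:
            raise ConfigurationError(
                f"unknown explicit hsr_category {product.hsr_category!r} "
                f"for product {product.product_id}"
            ) from None
    global _SUBCATEGORY_MAP
    if mapping is None:
        if _SUBCATEGORY_MAP is None:
            _SUBCATEGORY_MAP = _load_subcategory_map()
        mapping = _SUBCATEGORY_MAP
    key = product.subcategory.strip().lower()
    if key in mapping:
        return mapping[key]
    raise ConfigurationError(
        f"subcategory {product.subcategory!r} (product {product.product_id}) "
        "is not in the scoring-category mapping and no explicit hsr_category "
        "was given"
    )


# ---------------------------------------------------------------------------
# points

def component_points(value: float, cutpoints: Sequence[float]) -> int:
    """Points for one component: the count of cut-points strictly below value."""
    if value < 0:
        raise InputError(f"component value must be non-negative, got {value!r}")
    cuts = list(cutpoints)
    if any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise InputError("cutpoints must be strictly increasing")
    # "more than" semantics: value == cut-point earns nothing, so the point
    # count is the number of cut-points strictly below the value
    return bisect_left(cuts, value)


def baseline_points(
    panel: NutrientPanel, cat: HSRCategory, tables: ScoringTables
) -> int:
    """Sum of energy, saturated-fat, sugars and sodium points."""
    if not panel.has_core_panel:
        missing = [c for c in BASELINE_COMPONENTS if getattr(panel, c) is None]
        raise InputError(f"baseline nutrients missing: {', '.join(missing)}")
    return sum(
        component_points(getattr(panel, comp), tables.baseline[cat][comp])
        for comp in BASELINE_COMPONENTS
    )


def modifying_points_breakdown(
    panel: NutrientPanel,
    cat: HSRCategory,
    baseline: int,
    tables: ScoringTables,
    missing_policy: str = "zero",
) -> dict[str, int]:
    """Per-component modifying points, honouring the protein gate.

    Missing fibre or FVNL contribute zero points under the default
    ``missing_policy="zero"`` (a warning is emitted, because real labels
    often omit them and the substitution should be visible);
    ``missing_policy="error"`` raises instead.
    """
    if missing_policy not in ("zero", "error"):
        raise InputError(f"unknown missing_policy {missing_policy!r}")

    def value_of(comp: str) -> float:
        v = getattr(panel, comp)
        if v is None:
            if missing_policy == "error":
                raise InputError(f"{comp} is missing")
            warnings.warn(
                f"{comp} missing; contributing 0 modifying points",
                stacklevel=3,
            )
            return 0.0
        return v

    fvnl_pts = component_points(value_of("fvnl_pct"), tables.modifying[cat]["fvnl_pct"])
    fibre_pts = component_points(value_of("fibre_g"), tables.modifying[cat]["fibre_g"])
    protein_pts = component_points(
        value_of("protein_g"), tables.modifying[cat]["protein_g"]
    )
    if not tables.protein_eligibility.allows_protein(cat, baseline, fvnl_pts):
        protein_pts = 0
    return {"fvnl": fvnl_pts, "protein": protein_pts, "fibre": fibre_pts}


def modifying_points(
    panel: NutrientPanel,
    cat: HSRCategory,
    baseline: int,
    tables: ScoringTables,
    missing_policy: str = "zero",
) -> int:
    return sum(
        modifying_points_breakdown(panel, cat, baseline, tables, missing_policy).values()
    )


def stars_from_score(score: int, cat: HSRCategory, tables: ScoringTables) -> float:
    """Convert a final score to stars via the category matrix."""
    for bound, stars in tables.star_matrix[cat]:
        if bound is None or score <= bound:
            return stars
    raise ConfigurationError(  # unreachable with a validated matrix
        f"star matrix for {cat.value} does not cover score {score}"
    )


@dataclass(frozen=True)
class HSRResult:
    """Outcome of scoring one product."""

    baseline_points: int
    modifying_points: int
    modifying_breakdown: Mapping[str, int]
    final_score: int
    stars: float
    automatic: bool
    category: Optional[HSRCategory] = None

    def __post_init__(self) -> None:
        if self.stars not in STAR_LATTICE:
            raise ValueError(f"stars {self.stars!r} not on the half-star lattice")
        if not self.automatic and (
            self.final_score != self.baseline_points - self.modifying_points
        ):
            raise ValueError("final_score must equal baseline - modifying")


def compute_hsr(
    product: Product,
    tables: ScoringTables,
    category: Optional[HSRCategory] = None,
    missing_policy: str = "zero",
) -> HSRResult:
    """Score one product end to end.

    Auto-rated products (plain water, plain fruit and vegetables) receive
    5.0 stars with all point fields zeroed.  Everything else runs through
    baseline points, modifying points (with the protein gate), final score
    and the category star matrix.  Pure: identical inputs give identical
    results.
    """
    if product.auto_rated:
        return HSRResult(
            baseline_points=0,
            modifying_points=0,
            modifying_breakdown={"fvnl": 0, "protein": 0, "fibre": 0},
            final_score=0,
            stars=5.0,
            automatic=True,
            category=category,
        )
    cat = category if category is not None else assign_hsr_category(product)
    base = baseline_points(product.nutrients, cat, tables)
    breakdown = modifying_points_breakdown(
        product.nutrients, cat, base, tables, missing_policy
    )
    mod = sum(breakdown.values())
    score = base - mod
    return HSRResult(
        baseline_points=base,
        modifying_points=mod,
        modifying_breakdown=breakdown,
        final_score=score,
        stars=stars_from_score(score, cat, tables),
        automatic=False,
        category=cat,
    )
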