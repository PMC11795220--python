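"""Product data model, CSV round-trip and eligibility filtering.

A :class:`Product` is one packaged food or beverage as it appears in a
supermarket audit: nutrient declarations per 100 g (or 100 mL for
beverages), fruit/vegetable/nut/legume (FVNL) percentage, the free-text
ingredient list, and category labels from a hierarchical retail taxonomy
(15 major categories, e.g. *Bread and bakery products*; subcategories such
as *pita bread*).  Optional reference labels carry a NOVA processing group
(1–4) and a dietary-guidelines verdict (core/discretionary) used only for
agreement analysis, never for scoring.

The CSV schema (one product per row, UTF-8, comma separated, header row
mandatory, decimal point only)::

    product_id,name,major_category,subcategory,hsr_category,
    energy_kj,sat_fat_g,total_sugars_g,sodium_mg,protein_g,fibre_g,fvnl_pct,
    ingredient_text,flags,nova_group,adg_label

``hsr_category`` may be empty or ``auto`` to defer to the subcategory
mapping.  ``flags`` is a ``;``-joined subset of :data:`ALLOWED_FLAGS`.
``nova_group`` and ``adg_label`` are optional columns.  Empty nutrient
cells load as *missing* (``None``), never as zero: the distinction matters
because fibre and FVNL are frequently absent from labels and the scoring
engine applies an explicit missing-value policy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import pandas as pd

from .errors import SchemaError

#: The 15 major food categories of the retail taxonomy, closed vocabulary.
MAJOR_CATEGORIES: tuple[str, ...] = (
    "Bread and bakery products",
    "Cereal and grain products",
    "Confectionery",
    "Convenience foods",
    "Dairy",
    "Edible oils and oil emulsions",
    "Egg and egg products",
    "Foods for specific dietary use",
    "Fruit, vegetables, nuts and legumes",
    "Meat and meat alternatives",
    "Non-alcoholic beverages",
    "Sauces, dressings, spreads and dips",
    "Seafood and seafood products",
    "Snack foods",
    "Sugar, honey and related products",
)

ALLOWED_FLAGS: frozenset[str] = frozenset(
    {
        "plain_water",
        "plain_fruit_veg",
        "added_fruit",
        "no_nutrition_panel",
        "hsr_excluded_category",
    }
)

#: Flags that trigger an automatic 5.0-star rating and therefore exempt a
#: product from the nutrition-panel requirement.
AUTO_RATING_FLAGS: frozenset[str] = frozenset({"plain_water", "plain_fruit_veg"})

MANDATORY_COLUMNS: tuple[str, ...] = (
    "product_id",
    "name",
    "major_category",
    "subcategory",
    "hsr_category",
    "energy_kj",
    "sat_fat_g",
    "total_sugars_g",
    "sodium_mg",
    "protein_g",
    "fibre_g",
    "fvnl_pct",
    "ingredient_text",
    "flags",
)

OPTIONAL_COLUMNS: tuple[str, ...] = ("nova_group", "adg_label")

CORE_NUTRIENTS: tuple[str, ...] = (
    "energy_kj",
    "sat_fat_g",
    "total_sugars_g",
    "sodium_mg",
)


@dataclass(frozen=True)
class NutrientPanel:
    """Declared nutrient content per 100 g (or 100 mL).

    ``None`` means the value was not declared.  Energy, saturated fat,
    total sugars and sodium are the unfavourable (baseline) components;
    protein, fibre and FVNL percentage are the favourable (modifying)
    components.
    """

    energy_kj: Optional[float] = None
    sat_fat_g: Optional[float] = None
    total_sugars_g: Optional[float] = None
    sodium_mg: Optional[float] = None
    protein_g: Optional[float] = None
    fibre_g: Optional[float] = None
    fvnl_pct: Optional[float] = None

    def __post_init__(self) -> None:
        for name in (
            "energy_kj",
            "sat_fat_g",
            "total_sugars_g",
            "sodium_mg",
            "protein_g",
            "fibre_g",
            "fvnl_pct",
        ):
            v = getattr(self, name)
            if v is None:
                continue
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v!r}")
        if self.fvnl_pct is not None and self.fvnl_pct > 100:
            raise ValueError(f"fvnl_pct cannot exceed 100, got {self.fvnl_pct!r}")
        # a mass fraction cannot exceed the reference mass
        for name in ("sat_fat_g", "total_sugars_g", "protein_g", "fibre_g"):
            v = getattr(self, name)
            if v is not None and v > 100:
                raise ValueError(f"{name} cannot exceed 100 g/100 g, got {v!r}")

    @property
    def has_core_panel(self) -> bool:
        """True when all four baseline nutrients are declared."""
        return all(
            getattr(self, n) is not None for n in CORE_NUTRIENTS
        )


@dataclass(frozen=True)
class ReferenceLabels:
    """External classifications used as comparison references."""

    nova_group: Optional[int] = None  # 1-4; 4 = ultra-processed
    adg: Optional[str] = None  # "core" | "discretionary"

    def __post_init__(self) -> None:
        if self.nova_group is not None and self.nova_group not in (1, 2, 3, 4):
            raise ValueError(f"nova_group must be 1-4, got {self.nova_group!r}")
        if self.adg is not None and self.adg not in ("core", "discretionary"):
            raise ValueError(f"adg must be core|discretionary, got {self.adg!r}")


@dataclass(frozen=True)
class Product:
    """One packaged food or beverage."""

    product_id: str
    name: str
    major_category: str
    subcategory: str
    nutrients: NutrientPanel
    hsr_category: Optional[str] = None  # explicit six-way category, or None
    ingredient_text: str = ""
    flags: frozenset[str] = frozenset()
    reference_labels: ReferenceLabels = field(default_factory=ReferenceLabels)

    def __post_init__(self) -> None:
        if not self.product_id:
            raise ValueError("product_id must be non-empty")
        if self.major_category not in MAJOR_CATEGORIES:
            raise ValueError(
                f"unknown major_category {self.major_category!r}"
            )
        bad = set(self.flags) - ALLOWED_FLAGS
        if bad:
            raise ValueError(f"unknown flags: {sorted(bad)}")

    @property
    def auto_rated(self) -> bool:
        return bool(self.flags & AUTO_RATING_FLAGS)


@dataclass(frozen=True)
class RowError:
    """Structured record of a CSV row that could not become a Product."""

    row_index: int  # 0-based data-row index
    product_id: str
    message: str


@dataclass(frozen=True)
class FilterLogEntry:
    rule: str
    n_removed: int
    removed_ids: tuple[str, ...]


@dataclass
class ProductSet:
    """An ordered collection of products with provenance and a filter log."""

    products: list[Product]
    provenance: dict = field(default_factory=dict)
    filter_log: list[FilterLogEntry] = field(default_factory=list)
    row_errors: list[RowError] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.product_id for p in self.products]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate product_id {dup!r} in ProductSet")

    def __iter__(self) -> Iterator[Product]:
        return iter(self.products)

    def __len__(self) -> int:
        return len(self.products)

    def __getitem__(self, i: int) -> Product:
        return self.products[i]

    def to_frame(self) -> pd.DataFrame:
        """Render the set as a DataFrame in the documented CSV schema."""
        rows = []
        for p in self.products:
            n = p.nutrients
            rows.append(
                {
                    "product_id": p.product_id,
                    "name": p.name,
                    "major_category": p.major_category,
                    "subcategory": p.subcategory,
                    "hsr_category": p.hsr_category or "",
                    "energy_kj": _fmt(n.energy_kj),
                    "sat_fat_g": _fmt(n.sat_fat_g),
                    "total_sugars_g": _fmt(n.total_sugars_g),
                    "sodium_mg": _fmt(n.sodium_mg),
                    "protein_g": _fmt(n.protein_g),
                    "fibre_g": _fmt(n.fibre_g),
                    "fvnl_pct": _fmt(n.fvnl_pct),
                    "ingredient_text": p.ingredient_text,
                    "flags": ";".join(sorted(p.flags)),
                    "nova_group": (
                        "" if p.reference_labels.nova_group is None
                        else str(p.reference_labels.nova_group)
                    ),
                    "adg_label": p.reference_labels.adg or "",
                }
            )
        cols = list(MANDATORY_COLUMNS) + list(OPTIONAL_COLUMNS)
        return pd.DataFrame(rows, columns=cols)


def _fmt(v: Optional[float]) -> str:
    if v is None:
        return ""
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


def _parse_float(cell: str, column: str) -> Optional[float]:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise ValueError(f"non-numeric {column} value {cell!r}") from None


def read_products(
    path: str | Path, schema_version: str = "1", strict: bool = False
) -> ProductSet:
    """Read a product CSV into a :class:`ProductSet`.

    Malformed rows become structured :class:`RowError` records on the
    returned set (or raise, with ``strict=True``); well-formed rows are
    always loaded.  A missing mandatory column raises :class:`SchemaError`
    naming the column.
    """
    if schema_version != "1":
        raise SchemaError(f"unsupported schema_version {schema_version!r}")
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing mandatory column(s): {', '.join(missing)}"
        )

    products: list[Product] = []
    errors: list[RowError] = []
    seen_ids: set[str] = set()
    for i, row in enumerate(frame.to_dict(orient="records")):
        pid = str(row.get("product_id", "")).strip()
        try:
            product = _row_to_product(row)
            if product.product_id in seen_ids:
                raise ValueError(f"duplicate product_id {product.product_id!r}")
            seen_ids.add(product.product_id)
            products.append(product)
        except ValueError as exc:
            errors.append(RowError(row_index=i, product_id=pid, message=str(exc)))
    if strict and errors:
        first = errors[0]
        raise SchemaError(
            f"{path.name}: {len(errors)} malformed row(s); first at data row "
            f"{first.row_index}: {first.message}"
        )
    return ProductSet(
        products,
        provenance={"source": str(path), "schema_version": schema_version,
                    "n_rows": len(frame), "n_row_errors": len(errors)},
        row_errors=errors,
    )


def _row_to_product(row: dict) -> Product:
    panel = NutrientPanel(
        energy_kj=_parse_float(row["energy_kj"], "energy_kj"),
        sat_fat_g=_parse_float(row["sat_fat_g"], "sat_fat_g"),
        total_sugars_g=_parse_float(row["total_sugars_g"], "total_sugars_g"),
        sodium_mg=_parse_float(row["sodium_mg"], "sodium_mg"),
        protein_g=_parse_float(row["protein_g"], "protein_g"),
        fibre_g=_parse_float(row["fibre_g"], "fibre_g"),
        fvnl_pct=_parse_float(row["fvnl_pct"], "fvnl_pct"),
    )
    flags_cell = row["flags"].strip()
    flags = frozenset(f for f in (s.strip() for s in flags_cell.split(";")) if f)
    hsr_cat = row["hsr_category"].strip()
    if hsr_cat in ("", "auto"):
        hsr_category = None
    else:
        hsr_category = hsr_cat
    nova_cell = str(row.get("nova_group", "")).strip()
    nova = None
    if nova_cell:
        try:
            nova = int(float(nova_cell))
        except ValueError:
            raise ValueError(f"non-numeric nova_group value {nova_cell!r}") from None
    adg_cell = str(row.get("adg_label", "")).strip() or None
    return Product(
        product_id=str(row["product_id"]).strip(),
        name=row["name"],
        major_category=row["major_category"].strip(),
        subcategory=row["subcategory"].strip(),
        hsr_category=hsr_category,
        nutrients=panel,
        ingredient_text=row["ingredient_text"],
        flags=flags,
        reference_labels=ReferenceLabels(nova_group=nova, adg=adg_cell),
    )


def write_products(products: ProductSet, path: str | Path) -> Path:
    """Write a ProductSet back to CSV in the documented schema."""
    path = Path(path)
    products.to_frame().to_csv(path, index=False)
    return path


def filter_eligible(products: ProductSet) -> ProductSet:
    """Apply the eligibility rules used before any rating is computed.

    Rules are checked in a fixed order so each exclusion is attributed to
    exactly one rule in the filter log:

    1. ``hsr_excluded_category`` — categories the rating scheme does not
       cover (e.g. alcoholic beverages, supplements) or is not permitted
       to appear on (e.g. infant formula).
    2. ``no_nutrition_panel`` — products without a nutrient declaration,
       *except* those that receive an automatic rating (plain bottled
       water, plain fruit and vegetables).
    3. ``missing_core_nutrients`` — panel lacks any of energy, saturated
       fat, total sugars or sodium (auto-rated products again exempt).

    Idempotent: the retained products pass every rule, so a second
    application removes nothing.
    """
    kept: list[Product] = []
    removed: dict[str, list[str]] = {
        "hsr_excluded_category": [],
        "no_nutrition_panel": [],
        "missing_core_nutrients": [],
    }
    for p in products:
        if "hsr_excluded_category" in p.flags:
            removed["hsr_excluded_category"].append(p.product_id)
        elif "no_nutrition_panel" in p.flags and not p.auto_rated:
            removed["no_nutrition_panel"].append(p.product_id)
        elif not p.nutrients.has_core_panel and not p.auto_rated:
            removed["missing_core_nutrients"].append(p.product_id)
        else:
            kept.append(p)
    log = list(products.filter_log) + [
        FilterLogEntry(rule=r, n_removed=len(ids), removed_ids=tuple(ids))
        for r, ids in removed.items()
    ]
    prov = dict(products.provenance)
    prov.update(
        {"n_before_filter": len(products), "n_after_filter": len(kept)}
    )
    return ProductSet(kept, provenance=prov, filter_log=log,
                      row_errors=list(products.row_errors))


def product_set(products: Sequence[Product], **provenance) -> ProductSet:
    """Convenience constructor used by tests and the generator."""
    return ProductSet(list(products), provenance=dict(provenance))
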