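"""The four ultra-processing modifications of the star rating (m-HSR 1-4).

Three general approaches, four variants:

* **M1 (inclusion)** — add ``penalty_points`` (default 5) baseline points
  to every ultra-processed product and recompute the final score and
  stars through the category star matrix.
* **M2 (capping)** — cap ultra-processed products at ``cap_stars``
  (default 3.0) regardless of score: a 4.5-star ultra-processed product
  becomes 3.0, a 2.0-star one is untouched.
* **M3 / M4 (hybrids)** — apply M1 / M2 respectively, but only to
  ultra-processed products that already carry at least
  ``hybrid_threshold`` (default 10) baseline points from energy,
  saturated fat, sugars and sodium.  The threshold is evaluated on the
  *pre-penalty* baseline points.

Non-ultra-processed products are never altered; automatically rated
products (plain water, plain produce) pass through unchanged — the marker
rules cannot classify them as ultra-processed, and the engine asserts
rather than assumes this in tests.

The parameters reproduce the published defaults and expose the published
sensitivity alternatives (2- and 10-point penalties).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import ConfigurationError, InputError
from .hsr import HSRResult, ScoringTables, STAR_LATTICE, stars_from_score
from .product_io import Product, ProductSet


class ModificationVariant(str, enum.Enum):
    M1_inclusion = "m1"
    M2_capping = "m2"
    M3_hybrid_inclusion = "m3"
    M4_hybrid_capping = "m4"

    @property
    def is_inclusion(self) -> bool:
        return self in (self.M1_inclusion, self.M3_hybrid_inclusion)

    @property
    def is_hybrid(self) -> bool:
        return self in (self.M3_hybrid_inclusion, self.M4_hybrid_capping)


@dataclass(frozen=True)
class ModificationParams:
    penalty_points: int = 5
    cap_stars: float = 3.0
    hybrid_threshold: int = 10

    def __post_init__(self) -> None:
        if not (isinstance(self.penalty_points, int) and self.penalty_points > 0):
            raise ConfigurationError("penalty_points must be a positive integer")
        if self.cap_stars not in STAR_LATTICE:
            raise ConfigurationError("cap_stars must be on the half-star lattice")
        if not (isinstance(self.hybrid_threshold, int) and self.hybrid_threshold > 0):
            raise ConfigurationError("hybrid_threshold must be a positive integer")


@dataclass(frozen=True)
class ModifiedResult:
    original: HSRResult
    modified_stars: float
    penalised: bool
    variant: ModificationVariant

    @property
    def shifted_lower(self) -> bool:
        return self.modified_stars < self.original.stars


def apply_modification(
    result: HSRResult,
    is_upf: bool,
    variant: ModificationVariant,
    product: Product,
    tables: ScoringTables,
    params: Optional[ModificationParams] = None,
) -> ModifiedResult:
    """Apply one modification variant to an engine result.

    ``penalised`` records whether the variant's rule was applied at all:
    for inclusion variants the penalty may leave the star outcome
    unchanged yet still count as applied; for capping variants the rule
    only bites when it lowers the stars.
    """
    params = params or ModificationParams()
    unchanged = ModifiedResult(
        original=result, modified_stars=result.stars, penalised=False, variant=variant
    )
    if not is_upf or result.automatic:
        return unchanged
    if variant.is_hybrid and result.baseline_points < params.hybrid_threshold:
        return unchanged

    if variant.is_inclusion:
        if result.category is None:
            raise InputError("inclusion variants need the result's category "
                             "to recompute stars")
        new_score = (result.baseline_points + params.penalty_points) - (
            result.modifying_points
        )
        new_stars = stars_from_score(new_score, result.category, tables)
        return ModifiedResult(
            original=result,
            modified_stars=new_stars,
            penalised=True,
            variant=variant,
        )
    # capping
    capped = min(result.stars, params.cap_stars)
    return ModifiedResult(
        original=result,
        modified_stars=capped,
        penalised=capped != result.stars,
        variant=variant,
    )


def apply_batch(
    products: ProductSet | Sequence[Product],
    results: Sequence[HSRResult],
    upf_flags: Sequence[bool],
    variant: ModificationVariant,
    tables: ScoringTables,
    params: Optional[ModificationParams] = None,
) -> list[ModifiedResult]:
    """Elementwise :func:`apply_modification`, order preserved."""
    if not (len(products) == len(results) == len(upf_flags)):
        raise InputError(
            f"length mismatch: {len(products)} products, {len(results)} results, "
            f"{len(upf_flags)} flags"
        )
    return [
        apply_modification(r, u, variant, p, tables, params)
        for p, r, u in zip(products, results, upf_flags)
    ]
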