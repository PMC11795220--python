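"""Agreement of (modified) star ratings with reference classifications.

A rating is dichotomised at a star cut-off (default 3.5, sensitivity 2.5):
products rated below the cut-off "should" be ultra-processed (NOVA group
4) or discretionary, products at or above it "should" be NOVA 1-3 or
core.  *Alignment* is the proportion of products for which the dichotomy
and the reference label agree, reported overall and per major food
category.  The module also summarises rating distributions
(median / interquartile range) and counts ultra-processed products whose
rating shifted lower under a modification.

Descriptive only: no inferential statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .hsr import STAR_LATTICE
from .product_io import Product

_OVERALL = "Overall"


@dataclass(frozen=True)
class AlignmentScheme:
    reference: str  # "nova" | "adg"
    star_cutoff: float = 3.5

    def __post_init__(self) -> None:
        if self.reference not in ("nova", "adg"):
            raise ValueError(f"reference must be nova|adg, got {self.reference!r}")
        if self.star_cutoff not in STAR_LATTICE:
            raise ValueError("star_cutoff must lie on the half-star lattice")


def is_aligned(stars: float, reference_label, scheme: AlignmentScheme) -> bool:
    """True when the dichotomised rating agrees with the reference label.

    For the NOVA reference the label is the group 1-4 (4 = ultra-
    processed); for the dietary-guidelines reference it is
    "core"/"discretionary".  Agreement: stars below the cut-off with an
    unfavourable label (NOVA 4 / discretionary), or stars at or above the
    cut-off with a favourable one (NOVA 1-3 / core).
    """
    if reference_label is None:
        raise InputError("reference label is missing")
    if scheme.reference == "nova":
        if reference_label not in (1, 2, 3, 4):
            raise InputError(f"nova_group must be 1-4, got {reference_label!r}")
        unfavourable = reference_label == 4
    else:
        if reference_label not in ("core", "discretionary"):
            raise InputError(f"adg label must be core|discretionary, "
                             f"got {reference_label!r}")
        unfavourable = reference_label == "discretionary"
    below = stars < scheme.star_cutoff
    return below == unfavourable


def _label_of(product: Product, scheme: AlignmentScheme):
    if scheme.reference == "nova":
        return product.reference_labels.nova_group
    return product.reference_labels.adg


@dataclass
class AlignmentSummary:
    """Per-category and overall agreement counts (reference-vs-rating)."""

    scheme: AlignmentScheme
    table: pd.DataFrame  # index: group; columns: n, aligned_n, aligned_pct, aligned_pct_int
    missing_labels: int = 0
    empty_groups: tuple[str, ...] = ()

    @property
    def overall_pct(self) -> float:
        return float(self.table.loc[_OVERALL, "aligned_pct"])


def summarise_alignment(
    products: Sequence[Product],
    stars: Sequence[float],
    scheme: AlignmentScheme,
) -> AlignmentSummary:
    """Alignment counts and percentages, overall and by major category.

    Products without the relevant reference label are excluded from the
    counts and tallied in ``missing_labels``.  Percentages are carried at
    one decimal (``aligned_pct``) and rounded to integers
    (``aligned_pct_int``, round-half-even as numpy rounds) to match a
    whole-percent reporting style; an empty group keeps n=0 with NaN
    percentage and is flagged in ``empty_groups``.
    """
    if len(products) != len(stars):
        raise InputError(
            f"length mismatch: {len(products)} products vs {len(stars)} ratings"
        )
    rows: list[dict] = []
    missing = 0
    for p, s in zip(products, stars):
        label = _label_of(p, scheme)
        if label is None:
            missing += 1
            continue
        rows.append(
            {
                "group": p.major_category,
                "aligned": is_aligned(s, label, scheme),
            }
        )
    frame = pd.DataFrame(rows, columns=["group", "aligned"])
    groups = sorted(frame["group"].unique()) if len(frame) else []
    records = []
    for name in [_OVERALL] + groups:
        sub = frame if name == _OVERALL else frame[frame["group"] == name]
        n = int(len(sub))
        aligned_n = int(sub["aligned"].sum()) if n else 0
        pct = round(100.0 * aligned_n / n, 1) if n else float("nan")
        records.append(
            {
                "group": name,
                "n": n,
                "aligned_n": aligned_n,
                "aligned_pct": pct,
                "aligned_pct_int": int(np.round(pct)) if n else pd.NA,
            }
        )
    table = pd.DataFrame.from_records(records).set_index("group")
    empty = tuple(g for g in groups if table.loc[g, "n"] == 0)
    return AlignmentSummary(
        scheme=scheme, table=table, missing_labels=missing, empty_groups=empty
    )


def summarise_distribution(
    products: Sequence[Product], stars: Sequence[float]
) -> pd.DataFrame:
    """Median and quartiles of star ratings, overall and by major category.

    Quantiles use midpoint interpolation, a fixed documented convention:
    midpoints of half-star values land on the quarter-star grid (e.g.
    stars {1,2,3,4} give median 2.5).
    """
    if len(products) != len(stars):
        raise InputError("length mismatch between products and ratings")
    frame = pd.DataFrame(
        {
            "group": [p.major_category for p in products],
            "stars": list(stars),
        }
    )
    groups = sorted(frame["group"].unique()) if len(frame) else []
    records = []
    for name in [_OVERALL] + groups:
        sub = frame if name == _OVERALL else frame[frame["group"] == name]
        vals = sub["stars"].to_numpy(dtype=float)
        if len(vals) == 0:
            records.append({"group": name, "n": 0, "median": float("nan"),
                            "q25": float("nan"), "q75": float("nan")})
            continue
        q25, med, q75 = np.percentile(vals, [25, 50, 75], method="midpoint")
        records.append(
            {"group": name, "n": int(len(vals)), "median": float(med),
             "q25": float(q25), "q75": float(q75)}
        )
    return pd.DataFrame.from_records(records).set_index("group")


@dataclass
class ShiftCounts:
    """Ultra-processed products whose rating fell under a modification."""

    n_upf: int
    shifted_lower: int
    shifted_pct: float
    per_category: pd.DataFrame = field(default_factory=pd.DataFrame)


def count_shifts(
    original_stars: Sequence[float],
    modified_stars: Sequence[float],
    upf_flags: Sequence[bool],
    categories: Optional[Sequence[str]] = None,
) -> ShiftCounts:
    """Count ultra-processed products with a strictly lower modified rating."""
    if not (len(original_stars) == len(modified_stars) == len(upf_flags)):
        raise InputError("length mismatch between ratings and flags")
    if categories is not None and len(categories) != len(upf_flags):
        raise InputError("length mismatch for categories")
    frame = pd.DataFrame(
        {
            "orig": list(original_stars),
            "mod": list(modified_stars),
            "upf": list(upf_flags),
            "group": list(categories) if categories is not None else "",
        }
    )
    upf = frame[frame["upf"]]
    n_upf = int(len(upf))
    shifted = int((upf["mod"] < upf["orig"]).sum())
    pct = round(100.0 * shifted / n_upf, 1) if n_upf else 0.0
    per_cat = pd.DataFrame()
    if categories is not None and n_upf:
        per_cat = (
            upf.assign(shift=upf["mod"] < upf["orig"])
            .groupby("group")
            .agg(n_upf=("shift", "size"), shifted_lower=("shift", "sum"))
        )
    return ShiftCounts(
        n_upf=n_upf, shifted_lower=shifted, shifted_pct=pct, per_category=per_cat
    )
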