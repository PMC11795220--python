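"""Core/discretionary classification rule engine.

Australian dietary guidance splits packaged foods into *core* (the five
recommended food groups) and *discretionary* (energy-dense, nutrient-poor
foods to limit).  The national statistics office operationalises this as a
category list augmented with nutrient criteria where category membership
alone is ambiguous — e.g. breakfast cereals become discretionary at
>=30 g sugars/100 g (>=35 g with added fruit).

This module is the rule *engine*; the rule *content* is YAML config
(:func:`load_default_rules`) seeded with that cereal criterion and plain
category verdicts.  Every verdict carries the identifier of the rule that
fired, so classifications are auditable.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import yaml

from .errors import ConfigurationError
from .product_io import Product

_OPS = {">=": operator.ge, ">": operator.gt, "<=": operator.le, "<": operator.lt}


@dataclass(frozen=True)
class CriterionPredicate:
    """One nutrient predicate inside a ``criteria`` rule."""

    id: str
    nutrient: str
    op: str
    threshold: float
    verdict: str
    require_flag: Optional[str] = None
    forbid_flag: Optional[str] = None

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ConfigurationError(f"unknown comparator {self.op!r}")
        if self.threshold < 0:
            raise ConfigurationError("thresholds must be non-negative")
        if self.verdict not in ("core", "discretionary"):
            raise ConfigurationError(f"bad predicate verdict {self.verdict!r}")

    def applies(self, product: Product) -> bool:
        if self.require_flag and self.require_flag not in product.flags:
            return False
        if self.forbid_flag and self.forbid_flag in product.flags:
            return False
        value = getattr(product.nutrients, self.nutrient, None)
        if value is None:
            return False
        return _OPS[self.op](value, self.threshold)


@dataclass(frozen=True)
class CategoryRule:
    key: str
    verdict: str  # always_core | always_discretionary | criteria
    default: Optional[str] = None
    criteria: tuple[CriterionPredicate, ...] = ()

    def __post_init__(self) -> None:
        if self.verdict not in ("always_core", "always_discretionary", "criteria"):
            raise ConfigurationError(f"bad rule verdict {self.verdict!r}")
        if self.verdict == "criteria" and self.default not in ("core", "discretionary"):
            raise ConfigurationError(
                f"criteria rule {self.key!r} needs a default verdict"
            )


@dataclass(frozen=True)
class ADGLabel:
    verdict: str  # core | discretionary
    rule_id: str

    def __post_init__(self) -> None:
        if self.verdict not in ("core", "discretionary"):
            raise ValueError(f"bad verdict {self.verdict!r}")
        if not self.rule_id:
            raise ValueError("rule_id must be populated")


@dataclass(frozen=True)
class ADGRuleSet:
    rules: dict[str, CategoryRule]  # keyed by normalized subcategory/major
    source: str = "in-memory"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ADGRuleSet":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        rules: dict[str, CategoryRule] = {}
        for key, body in (raw.get("rules") or {}).items():
            norm = str(key).strip().lower()
            preds = tuple(
                CriterionPredicate(
                    id=str(p["id"]),
                    nutrient=str(p["nutrient"]),
                    op=str(p["op"]),
                    threshold=float(p["threshold"]),
                    verdict=str(p["verdict"]),
                    require_flag=p.get("require_flag"),
                    forbid_flag=p.get("forbid_flag"),
                )
                for p in body.get("criteria") or ()
            )
            rules[norm] = CategoryRule(
                key=norm,
                verdict=str(body["verdict"]),
                default=body.get("default"),
                criteria=preds,
            )
        return cls(rules=rules, source=str(path))

    def resolve(self, product: Product) -> CategoryRule:
        for key in (
            product.subcategory.strip().lower(),
            product.major_category.strip().lower(),
        ):
            if key in self.rules:
                return self.rules[key]
        raise ConfigurationError(
            f"no core/discretionary rule resolves subcategory "
            f"{product.subcategory!r} or category {product.major_category!r}"
        )


def load_default_rules() -> ADGRuleSet:
    ref = resources.files("starmod.data").joinpath("adg_rules.yaml")
    with resources.as_file(ref) as path:
        return ADGRuleSet.from_yaml(path)


def classify_adg(product: Product, rules: Optional[ADGRuleSet] = None) -> ADGLabel:
    """Classify one product as core or discretionary.

    Plain verdicts return directly; ``criteria`` rules evaluate predicates
    in order with first match winning, falling back to the rule's declared
    default.  Deterministic and total over any product whose subcategory
    or major category is covered.
    """
    if rules is None:
        rules = load_default_rules()
    rule = rules.resolve(product)
    if rule.verdict == "always_core":
        return ADGLabel("core", rule_id=f"{rule.key}:always_core")
    if rule.verdict == "always_discretionary":
        return ADGLabel("discretionary", rule_id=f"{rule.key}:always_discretionary")
    for pred in rule.criteria:
        if pred.applies(product):
            return ADGLabel(pred.verdict, rule_id=f"{rule.key}:{pred.id}")
    return ADGLabel(rule.default, rule_id=f"{rule.key}:default")  # type: ignore[arg-type]


def classify_adg_batch(
    products: Iterable[Product], rules: Optional[ADGRuleSet] = None
) -> list[ADGLabel]:
    if rules is None:
        rules = load_default_rules()
    return [classify_adg(p, rules) for p in products]
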