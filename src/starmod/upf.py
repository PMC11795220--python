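"""Ingredient-list parsing and ultra-processed food classification.

The classifier implements an adapted NOVA approach: a product is deemed
ultra-processed (NOVA group 4) when its ingredient list contains at least
one *marker of ultra-processing* — a cosmetic additive class (anti-caking,
firming or glazing agent, colour, flavour, emulsifier, extract, thickener),
a sweetener other than sugar, maple syrup or honey, a whole-food component
included as an isolate (lactose, wheat gluten, triglycerides, ...), or a
protein powder.  Vitamins, minerals, live cultures, and acids/acidity
regulators are explicitly not markers; an exemption list is consulted
before any marker match.

The marker vocabulary is data (:func:`load_default_lexicon`), not code.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import yaml

from .errors import ConfigurationError
from .product_io import Product

MARKER_CLASSES = frozenset(
    {
        "anti_caking_agent",
        "firming_agent",
        "glazing_agent",
        "colour",
        "flavour",
        "emulsifier",
        "extract",
        "thickener",
        "non_exempt_sweetener",
        "isolate",
        "protein_powder",
    }
)

# additive code shapes: "1442", "160b", "e471", "ins 1442"
_CODE_RE = re.compile(r"^(?:e|ins)?\s*(\d{3,4})\s*([a-z])?$", re.IGNORECASE)
# punctuation stripped during normalization; parentheses never reach here
# because the tokenizer consumes them
_PUNCT_RE = re.compile(r"[^0-9a-z\s]")


def normalize_term(text: str) -> str:
    """Lowercase, strip punctuation (parentheses excepted upstream) and
    collapse whitespace."""
    return re.sub(r"\s+", " ", _PUNCT_RE.sub(" ", text.lower())).strip()


@dataclass(frozen=True)
class IngredientToken:
    """One ingredient phrase with its parenthetical nesting depth."""

    text: str
    depth: int

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")


def parse_ingredients(text: str) -> list[IngredientToken]:
    """Tokenize a free-text ingredient list.

    Splits on commas at the current nesting depth; a parenthesised group
    becomes child tokens at depth+1 (the text before the parenthesis stays
    a token at the parent depth).  Percentages and bracketed numbers are
    retained in token text.  Unbalanced parentheses trigger a warning and
    a best-effort parse.  Deterministic.
    """
    tokens: list[IngredientToken] = []
    if not text or not text.strip():
        return tokens

    depth = 0
    buf: list[str] = []
    unbalanced = False

    def flush() -> None:
        chunk = buf and "".join(buf).strip(" ;.")
        if chunk:
            tokens.append(IngredientToken(text=chunk.strip(), depth=depth))
        buf.clear()

    for ch in text:
        if ch == "(" or ch == "[":
            flush()
            depth += 1
        elif ch == ")" or ch == "]":
            flush()
            if depth == 0:
                unbalanced = True
            else:
                depth -= 1
        elif ch == ",":
            flush()
        else:
            buf.append(ch)
    if depth != 0:
        unbalanced = True
    depth = max(depth, 0)
    flush()
    if unbalanced:
        warnings.warn("unbalanced parentheses in ingredient list; "
                      "tokens parsed best-effort", stacklevel=2)
    return tokens


@dataclass(frozen=True)
class MarkerLexicon:
    """Marker terms, exemptions and additive codes, all normalized."""

    marker_terms: dict[str, str]
    exempt_terms: frozenset[str]
    additive_code_map: dict[str, str]
    source: str = "in-memory"

    def __post_init__(self) -> None:
        bad = set(self.marker_terms.values()) - MARKER_CLASSES
        if bad:
            raise ConfigurationError(f"unknown marker classes: {sorted(bad)}")
        bad = set(self.additive_code_map.values()) - MARKER_CLASSES
        if bad:
            raise ConfigurationError(f"unknown additive-code classes: {sorted(bad)}")
        overlap = set(self.marker_terms) & self.exempt_terms
        if overlap:
            raise ConfigurationError(
                f"terms both marker and exempt: {sorted(overlap)}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MarkerLexicon":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(
            marker_terms={
                normalize_term(t): c for t, c in (raw.get("marker_terms") or {}).items()
            },
            exempt_terms=frozenset(
                normalize_term(t) for t in raw.get("exempt_terms") or []
            ),
            additive_code_map={
                str(code).strip().lower(): c
                for code, c in (raw.get("additive_code_map") or {}).items()
            },
            source=str(path),
        )


def load_default_lexicon() -> MarkerLexicon:
    ref = resources.files("starmod.data").joinpath("upf_lexicon.yaml")
    with resources.as_file(ref) as path:
        return MarkerLexicon.from_yaml(path)


@lru_cache(maxsize=8192)
def _term_pattern(term: str) -> re.Pattern:
    return re.compile(rf"(?<![0-9a-z]){re.escape(term)}(?![0-9a-z])")


def _phrase_in(term: str, text: str) -> bool:
    """Whole-word phrase containment on normalized text."""
    return _term_pattern(term).search(text) is not None


def match_marker(
    token: IngredientToken, lexicon: MarkerLexicon
) -> list[tuple[str, str]]:
    """Markers matched by one token, as (term, class) pairs.

    The exemption check runs first: a token matching any exempt term
    yields no markers at all ("raw sugar" never matches via "sugar"-free
    marker substrings).  Otherwise marker terms are matched as whole-word
    phrases with longest-match preference (a token matching both
    "natural flavour" and "flavour" reports only the former), and the raw
    token is checked against the additive-code map.
    """
    raw = token.text.strip()
    norm = normalize_term(raw)
    if not norm:
        return []
    for exempt in lexicon.exempt_terms:
        if _phrase_in(exempt, norm):
            return []
    hits = [t for t in lexicon.marker_terms if _phrase_in(t, norm)]
    # longest-match: drop any matched term wholly contained in another match
    hits = [
        t for t in hits
        if not any(o != t and _phrase_in(t, o) for o in hits)
    ]
    out = [(t, lexicon.marker_terms[t]) for t in sorted(hits)]
    m = _CODE_RE.match(raw.strip())
    if m:
        code = (m.group(1) + (m.group(2) or "")).lower()
        if code in lexicon.additive_code_map:
            out.append((code, lexicon.additive_code_map[code]))
    return out


@dataclass(frozen=True)
class UPFAnnotation:
    """Ultra-processed verdict with the matched markers for audit."""

    is_upf: bool
    matches: tuple[tuple[str, str, str], ...]  # (token text, term, class)

    def __post_init__(self) -> None:
        if self.is_upf != bool(self.matches):
            raise ValueError("is_upf must hold exactly when matches are non-empty")

    @property
    def matched_classes(self) -> frozenset[str]:
        return frozenset(c for _, _, c in self.matches)


def classify_upf(
    product: Product, lexicon: Optional[MarkerLexicon] = None
) -> UPFAnnotation:
    """Classify a product as ultra-processed from its ingredient text.

    Tokens at every nesting depth are matched; one marker suffices.  An
    empty ingredient list yields a non-ultra-processed verdict.
    """
    if lexicon is None:
        lexicon = load_default_lexicon()
    matches: list[tuple[str, str, str]] = []
    for token in parse_ingredients(product.ingredient_text):
        for term, cls in match_marker(token, lexicon):
            matches.append((token.text, term, cls))
    return UPFAnnotation(is_upf=bool(matches), matches=tuple(matches))


def classify_upf_batch(
    products: Iterable[Product], lexicon: Optional[MarkerLexicon] = None
) -> list[UPFAnnotation]:
    if lexicon is None:
        lexicon = load_default_lexicon()
    return [classify_upf(p, lexicon) for p in products]
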