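"""Feature queries over the pattern catalog.

A query is a conjunction of (category, value) constraints over
``shape / color / size / texture / relationship / relative position /
body position``.  A term matches when its (sub-pattern-expanded) clauses
satisfy every constraint; *appearance* constraints — shape, color, size,
texture, relative position — must be co-satisfied by a single shape
clause (a "dark circle" is one clause that is both dark and a circle),
while relationship and body position may be satisfied anywhere in the
clause set.  ``subsumes`` match mode walks the color hierarchy downward
(a query for Dark accepts a clause colored Black); ``exact`` mode
requires the literal value.

Results are ordered by number of matched clauses (descending), then term
(ascending), so the ordering is deterministic.

Free-text queries of the form "<color adjective> <shape noun>" ("dark
circles", "white lines") are parsed by a fixed grammar with plural
folding; anything else raises, pointing the caller at the structured
query form — no general natural-language parsing is attempted.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from typing import Optional

from .catalog import (
    BODY_POSITIONS,
    Catalog,
    ElementClause,
    RELATIONSHIPS,
    RELATIVE_POSITIONS,
    decompose,
)
from .errors import UnknownTermError, ValidationError, VocabularyError
from .model import POLYGON_CARDINALITY, SHAPE_ALIASES, SHAPE_KINDS, SIZES, TEXTURES
from .palette import COLOR_SUBSUMPTION, default_palette

QUERY_CATEGORIES = (
    "shape",
    "color",
    "size",
    "texture",
    "relationship",
    "relative position",
    "body position",
)

#: appearance constraints must hold on one and the same shape clause
_CLAUSE_LEVEL = ("shape", "color", "size", "texture", "relative position")


def _color_closure() -> dict[str, frozenset[str]]:
    """Transitive closure of the color subsumption hierarchy."""
    closure: dict[str, set[str]] = {k: set(v) for k, v in COLOR_SUBSUMPTION.items()}
    changed = True
    while changed:
        changed = False
        for k, vs in closure.items():
            for v in list(vs):
                extra = closure.get(v, set()) - vs
                if extra:
                    vs |= extra
                    changed = True
    return {k: frozenset(v) for k, v in closure.items()}


_COLOR_CLOSURE = _color_closure()


@dataclass(frozen=True)
class FeatureQuery:
    """A conjunction of feature constraints; empty matches everything."""

    shape: Optional[str] = None
    color: Optional[str] = None
    size: Optional[str] = None
    texture: Optional[str] = None
    relationship: Optional[str] = None
    relative_position: Optional[str] = None
    body_position: Optional[str] = None
    match_mode: str = "subsumes"

    def constraints(self) -> dict[str, str]:
        pairs = {
            "shape": self.shape,
            "color": self.color,
            "size": self.size,
            "texture": self.texture,
            "relationship": self.relationship,
            "relative position": self.relative_position,
            "body position": self.body_position,
        }
        return {k: v for k, v in pairs.items() if v is not None}


def _suggest(value: str, vocabulary) -> str:
    hits = difflib.get_close_matches(value, list(vocabulary), n=3, cutoff=0.5)
    return f" (did you mean: {', '.join(hits)}?)" if hits else ""


def validate_query(q: FeatureQuery) -> FeatureQuery:
    """Check every constraint value against its registered vocabulary."""
    if q.match_mode not in ("exact", "subsumes"):
        raise ValidationError(f"match_mode must be 'exact' or 'subsumes', got {q.match_mode!r}")
    colors = set(default_palette())
    vocab = {
        "shape": set(SHAPE_KINDS) | set(POLYGON_CARDINALITY),
        "color": colors,
        "size": set(SIZES),
        "texture": set(TEXTURES),
        "relationship": set(RELATIONSHIPS),
        "relative position": set(RELATIVE_POSITIONS),
        "body position": set(BODY_POSITIONS),
    }
    for cat, value in q.constraints().items():
        if value not in vocab[cat]:
            raise VocabularyError(
                f"unknown {cat} value {value!r}{_suggest(value, vocab[cat])}"
            )
    return q


def _color_matches(query_color: str, clause_colors: tuple[str, ...], mode: str) -> bool:
    if not clause_colors:
        return False
    if query_color in clause_colors:
        return True
    if mode == "subsumes":
        return bool(_COLOR_CLOSURE.get(query_color, frozenset()) & set(clause_colors))
    return False


def clause_satisfies(c: ElementClause, constraints: dict[str, str], mode: str) -> bool:
    """Does a single shape clause co-satisfy all clause-level constraints?"""
    if c.role != "shape-requirement":
        return False
    for cat, value in constraints.items():
        if cat not in _CLAUSE_LEVEL:
            continue
        if cat == "shape" and c.shape_kind != value:
            return False
        if cat == "color" and not _color_matches(value, c.color, mode):
            return False
        if cat == "size" and c.size != value:
            return False
        if cat == "texture" and c.texture != value:
            return False
        if cat == "relative position" and c.relative_position != value:
            return False
    return True


def _term_matches(clauses: list[ElementClause], d_body: Optional[str],
                  constraints: dict[str, str], mode: str) -> list[ElementClause]:
    """Matched clauses if the term satisfies the query, else []."""
    clause_level = {k: v for k, v in constraints.items() if k in _CLAUSE_LEVEL}
    matched: list[ElementClause] = []
    if clause_level:
        matched = [c for c in clauses if clause_satisfies(c, clause_level, mode)]
        if not matched:
            return []
    if "relationship" in constraints:
        want = constraints["relationship"]
        rel_hits = [c for c in clauses if c.role == "shape-requirement" and c.relationship == want]
        if not rel_hits:
            return []
        matched.extend(c for c in rel_hits if c not in matched)
    if "body position" in constraints:
        want = constraints["body position"]
        bp_hits = [c for c in clauses if c.role == "body-position" and c.value == want]
        if not bp_hits and d_body != want:
            return []
        matched.extend(c for c in bp_hits if c not in matched)
    if not constraints:
        matched = list(clauses)
    return matched


def find_patterns(q: FeatureQuery, catalog: Catalog) -> list[tuple[str, list[ElementClause]]]:
    """Terms satisfying every constraint, with their matched clauses.

    Deterministic order: matched-clause count descending, then term
    ascending.  An empty query returns every registered term.
    """
    validate_query(q)
    constraints = q.constraints()
    results = []
    for term in catalog.terms():
        clauses = decompose(term, catalog)
        matched = _term_matches(clauses, catalog.definitions[term].body_position, constraints, q.match_mode)
        if matched or not constraints:
            results.append((term, matched))
    results.sort(key=lambda r: (-len(r[1]), r[0]))
    return results


def features_of(term: str, catalog: Catalog) -> dict[str, list[str]]:
    """Complete, deterministic category -> values listing for one term."""
    canonical = catalog.resolve(term)  # raises UnknownTermError
    clauses = decompose(canonical, catalog)
    d = catalog.definitions[canonical]
    out: dict[str, list[str]] = {}

    def add(cat: str, value: Optional[str]):
        if value:
            out.setdefault(cat, [])
            if value not in out[cat]:
                out[cat].append(value)

    for c in clauses:
        if c.role == "shape-requirement":
            add("shape", c.shape_kind)
            for col in c.color:
                add("color", col)
            add("size", c.size)
            add("texture", c.texture)
            add("relationship", c.relationship)
            add("relative position", c.relative_position)
        elif c.role == "relation-assertion":
            add("spatial predicate", c.predicate)
        elif c.role == "spatial-pattern":
            add("spatial pattern", c.value)
        elif c.role == "body-position":
            add("body position", c.value)
    add("body position", d.body_position)
    return {k: sorted(v) for k, v in sorted(out.items())}


# ---------------------------------------------------------------------------
# fixed-grammar text queries


def parse_query(text: str) -> FeatureQuery:
    """Parse "<color adjective> <shape noun>" ("dark circles") into a
    structured query; plural shape nouns are folded.  Anything outside
    this grammar raises, asking for a structured query.
    """
    tokens = text.strip().lower().split()
    if len(tokens) < 2:
        raise ValidationError(
            f"cannot parse {text!r}: expected '<color> <shape>' (e.g. 'dark circles'); "
            "use a structured FeatureQuery for anything richer"
        )
    shape_word = tokens[-1]
    singular = shape_word[:-1] if shape_word.endswith("s") else shape_word
    shape = None
    for cand in (shape_word, singular):
        for kind in SHAPE_KINDS + tuple(POLYGON_CARDINALITY):
            if cand == kind.lower():
                shape = kind
        if cand in SHAPE_ALIASES:
            shape = SHAPE_ALIASES[cand][0]
    if shape is None:
        raise ValidationError(
            f"cannot parse {text!r}: {shape_word!r} is not a known shape noun; "
            "use a structured FeatureQuery"
        )
    color_text = " ".join(tokens[:-1])
    palette = {name.lower(): name for name in default_palette()}
    color = palette.get(color_text)
    if color is None:
        raise ValidationError(
            f"cannot parse {text!r}: {color_text!r} is not a known color"
            f"{_suggest(color_text, palette)}; use a structured FeatureQuery"
        )
    return FeatureQuery(shape=shape, color=color)
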