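"""Declarative catalog of metaphoric dermoscopic patterns.

Each metaphoric term (``Pseudopods``, ``Pigment Network``, ``Rosettes``,
...) is decomposed into a set of *element clauses* over the visual-element
vocabulary: shape requirements (kind, color, size, texture, stroke,
relative position, arrangement relationship), references to sub-patterns,
pairwise spatial-relation assertions, an overall spatial pattern, a body
position, and free-text annotations for non-visual information (e.g. the
imaging modality a pattern is detected under).

Similar terms are grouped into higher-level patterns (Blotch, Globules,
Dots, Streaks, Shiny White Structures, Network); the group index is
derived from each definition's ``group`` field.

Catalog files are YAML: a list of term documents with keys
``term / alt_labels / group / clauses / body_position / annotations``.
The loader validates strictly and reports the YAML line of each offending
document.  A built-in catalog covering the pattern definitions whose
decompositions are fixed by the published consensus descriptions ships
with the package; clauses inferred for terms whose decomposition is only
named, not spelled out, carry a ``provisional`` annotation.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import yaml

from .errors import UnknownTermError, ValidationError, VocabularyError
from .geometry import PREDICATES
from .model import (
    POLYGON_CARDINALITY,
    SHAPE_ALIASES,
    SHAPE_KINDS,
    SIZES,
    SPATIAL_PATTERNS,
    STROKE_WIDTH_CATEGORIES,
    TEXTURES,
)
from .palette import default_palette

CLAUSE_ROLES = (
    "shape-requirement",
    "subpattern-reference",
    "relation-assertion",
    "spatial-pattern",
    "body-position",
    "annotation",
)

RELATIONSHIPS = (
    "Interconnecting",
    "Incomplete Connection",
    "Non-interconnecting",
    "Parallel",
    "Orthogonal",
    "Radial",
    "Clustered",
    "Distributed",
    "Symmetrical",
    "Asymmetrical",
    "Uniform",
    "Variable",
)

RELATIVE_POSITIONS = ("Center", "Off-Center", "Periphery")

BODY_POSITIONS = ("Face", "Volar")

#: Pairwise predicates usable in relation assertions; ``spatialCover`` is
#: accepted as an alternative label for ``spatialCovers``.
PAIR_PREDICATES = PREDICATES + ("spatialCover",)
_PREDICATE_ALIASES = {"spatialCover": "spatialCovers", "spatialMeets": "spatialMeet"}

#: Fields each clause role may populate.
_ROLE_FIELDS = {
    "shape-requirement": {
        "shape_kind", "color", "size", "texture", "stroke", "relative_position", "relationship",
    },
    "subpattern-reference": {"pattern_ref", "expand"},
    "relation-assertion": {"subject", "predicate", "object"},
    "spatial-pattern": {"value"},
    "body-position": {"value"},
    "annotation": {"text"},
}

#: Fixed category inventory for the coverage audit, in report order.
AUDIT_CATEGORIES = (
    "shape",
    "color",
    "size",
    "texture",
    "spatial relationship",
    "relative position",
    "body position",
)


@dataclass(frozen=True)
class ElementClause:
    """One declarative requirement inside a pattern definition."""

    role: str
    shape_kind: Optional[str] = None
    color: tuple[str, ...] = ()  # acceptable alternatives
    size: Optional[str] = None
    texture: Optional[str] = None
    stroke: Optional[dict] = None
    relative_position: Optional[str] = None
    relationship: Optional[str] = None
    pattern_ref: Optional[str] = None
    expand: bool = True
    subject: Optional[str] = None
    predicate: Optional[str] = None
    object: Optional[str] = None
    value: Optional[str] = None
    text: Optional[str] = None

    def __post_init__(self):
        if self.role not in CLAUSE_ROLES:
            raise VocabularyError(f"unknown clause role {self.role!r}; expected one of {CLAUSE_ROLES}")
        allowed = _ROLE_FIELDS[self.role]
        defaults = {"color": (), "expand": True}
        for name in ("shape_kind", "color", "size", "texture", "stroke", "relative_position",
                     "relationship", "pattern_ref", "expand", "subject", "predicate", "object",
                     "value", "text"):
            v = getattr(self, name)
            if name in allowed:
                continue
            if v != defaults.get(name, None):
                raise ValidationError(
                    f"clause role {self.role!r} may not set field {name!r}"
                )


@dataclass(frozen=True)
class PatternDefinition:
    """Decomposition of one metaphoric term into element clauses."""

    term: str
    clauses: tuple[ElementClause, ...]
    alt_labels: tuple[str, ...] = ()
    group: Optional[str] = None
    body_position: Optional[str] = None
    annotations: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.clauses:
            raise ValidationError(f"pattern definition {self.term!r} needs at least one clause")
        if self.body_position is not None and self.body_position not in BODY_POSITIONS:
            raise VocabularyError(
                f"{self.term!r}: unknown body position {self.body_position!r}; "
                f"expected one of {BODY_POSITIONS}"
            )


@dataclass
class Catalog:
    """Mapping of metaphoric terms to their definitions, plus group index."""

    definitions: dict[str, PatternDefinition] = field(default_factory=dict)
    _labels: dict[str, str] = field(default_factory=dict)  # casefolded label -> term

    def __len__(self) -> int:
        return len(self.definitions)

    def terms(self) -> list[str]:
        return sorted(self.definitions)

    def resolve(self, label: str) -> str:
        """Resolve a term or alternative label (case-insensitive) to the
        canonical term name."""
        key = label.strip().casefold()
        if key in self._labels:
            return self._labels[key]
        suggestions = difflib.get_close_matches(key, list(self._labels), n=3, cutoff=0.6)
        raise UnknownTermError(label, [self._labels[s] for s in suggestions])

    def __contains__(self, label: str) -> bool:
        return label.strip().casefold() in self._labels


def _known_colors() -> frozenset[str]:
    return frozenset(default_palette())


def _validate_clause(c: ElementClause, term: str) -> ElementClause:
    """Vocabulary-check one clause; returns the (possibly normalized) clause."""
    where = f"{term!r}"
    if c.role == "shape-requirement":
        kind = c.shape_kind
        if kind is None:
            raise ValidationError(f"{where}: shape-requirement clause needs shape_kind")
        if kind.lower() in SHAPE_ALIASES:
            kind = SHAPE_ALIASES[kind.lower()][0]
        if kind not in SHAPE_KINDS and kind not in POLYGON_CARDINALITY:
            raise VocabularyError(f"{where}: unknown shape kind {c.shape_kind!r}")
        colors = _known_colors()
        for col in c.color:
            if col not in colors:
                raise VocabularyError(f"{where}: unknown color {col!r}")
        if c.size is not None and c.size not in SIZES:
            raise VocabularyError(f"{where}: unknown size {c.size!r}")
        if c.texture is not None and c.texture not in TEXTURES:
            raise VocabularyError(f"{where}: unknown texture {c.texture!r}")
        if c.relative_position is not None and c.relative_position not in RELATIVE_POSITIONS:
            raise VocabularyError(f"{where}: unknown relative position {c.relative_position!r}")
        if c.relationship is not None and c.relationship not in RELATIONSHIPS:
            raise VocabularyError(f"{where}: unknown spatial relationship {c.relationship!r}")
        if c.stroke is not None:
            qw = c.stroke.get("qualitative_width")
            if qw is not None and qw not in STROKE_WIDTH_CATEGORIES:
                raise VocabularyError(f"{where}: unknown stroke width category {qw!r}")
        return replace(c, shape_kind=kind)
    if c.role == "relation-assertion":
        if not (c.subject and c.predicate and c.object):
            raise ValidationError(f"{where}: relation-assertion needs subject, predicate, object")
        pred = _PREDICATE_ALIASES.get(c.predicate, c.predicate)
        if pred not in PREDICATES:
            raise VocabularyError(f"{where}: unknown predicate {c.predicate!r}; vocabulary: {PAIR_PREDICATES}")
        return replace(c, predicate=pred)
    if c.role == "subpattern-reference":
        if not c.pattern_ref:
            raise ValidationError(f"{where}: subpattern-reference needs pattern_ref")
        return c
    if c.role == "spatial-pattern":
        if c.value not in SPATIAL_PATTERNS:
            raise VocabularyError(f"{where}: unknown spatial pattern {c.value!r}")
        return c
    if c.role == "body-position":
        if c.value not in BODY_POSITIONS:
            raise VocabularyError(f"{where}: unknown body position {c.value!r}")
        return c
    if c.role == "annotation":
        if not c.text:
            raise ValidationError(f"{where}: annotation clause needs text")
        return c
    raise VocabularyError(f"{where}: unknown clause role {c.role!r}")


def register_pattern(d: PatternDefinition, catalog: Catalog) -> Catalog:
    """Register a definition in the catalog (in place; also returned).

    The term and its alternative labels must be new (after case folding)
    and the group, if named, must already be registered.
    """
    labels = [d.term, *d.alt_labels]
    for label in labels:
        key = label.strip().casefold()
        if key in catalog._labels:
            raise ValidationError(
                f"term/label {label!r} already registered (for {catalog._labels[key]!r})"
            )
    if d.group is not None and d.group not in catalog:
        raise ValidationError(f"{d.term!r}: group {d.group!r} is not a registered pattern")
    validated = tuple(_validate_clause(c, d.term) for c in d.clauses)
    d = replace(d, clauses=validated)
    catalog.definitions[d.term] = d
    for label in labels:
        catalog._labels[label.strip().casefold()] = d.term
    return catalog


def decompose(term: str, catalog: Catalog) -> list[ElementClause]:
    """The full clause set for a term, with sub-pattern references spliced
    in recursively (cycle-safe).  References explicitly marked
    ``expand: false`` are kept as reference clauses.
    """
    canonical = catalog.resolve(term)

    def walk(name: str, seen: frozenset[str]) -> list[ElementClause]:
        d = catalog.definitions[name]
        out: list[ElementClause] = []
        for c in d.clauses:
            if c.role == "subpattern-reference" and c.expand:
                ref = catalog.resolve(c.pattern_ref)
                if ref in seen:
                    continue  # cycle guard; registration should prevent this
                out.extend(walk(ref, seen | {name}))
            else:
                out.append(c)
        return out

    return walk(canonical, frozenset())


def groups(catalog: Catalog) -> dict[str, list[str]]:
    """Mapping of higher-level group name to its member terms (derived from
    each definition's ``group`` field; members in registration order)."""
    out: dict[str, list[str]] = {}
    for term, d in catalog.definitions.items():
        if d.group is not None:
            out.setdefault(catalog.resolve(d.group), []).append(term)
    return out


def _categories_of(clauses: Iterable[ElementClause], d: PatternDefinition) -> set[str]:
    cats: set[str] = set()
    for c in clauses:
        if c.role == "shape-requirement":
            cats.add("shape")
            if c.color:
                cats.add("color")
            if c.size:
                cats.add("size")
            if c.texture:
                cats.add("texture")
            if c.relationship:
                cats.add("spatial relationship")
            if c.relative_position:
                cats.add("relative position")
        elif c.role == "relation-assertion":
            cats.add("spatial relationship")
        elif c.role == "spatial-pattern":
            cats.add("spatial relationship")
        elif c.role == "body-position":
            cats.add("body position")
    if d.body_position is not None:
        cats.add("body position")
    return cats


def audit_category_coverage(catalog: Catalog) -> dict[str, list[str]]:
    """Consistency audit: a category defined for one term should be a
    feature of every term.

    For each category (fixed order: shape, color, size, texture, spatial
    relationship, relative position, body position) used by at least one
    definition, list the terms lacking it.  The report is empty iff
    coverage is complete.  Sub-pattern references are expanded first so a
    composite term is credited with its parts' features.
    """
    per_term = {
        term: _categories_of(decompose(term, catalog), d)
        for term, d in catalog.definitions.items()
    }
    used = set().union(*per_term.values()) if per_term else set()
    report: dict[str, list[str]] = {}
    for cat in AUDIT_CATEGORIES:
        if cat not in used:
            continue
        missing = sorted(t for t, cats in per_term.items() if cat not in cats)
        if missing:
            report[cat] = missing
    return report


def validate_catalog(catalog: Catalog) -> list[str]:
    """Cross-reference check over a fully loaded catalog.

    Returns a list of problems (empty when the catalog is clean):
    dangling sub-pattern references, relation assertions whose subject or
    object names no shape clause or sub-pattern of the same definition.
    """
    problems: list[str] = []
    for term, d in catalog.definitions.items():
        shape_kinds = {c.shape_kind for c in d.clauses if c.role == "shape-requirement"}
        refs = set()
        for c in d.clauses:
            if c.role == "subpattern-reference":
                try:
                    refs.add(catalog.resolve(c.pattern_ref))
                except UnknownTermError:
                    problems.append(f"{term}: dangling sub-pattern reference {c.pattern_ref!r}")
        for c in d.clauses:
            if c.role != "relation-assertion":
                continue
            for end, label in ((c.subject, "subject"), (c.object, "object")):
                if end not in shape_kinds and end not in refs and end not in catalog:
                    problems.append(f"{term}: relation {label} {end!r} matches no clause")
    return problems


# ---------------------------------------------------------------------------
# YAML catalog files


class _LineLoader(yaml.SafeLoader):
    """SafeLoader that records the source line of every mapping."""

    def construct_mapping(self, node, deep=False):
        mapping = super().construct_mapping(node, deep=deep)
        mapping["__line__"] = node.start_mark.line + 1
        return mapping


_DOC_KEYS = {"term", "alt_labels", "group", "clauses", "body_position", "annotations"}
_CLAUSE_KEYS = {
    "role", "shape_kind", "color", "size", "texture", "stroke", "relative_position",
    "relationship", "pattern_ref", "expand", "subject", "predicate", "object", "value", "text",
}


def _clause_from_dict(raw: dict, term: str, line: int) -> ElementClause:
    extra = set(raw) - _CLAUSE_KEYS - {"__line__"}
    if extra:
        raise ValidationError(f"line {raw.get('__line__', line)}: {term!r}: unknown clause keys {sorted(extra)}")
    kw = {k: v for k, v in raw.items() if k != "__line__"}
    color = kw.get("color")
    if isinstance(color, str):
        kw["color"] = (color,)
    elif color is not None:
        kw["color"] = tuple(color)
    try:
        return ElementClause(**kw)
    except (TypeError, ValidationError) as e:
        raise ValidationError(f"line {raw.get('__line__', line)}: {term!r}: {e}") from e


def definition_from_dict(raw: dict) -> PatternDefinition:
    line = raw.get("__line__", 0)
    extra = set(raw) - _DOC_KEYS - {"__line__"}
    if extra:
        raise ValidationError(f"line {line}: unknown keys {sorted(extra)}")
    term = raw.get("term")
    if not term:
        raise ValidationError(f"line {line}: catalog document needs a 'term'")
    clauses_raw = raw.get("clauses") or []
    clauses = tuple(_clause_from_dict(c, term, line) for c in clauses_raw)
    alt = raw.get("alt_labels") or []
    annotations = raw.get("annotations") or []
    try:
        return PatternDefinition(
            term=term,
            clauses=clauses,
            alt_labels=tuple(alt),
            group=raw.get("group"),
            body_position=raw.get("body_position"),
            annotations=tuple(annotations),
        )
    except (ValidationError, VocabularyError) as e:
        raise ValidationError(f"line {line}: {e}") from e


def load_catalog(source: Union[str, Path, None] = None, *, into: Optional[Catalog] = None) -> Catalog:
    """Load a YAML catalog file into a (new or existing) catalog.

    With ``source=None`` the shipped built-in catalog is loaded.
    Documents are registered in file order, so groups must precede their
    members.  Validation errors carry the YAML line of the offending
    document.
    """
    if source is None:
        text = resources.files("vizonto").joinpath("data/catalog.yaml").read_text()
    else:
        text = Path(source).read_text()
    data = yaml.load(text, Loader=_LineLoader)
    if data is None:
        data = []
    if not isinstance(data, list):
        raise ValidationError("a catalog file must contain a YAML list of term documents")
    catalog = into if into is not None else Catalog()
    for raw in data:
        d = definition_from_dict(raw)
        try:
            register_pattern(d, catalog)
        except (ValidationError, VocabularyError) as e:
            raise ValidationError(f"line {raw.get('__line__', 0)}: {e}") from e
    return catalog


def shipped_catalog() -> Catalog:
    """The built-in pattern catalog."""
    return load_catalog(None)
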