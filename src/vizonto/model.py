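"""Typed domain model for visual elements and their composition.

The model follows a two-layer architecture: a *base* layer covering the
generic vocabulary for describing visualizations (shapes, colors, strokes,
textures, points, sizes, spatial patterns) and a *dermoscopy* layer that
extends it with vocabulary specific to dermoscopic pattern description
(shiny texture, uniform/variable stroke widths, relative position on the
lesion, body position, extra colors and spatial patterns).  Every
constructor takes a ``mode`` argument; ``"base"`` mode rejects values that
exist only in the dermoscopy extension, ``"dermoscopy"`` (the default)
accepts the full vocabulary.

Conventions
-----------
* A *visualization* is a non-empty ordered composite of visual elements.
* A *pattern* is a composite of shapes and/or sub-patterns, optionally
  carrying an overall spatial arrangement and pairwise relationship
  assertions; the sub-pattern graph must be acyclic.
* A *dot* is not its own shape kind: it is a small circle.  Likewise
  *clod* and *globule* resolve to circles and *ellipse* to an elongated
  circle (the circle concept is deliberately loose: a rounded shape that
  need not have uniform radius).  :func:`resolve_shape_alias` performs
  this resolution and the aliases are kept as alternative labels.
* Coordinates, where present, are dimensionless 2-D pairs with x growing
  rightward and y downward (the SVG convention).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import networkx as nx

from .errors import CardinalityError, CycleError, ValidationError, VocabularyError

MODES = ("base", "dermoscopy")

#: The element kinds of the model.  RelativePosition and BodyPosition exist
#: only in the dermoscopy layer.
ELEMENT_KINDS = (
    "Shape",
    "Texture",
    "Color",
    "Pattern",
    "SpatialPattern",
    "Stroke",
    "Point",
    "SpatialRelationship",
    "Size",
    "Path",
    "RelativePosition",
    "BodyPosition",
)
DERMOSCOPY_ONLY_KINDS = frozenset({"RelativePosition", "BodyPosition"})

SHAPE_KINDS = (
    "Circle",
    "Ellipse",
    "Line",
    "Polygon",
    "Polyline",
    "Rectangle",
    "Path",
    "Structureless",
)

#: Named polygon subkinds with their exact point (vertex) cardinality.
#: The cardinality is *exact*, not a maximum: a decagon has exactly 10
#: points, a triangle exactly 3.
POLYGON_CARDINALITY = {
    "Triangle": 3,
    "Quadrilateral": 4,
    "Pentagon": 5,
    "Hexagon": 6,
    "Heptagon": 7,
    "Octagon": 8,
    "Nonagon": 9,
    "Decagon": 10,
}

LINE_STYLES = ("Straight", "Sharp", "Curved", "Serpiginous", "Wavy", "Dotted", "Double")

TEXTURES = ("Smooth", "Rough", "Shiny")
DERMOSCOPY_ONLY_TEXTURES = frozenset({"Shiny"})

SIZES = ("Small", "Large", "Long", "Uniform", "Variable")
#: Uniform/Variable qualify a collection of elements, not a single one.
COLLECTION_SIZES = frozenset({"Uniform", "Variable"})

STROKE_WIDTH_CATEGORIES = ("Thin", "Medium", "Thick", "Uniform", "Variable")
DERMOSCOPY_ONLY_WIDTHS = frozenset({"Uniform", "Variable"})

POINT_ROLES = ("Beginning", "Middle", "Ending", "Unspecified")

#: Generic arrangements available in the base layer plus the dermoscopy
#: extensions (polygon/square formations arise when shapes taken together
#: outline a larger shape-like structure; leaflike covers foliate outlines).
BASE_SPATIAL_PATTERNS = ("LinearArrangement", "RadialArrangement", "GridArrangement", "ScatteredArrangement")
DERMOSCOPY_SPATIAL_PATTERNS = ("PolygonFormation", "SquareFormation", "LeaflikePattern")
SPATIAL_PATTERNS = BASE_SPATIAL_PATTERNS + DERMOSCOPY_SPATIAL_PATTERNS

#: Aliases from the descriptive basic-element vocabulary, resolved to
#: circle-based shapes: a dot is a small circle, a clod/globule is a circle,
#: an ellipse is an elongated circle.
SHAPE_ALIASES = {
    "dot": ("Circle", "Small"),
    "clod": ("Circle", None),
    "globule": ("Circle", None),
    "ellipse": ("Circle", "Long"),
}

_HEX_RE = re.compile(r"^#[0-9A-Fa-f]{6}$")


def _check_mode(mode: str) -> str:
    if mode not in MODES:
        raise VocabularyError(f"unknown mode {mode!r}; expected one of {MODES}")
    return mode


@dataclass(frozen=True)
class Color:
    """A named color with RGB and hex encodings.

    ``symbolic`` colors (Pigmented, Hypopigmented, Dark, ...) name a
    perceptual category relative to the surrounding skin rather than an
    absolute value and carry no RGB data.  ``qualifier`` marks the
    collection-level pseudo-colors Uniform/Variable.
    """

    name: str
    rgb: Optional[tuple[int, int, int]] = None
    hex: Optional[str] = None
    symbolic: bool = False
    qualifier: bool = False
    # mutable backlink registry: MultiColor instances this color composes
    _multicolors: list = field(default_factory=list, compare=False, repr=False, hash=False)

    @property
    def kind(self) -> str:
        return "Color"

    def composed_of(self) -> tuple["MultiColor", ...]:
        """Multi-colors this color is a component of (inverse navigation)."""
        return tuple(self._multicolors)


@dataclass(frozen=True)
class MultiColor:
    """A mix of two or more distinct colors."""

    components: tuple[Color, ...]

    @property
    def kind(self) -> str:
        return "Color"

    @property
    def name(self) -> str:
        return " ".join(c.name for c in self.components)


@dataclass(frozen=True)
class Texture:
    value: str

    @property
    def kind(self) -> str:
        return "Texture"


@dataclass(frozen=True)
class Size:
    value: str

    @property
    def kind(self) -> str:
        return "Size"


@dataclass(frozen=True)
class Stroke:
    """Outline of a shape: relative integer width, qualitative width
    category, and an outline color."""

    width: Optional[int] = None
    qualitative_width: Optional[str] = None
    stroke_color: Optional[Union[Color, MultiColor]] = None

    @property
    def kind(self) -> str:
        return "Stroke"


@dataclass(frozen=True)
class Point:
    role: str = "Unspecified"
    coordinates: Optional[tuple[float, float]] = None

    @property
    def kind(self) -> str:
        return "Point"


@dataclass(frozen=True)
class SpatialPattern:
    value: str

    @property
    def kind(self) -> str:
        return "SpatialPattern"


@dataclass(frozen=True)
class Shape:
    """A visual primitive carrying fill, stroke, texture, size and points."""

    shape_kind: str
    fill: Optional[Union[Color, MultiColor]] = None
    stroke: Optional[Stroke] = None
    texture: Optional[Texture] = None
    size: Optional[Size] = None
    points: tuple[Point, ...] = ()
    line_style: Optional[str] = None
    polygon_sides: Optional[int] = None

    @property
    def kind(self) -> str:
        return "Shape"


@dataclass(frozen=True)
class RelationAssertion:
    """A pairwise relationship assertion inside a pattern: subject element,
    predicate label, object element (indices into the pattern's composite)."""

    subject: str
    predicate: str
    object: str


@dataclass(frozen=True)
class Pattern:
    name: str
    shapes: tuple[Shape, ...] = ()
    subpatterns: tuple["Pattern", ...] = ()
    spatial_pattern: Optional[SpatialPattern] = None
    relations: tuple[RelationAssertion, ...] = ()

    @property
    def kind(self) -> str:
        return "Pattern"


@dataclass(frozen=True)
class Visualization:
    """A non-empty ordered composite of visual elements."""

    elements: tuple = ()

    def __post_init__(self):
        if len(self.elements) < 1:
            raise ValidationError("a visualization must contain at least one element")


# ---------------------------------------------------------------------------
# constructors


def make_color(
    name: str,
    rgb: Optional[Sequence[int]] = None,
    hex: Optional[str] = None,
    *,
    symbolic: bool = False,
    qualifier: bool = False,
) -> Color:
    """Build a validated :class:`Color`.

    The hex and RGB encodings must agree; symbolic colors carry neither.

    >>> make_color("Black", (0, 0, 0), "#000000").hex
    '#000000'
    """
    if symbolic or qualifier:
        if rgb is not None or hex is not None:
            raise ValidationError(f"symbolic color {name!r} must not carry rgb/hex data")
        return Color(name=name, symbolic=symbolic or qualifier, qualifier=qualifier)
    if rgb is None or hex is None:
        raise ValidationError(f"color {name!r}: both rgb and hex are required (or mark it symbolic)")
    rgb = tuple(int(v) for v in rgb)
    if len(rgb) != 3 or any(not (0 <= v <= 255) for v in rgb):
        raise ValidationError(f"color {name!r}: rgb components must be three integers in [0, 255], got {rgb}")
    if not _HEX_RE.match(hex):
        raise ValidationError(f"color {name!r}: hex must match '#RRGGBB', got {hex!r}")
    decoded = tuple(int(hex[i : i + 2], 16) for i in (1, 3, 5))
    if decoded != rgb:
        raise ValidationError(
            f"color {name!r}: hex {hex!r} decodes to rgb {decoded} but rgb given as {rgb}"
        )
    return Color(name=name, rgb=rgb, hex=hex.upper() if hex[1:].islower() else hex)


def make_multicolor(components: Iterable[Color]) -> MultiColor:
    """Build a :class:`MultiColor` from >= 2 distinct component colors.

    Components are de-duplicated by name; the inverse navigation
    (``Color.composed_of``) is updated to list the new multi-color.
    """
    seen: dict[str, Color] = {}
    for c in components:
        if not isinstance(c, Color):
            raise ValidationError(f"multi-color components must be Color, got {type(c).__name__}")
        seen.setdefault(c.name, c)
    distinct = tuple(seen.values())
    if len(distinct) < 2:
        raise ValidationError(
            f"a multi-color needs at least 2 distinct component colors, got {len(distinct)}"
        )
    mc = MultiColor(components=distinct)
    for c in distinct:
        c._multicolors.append(mc)
    return mc


def make_texture(value: str, mode: str = "dermoscopy") -> Texture:
    _check_mode(mode)
    if value not in TEXTURES:
        raise VocabularyError(f"unknown texture {value!r}; expected one of {TEXTURES}")
    if mode == "base" and value in DERMOSCOPY_ONLY_TEXTURES:
        raise VocabularyError(f"texture {value!r} exists only in dermoscopy mode")
    return Texture(value)


def make_size(value: str) -> Size:
    if value not in SIZES:
        raise VocabularyError(f"unknown size {value!r}; expected one of {SIZES}")
    return Size(value)


def make_stroke(
    width: Optional[int] = None,
    qualitative_width: Optional[str] = None,
    stroke_color: Optional[Union[Color, MultiColor]] = None,
    mode: str = "dermoscopy",
) -> Stroke:
    _check_mode(mode)
    if width is not None:
        if int(width) < 1:
            raise ValidationError(f"stroke width must be >= 1, got {width}")
        width = int(width)
    if qualitative_width is not None:
        if qualitative_width not in STROKE_WIDTH_CATEGORIES:
            raise VocabularyError(
                f"unknown stroke width category {qualitative_width!r}; "
                f"expected one of {STROKE_WIDTH_CATEGORIES}"
            )
        if mode == "base" and qualitative_width in DERMOSCOPY_ONLY_WIDTHS:
            raise VocabularyError(f"width category {qualitative_width!r} exists only in dermoscopy mode")
    return Stroke(width=width, qualitative_width=qualitative_width, stroke_color=stroke_color)


def make_point(role: str = "Unspecified", coordinates: Optional[Sequence[float]] = None) -> Point:
    if role not in POINT_ROLES:
        raise VocabularyError(f"unknown point role {role!r}; expected one of {POINT_ROLES}")
    if coordinates is not None:
        coordinates = (float(coordinates[0]), float(coordinates[1]))
    return Point(role=role, coordinates=coordinates)


def make_spatial_pattern(value: str, mode: str = "dermoscopy") -> SpatialPattern:
    _check_mode(mode)
    if value not in SPATIAL_PATTERNS:
        raise VocabularyError(f"unknown spatial pattern {value!r}; expected one of {SPATIAL_PATTERNS}")
    if mode == "base" and value in DERMOSCOPY_SPATIAL_PATTERNS:
        raise VocabularyError(f"spatial pattern {value!r} exists only in dermoscopy mode")
    return SpatialPattern(value)


def point_cardinality(shape_kind: str) -> int:
    """Exact vertex count required for a named polygon subkind.

    >>> point_cardinality("Triangle")
    3
    >>> point_cardinality("Decagon")
    10
    """
    try:
        return POLYGON_CARDINALITY[shape_kind]
    except KeyError:
        raise VocabularyError(
            f"{shape_kind!r} has no point cardinality; named polygons are "
            + ", ".join(POLYGON_CARDINALITY)
        ) from None


def resolve_shape_alias(label: str) -> tuple[str, Optional[str]]:
    """Resolve a descriptive-terminology alias to (shape_kind, implied size).

    >>> resolve_shape_alias("dot")
    ('Circle', 'Small')
    """
    try:
        return SHAPE_ALIASES[label.lower()]
    except KeyError:
        raise VocabularyError(
            f"{label!r} is not a known shape alias; known aliases: " + ", ".join(SHAPE_ALIASES)
        ) from None


def make_shape(
    shape_kind: str,
    *,
    fill: Optional[Union[Color, MultiColor]] = None,
    stroke: Optional[Stroke] = None,
    texture: Optional[Texture] = None,
    size: Optional[Size] = None,
    points: Sequence[Point] = (),
    line_style: Optional[str] = None,
    polygon_sides: Optional[int] = None,
    mode: str = "dermoscopy",
) -> Shape:
    """Build a validated :class:`Shape`.

    * a named polygon subkind (Triangle .. Decagon) must carry exactly its
      defining number of points, when points are given;
    * line styles apply to lines only and default to Straight;
    * Structureless carries no point-structure constraint.
    """
    _check_mode(mode)
    alias = SHAPE_ALIASES.get(shape_kind.lower()) if shape_kind not in SHAPE_KINDS else None
    if alias is not None:
        shape_kind, implied_size = alias
        if size is None and implied_size is not None:
            size = make_size(implied_size)
    named_polygon = shape_kind in POLYGON_CARDINALITY
    if shape_kind not in SHAPE_KINDS and not named_polygon:
        raise VocabularyError(
            f"unknown shape kind {shape_kind!r}; expected one of "
            f"{SHAPE_KINDS + tuple(POLYGON_CARDINALITY)}"
        )
    points = tuple(points)
    if named_polygon:
        required = POLYGON_CARDINALITY[shape_kind]
        if points and len(points) != required:
            raise CardinalityError(
                f"a {shape_kind.lower()} has exactly {required} points, got {len(points)}"
            )
        if polygon_sides is not None and polygon_sides != required:
            raise CardinalityError(
                f"a {shape_kind.lower()} has exactly {required} sides, got {polygon_sides}"
            )
        polygon_sides = required
    if polygon_sides is not None and polygon_sides < 3:
        raise ValidationError(f"polygon_sides must be >= 3, got {polygon_sides}")
    if line_style is not None:
        if shape_kind != "Line":
            raise ValidationError(f"line_style applies to Line shapes only, not {shape_kind}")
        if line_style not in LINE_STYLES:
            raise VocabularyError(f"unknown line style {line_style!r}; expected one of {LINE_STYLES}")
    if shape_kind == "Line" and line_style is None:
        line_style = "Straight"  # an unqualified line is straight
    if size is not None and size.value == "Long" and shape_kind not in ("Circle", "Ellipse", "Line"):
        raise ValidationError(f"size Long needs an elongation axis; {shape_kind} has none")
    if texture is not None and mode == "base" and texture.value in DERMOSCOPY_ONLY_TEXTURES:
        raise VocabularyError(f"texture {texture.value!r} exists only in dermoscopy mode")
    return Shape(
        shape_kind=shape_kind,
        fill=fill,
        stroke=stroke,
        texture=texture,
        size=size,
        points=points,
        line_style=line_style,
        polygon_sides=polygon_sides,
    )


def _subpattern_graph(p: Pattern, g: nx.DiGraph) -> None:
    for sub in p.subpatterns:
        g.add_edge(p.name, sub.name)
        _subpattern_graph(sub, g)


def make_pattern(
    name: str,
    shapes: Sequence[Shape] = (),
    subpatterns: Sequence[Pattern] = (),
    spatial_pattern: Optional[SpatialPattern] = None,
    relations: Sequence[RelationAssertion] = (),
    predicate_vocabulary: Optional[Iterable[str]] = None,
) -> Pattern:
    """Build a validated :class:`Pattern` (a composite of shapes and/or
    sub-patterns).  The sub-pattern graph must be acyclic; a pattern may
    contain any number of sub-patterns.
    """
    shapes = tuple(shapes)
    subpatterns = tuple(subpatterns)
    if not shapes and not subpatterns:
        raise ValidationError(f"pattern {name!r} is an empty composite: it needs shapes or subpatterns")
    if predicate_vocabulary is not None:
        vocab = set(predicate_vocabulary)
        for r in relations:
            if r.predicate not in vocab:
                raise VocabularyError(
                    f"pattern {name!r}: relation predicate {r.predicate!r} not in vocabulary "
                    + str(sorted(vocab))
                )
    p = Pattern(
        name=name,
        shapes=shapes,
        subpatterns=subpatterns,
        spatial_pattern=spatial_pattern,
        relations=tuple(relations),
    )
    g = nx.DiGraph()
    g.add_node(name)
    _subpattern_graph(p, g)
    try:
        cyc = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        return p
    raise CycleError([e[0] for e in cyc] + [cyc[-1][1]])


def elements_of(v: Visualization) -> list:
    """Deterministically enumerate all elements of a visualization,
    recursing through patterns (each pattern is listed before its parts)."""
    out: list = []

    def walk(e) -> None:
        out.append(e)
        if isinstance(e, Pattern):
            for s in e.shapes:
                walk(s)
            for sp in e.subpatterns:
                walk(sp)

    for e in v.elements:
        walk(e)
    return out
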