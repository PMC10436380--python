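"""Synthetic geometric scenes instantiating pattern definitions.

The generator maps a catalog term's (expanded) clauses to concrete
geometry on the unit canvas so that spatial predicates, query answers
and SVG round trips are all testable without any external data.  The
placement conventions are toolkit choices:

* canvas = unit square, origin top-left, y downward (SVG convention);
* *Periphery* = centroid further than 0.35 from the canvas center,
  *Center* = closer than 0.15;
* circle radii by size: Small 0.03, Large 0.12, otherwise 0.06;
* a ``Circle spatialMeet Line`` assertion is realized by radial spokes
  whose outer ends stop half an eps-band short of a peripheral circle,
  which keeps the meet robust under the eps-tolerant boundary test;
* a ``Line spatialSurround Circle`` assertion is realized as a square
  frame of four segments around each circle;
* a SquareFormation spatial pattern places circle centers on a rotated
  square.

Structureless areas have no geometric realization and are rejected.
All randomness flows through a named, seedable generator: identical
(term, seed) pairs produce byte-identical SVG.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .catalog import Catalog, ElementClause, decompose, shipped_catalog
from .errors import NotRealizableError, ValidationError, VocabularyError
from .geometry import (
    CircleGeom,
    Geometry,
    PREDICATES,
    PolygonGeom,
    SegmentGeom,
    SpatialConfig,
    spatial_predicate,
)
from .palette import default_palette
from .svg import emit_svg

CANVAS_CENTER = (0.5, 0.5)
PERIPHERY_MIN = 0.35
CENTER_MAX = 0.15

_SIZE_RADIUS = {"Small": 0.03, "Large": 0.12}
_DEFAULT_RADIUS = 0.06

#: representative hex fills for the skin-relative symbolic colors
_SYMBOLIC_FILL = {
    "Pigmented": "#5B3A29",
    "Hypopigmented": "#F2E3DA",
    "Non-pigmented": "#FFFFFF",
    "Dark": "#1A1A1A",
    "Uniform": "#888888",
    "Variable": "#888888",
}


@dataclass(frozen=True)
class Scene:
    """A concrete geometric instantiation of a pattern (or ad-hoc set)."""

    geometries: dict[str, Geometry]
    styles: dict[str, dict[str, str]] = field(default_factory=dict)
    seed: int = 0
    provenance: str = "adhoc"

    def to_svg(self) -> str:
        return emit_svg(self.geometries, self.styles)


def _rng(term: str, seed: int) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(term.encode()) % (2**31)])


def _fill_for(colors: tuple[str, ...]) -> str:
    palette = default_palette()
    for name in colors:
        c = palette.get(name)
        if c is not None and c.hex:
            return c.hex
        if name in _SYMBOLIC_FILL:
            return _SYMBOLIC_FILL[name]
    return "#808080"


def _radius_for(clause: ElementClause) -> float:
    return _SIZE_RADIUS.get(clause.size or "", _DEFAULT_RADIUS)


def _clamp(v: float, lo: float = 0.02, hi: float = 0.98) -> float:
    return float(min(hi, max(lo, v)))


class _Builder:
    def __init__(self, rng: np.random.Generator, eps: float):
        self.rng = rng
        self.eps = eps
        self.geometries: dict[str, Geometry] = {}
        self.styles: dict[str, dict[str, str]] = {}
        self.counter: dict[str, int] = {}

    def add(self, prefix: str, g: Geometry, style: dict[str, str]) -> str:
        n = self.counter.get(prefix, 0) + 1
        self.counter[prefix] = n
        gid = f"{prefix}{n}"
        self.geometries[gid] = g
        self.styles[gid] = style
        return gid

    # -- construction idioms -------------------------------------------------
    def spokes_with_tip_circles(self, n: int, line_fill: str, circle_fill: str,
                                circle_r: float) -> None:
        """Radial lines whose outer ends meet peripheral circles."""
        base = self.rng.uniform(0, 2 * np.pi)
        outer = 0.36
        for k in range(n):
            ang = base + 2 * np.pi * k / n + self.rng.uniform(-0.1, 0.1)
            ux, uy = np.cos(ang), np.sin(ang)
            start = (CANVAS_CENTER[0] + 0.18 * ux, CANVAS_CENTER[1] + 0.18 * uy)
            end = (CANVAS_CENTER[0] + outer * ux, CANVAS_CENTER[1] + outer * uy)
            self.add("line", SegmentGeom(start, end), {"stroke": line_fill})
            # tip circle: gap of eps/2 beyond the line end keeps the meet
            # inside the boundary band but clear of the interiors
            d = outer + self.eps / 2 + circle_r
            center = (CANVAS_CENTER[0] + d * ux, CANVAS_CENTER[1] + d * uy)
            self.add("circle", CircleGeom(center, circle_r), {"fill": circle_fill})

    def radial_lines(self, n: int, fill: str) -> None:
        base = self.rng.uniform(0, 2 * np.pi)
        for k in range(n):
            ang = base + 2 * np.pi * k / n + self.rng.uniform(-0.12, 0.12)
            ux, uy = np.cos(ang), np.sin(ang)
            start = (CANVAS_CENTER[0] + 0.16 * ux, CANVAS_CENTER[1] + 0.16 * uy)
            end = (CANVAS_CENTER[0] + 0.42 * ux, CANVAS_CENTER[1] + 0.42 * uy)
            self.add("line", SegmentGeom(start, end), {"stroke": fill})

    def parallel_lines(self, n: int, fill: str, angle: Optional[float] = None) -> None:
        ang = self.rng.uniform(0, np.pi) if angle is None else angle
        ux, uy = np.cos(ang), np.sin(ang)
        nx, ny = -uy, ux
        for k in range(n):
            off = -0.3 + 0.6 * k / max(n - 1, 1)
            cx = CANVAS_CENTER[0] + off * nx
            cy = CANVAS_CENTER[1] + off * ny
            self.add(
                "line",
                SegmentGeom(
                    (_clamp(cx - 0.3 * ux), _clamp(cy - 0.3 * uy)),
                    (_clamp(cx + 0.3 * ux), _clamp(cy + 0.3 * uy)),
                ),
                {"stroke": fill},
            )

    def grid_lines(self, n: int, fill: str) -> None:
        for k in range(n):
            off = 0.2 + 0.6 * k / max(n - 1, 1)
            self.add("line", SegmentGeom((off, 0.2), (off, 0.8)), {"stroke": fill})
            self.add("line", SegmentGeom((0.2, off), (0.8, off)), {"stroke": fill})

    def square_frame(self, center: tuple[float, float], half: float, fill: str) -> list[str]:
        x, y = center
        c = [(x - half, y - half), (x + half, y - half), (x + half, y + half), (x - half, y + half)]
        ids = []
        for i in range(4):
            ids.append(self.add("line", SegmentGeom(c[i], c[(i + 1) % 4]), {"stroke": fill}))
        return ids

    def scattered_circles(self, n: int, r: float, fill: str, placement: Optional[str]) -> None:
        for _ in range(n):
            if placement == "Periphery":
                ang = self.rng.uniform(0, 2 * np.pi)
                hi = max(0.5 - r - 0.02, PERIPHERY_MIN + 0.01)
                d = self.rng.uniform(PERIPHERY_MIN + 0.005, hi)
                cx = CANVAS_CENTER[0] + d * np.cos(ang)
                cy = CANVAS_CENTER[1] + d * np.sin(ang)
            elif placement == "Center":
                ang = self.rng.uniform(0, 2 * np.pi)
                d = self.rng.uniform(0, max(CENTER_MAX - r - 0.01, 0.01))
                cx = CANVAS_CENTER[0] + d * np.cos(ang)
                cy = CANVAS_CENTER[1] + d * np.sin(ang)
            elif placement == "Clustered":
                cx = CANVAS_CENTER[0] + self.rng.uniform(-0.12, 0.12)
                cy = CANVAS_CENTER[1] + self.rng.uniform(-0.12, 0.12)
            else:
                cx = self.rng.uniform(0.15, 0.85)
                cy = self.rng.uniform(0.15, 0.85)
            self.add("circle", CircleGeom((_clamp(cx), _clamp(cy)), r), {"fill": fill})

    def square_formation_circles(self, r: float, fill: str) -> None:
        half = 0.1
        rot = self.rng.uniform(0, np.pi / 2)
        for sx, sy in ((-1, -1), (1, -1), (1, 1), (-1, 1)):
            x = sx * half * np.cos(rot) - sy * half * np.sin(rot)
            y = sx * half * np.sin(rot) + sy * half * np.cos(rot)
            self.add("circle", CircleGeom((CANVAS_CENTER[0] + x, CANVAS_CENTER[1] + y), r), {"fill": fill})

    def clustered_polygons(self, n: int, fill: str) -> None:
        r = 0.09
        for k in range(n):
            cx = CANVAS_CENTER[0] + 1.9 * r * (k - (n - 1) / 2)
            cy = CANVAS_CENTER[1] + self.rng.uniform(-0.02, 0.02)
            base = self.rng.uniform(0, np.pi / 3)
            verts = tuple(
                (cx + r * np.cos(base + i * np.pi / 3), cy + r * np.sin(base + i * np.pi / 3))
                for i in range(6)
            )
            self.add("polygon", PolygonGeom(verts), {"fill": fill})


def render_scene(
    term: str,
    seed: int,
    catalog: Optional[Catalog] = None,
    config: Optional[SpatialConfig] = None,
) -> tuple[Scene, str]:
    """Instantiate a registered term as a geometric scene plus its SVG.

    The construction honors the term's clauses (placement, relation
    assertions, spatial patterns); clause sets with no supported
    geometric realization (e.g. Structureless areas) raise
    :class:`NotRealizableError`.
    """
    catalog = catalog or shipped_catalog()
    config = config or SpatialConfig()
    canonical = catalog.resolve(term)
    clauses = decompose(canonical, catalog)
    shape_clauses = [c for c in clauses if c.role == "shape-requirement"]
    if not shape_clauses:
        raise NotRealizableError(f"{canonical!r} has no shape clauses to realize")
    if any(c.shape_kind == "Structureless" for c in shape_clauses):
        raise NotRealizableError(f"{canonical!r} contains a structureless area: no geometric realization")

    relations = [c for c in clauses if c.role == "relation-assertion"]
    spatial = next((c.value for c in clauses if c.role == "spatial-pattern"), None)
    rng = _rng(canonical, seed)
    b = _Builder(rng, config.effective_eps)

    circle_clauses = [c for c in shape_clauses if c.shape_kind in ("Circle", "Ellipse")]
    line_clauses = [c for c in shape_clauses if c.shape_kind == "Line"]
    poly_clauses = [c for c in shape_clauses if c.shape_kind in ("Polygon",) or c.shape_kind in
                    ("Triangle", "Quadrilateral", "Pentagon", "Hexagon", "Heptagon", "Octagon", "Nonagon", "Decagon")]

    has_meet = any(r.predicate == "spatialMeet" for r in relations)
    has_surround = any(r.predicate == "spatialSurround" for r in relations)

    handled_circles = False
    handled_lines = False
    if has_meet and circle_clauses and line_clauses:
        cc, lc = circle_clauses[0], line_clauses[0]
        b.spokes_with_tip_circles(5, _fill_for(lc.color), _fill_for(cc.color), _radius_for(cc))
        handled_circles = handled_lines = True
    elif has_surround and circle_clauses and line_clauses:
        cc, lc = circle_clauses[0], line_clauses[0]
        r = _radius_for(cc)
        for k in range(3):
            center = (0.28 + 0.22 * k, 0.5 + rng.uniform(-0.05, 0.05))
            b.add("circle", CircleGeom(center, r), {"fill": _fill_for(cc.color)})
            b.square_frame(center, r + 0.05, _fill_for(lc.color))
        handled_circles = handled_lines = True

    if not handled_circles:
        for cc in circle_clauses:
            r = _radius_for(cc)
            fill = _fill_for(cc.color)
            if spatial == "SquareFormation":
                b.square_formation_circles(r, fill)
            else:
                placement = cc.relative_position or (
                    "Clustered" if cc.relationship == "Clustered" else None
                )
                b.scattered_circles(5, r, fill, placement)
    if not handled_lines:
        for lc in line_clauses:
            fill = _fill_for(lc.color)
            if lc.relationship == "Radial":
                b.radial_lines(6, fill)
            elif lc.relationship == "Parallel":
                b.parallel_lines(5, fill)
            elif lc.relationship == "Orthogonal":
                b.parallel_lines(4, fill, angle=0.35)
                b.parallel_lines(4, fill, angle=0.35 + np.pi / 2)
            elif lc.relationship == "Interconnecting":
                b.grid_lines(4, fill)
            else:
                b.parallel_lines(3, fill)
    for pc in poly_clauses:
        b.clustered_polygons(3, _fill_for(pc.color))

    if not b.geometries:
        raise NotRealizableError(f"{canonical!r}: no clause mapped to a supported geometry")
    scene = Scene(geometries=b.geometries, styles=b.styles, seed=seed, provenance=canonical)
    return scene, scene.to_svg()


# ---------------------------------------------------------------------------
# single-relation pairs


def sample_relation_pair(relation: str, seed: int, config: Optional[SpatialConfig] = None):
    """A geometry pair (or (composite, geometry) for spatialSurround) for
    which the requested relation holds; verified before returning."""
    if relation not in PREDICATES:
        raise VocabularyError(f"unsupported relation {relation!r}; vocabulary: {PREDICATES}")
    config = config or SpatialConfig()
    eps = config.effective_eps
    rng = _rng(relation, seed)

    def circle(cx, cy, r):
        return CircleGeom((float(cx), float(cy)), float(r))

    if relation == "spatialDisjoint":
        r1, r2 = rng.uniform(0.05, 0.12, 2)
        a = circle(0.25, 0.5 + rng.uniform(-0.1, 0.1), r1)
        bgeom = circle(0.75, 0.5 + rng.uniform(-0.1, 0.1), r2)
    elif relation == "spatialMeet":
        r1, r2 = rng.uniform(0.08, 0.18, 2)
        ang = rng.uniform(0, 2 * np.pi)
        d = r1 + r2 + eps / 2  # inside the boundary band, clear of interiors
        a = circle(0.5, 0.5, r1)
        bgeom = circle(0.5 + d * np.cos(ang), 0.5 + d * np.sin(ang), r2)
    elif relation == "spatialEqual":
        r = rng.uniform(0.1, 0.3)
        c = (0.5 + rng.uniform(-0.05, 0.05), 0.5 + rng.uniform(-0.05, 0.05))
        a = CircleGeom(c, float(r))
        bgeom = CircleGeom(c, float(r))
    elif relation == "spatialOverlap":
        r1, r2 = rng.uniform(0.15, 0.25, 2)
        lo = abs(r1 - r2) + 4 * eps
        hi = r1 + r2 - 4 * eps
        d = rng.uniform(lo, hi) if lo < hi else (lo + hi) / 2
        ang = rng.uniform(0, 2 * np.pi)
        a = circle(0.5, 0.5, r1)
        bgeom = circle(0.5 + d * np.cos(ang), 0.5 + d * np.sin(ang), r2)
    elif relation in ("spatialInside", "spatialContains"):
        r_outer = rng.uniform(0.28, 0.36)
        r_inner = rng.uniform(0.08, r_outer - 5 * eps - 0.05)
        off = rng.uniform(0, r_outer - r_inner - 5 * eps)
        ang = rng.uniform(0, 2 * np.pi)
        inner = circle(0.5 + off * np.cos(ang), 0.5 + off * np.sin(ang), r_inner)
        outer = circle(0.5, 0.5, r_outer)
        a, bgeom = (inner, outer) if relation == "spatialInside" else (outer, inner)
    elif relation in ("spatialCoveredBy", "spatialCovers"):
        r_outer = rng.uniform(0.28, 0.36)
        r_inner = rng.uniform(0.1, r_outer - 0.08)
        ang = rng.uniform(0, 2 * np.pi)
        off = r_outer - r_inner  # internal tangency: boundaries share a point
        inner = circle(0.5 + off * np.cos(ang), 0.5 + off * np.sin(ang), r_inner)
        outer = circle(0.5, 0.5, r_outer)
        a, bgeom = (inner, outer) if relation == "spatialCoveredBy" else (outer, inner)
    else:  # spatialSurround: composite frame around a circle
        r = rng.uniform(0.08, 0.15)
        cx, cy = 0.5 + rng.uniform(-0.05, 0.05), 0.5 + rng.uniform(-0.05, 0.05)
        half = r + rng.uniform(0.04, 0.1)
        corners = [(cx - half, cy - half), (cx + half, cy - half), (cx + half, cy + half), (cx - half, cy + half)]
        a = tuple(SegmentGeom(corners[i], corners[(i + 1) % 4]) for i in range(4))
        bgeom = circle(cx, cy, r)

    if not spatial_predicate(relation, a, bgeom, config):
        raise ValidationError(
            f"internal error: generated pair fails {relation} (seed {seed})"
        )
    return a, bgeom
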