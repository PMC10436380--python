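"""Geometric realization of the spatial-relationship predicates.

Spatial relations between two planar objects are decided from four
boundary/interior intersection flags, a four-flag abstraction of the
Dimensionally Extended 9-Intersection Model (DE-9IM):

* ``bb`` — the boundaries of the two objects share points,
* ``ii`` — the interiors share points,
* ``bi`` — the boundary of A meets the interior of B,
* ``ib`` — the interior of A meets the boundary of B.

Boundaries are fattened to an ``eps``-band so that tangency and shared
edges are detectable on a finite grid: a query point counts as *boundary*
when it lies within ``eps`` of the object's topological boundary, as
*interior* when it is inside the object but outside the band, and as
*exterior* otherwise.  For curve objects (polylines, segments) the
topological boundary is the endpoint set and the interior is the rest of
the curve, both fattened by ``eps``; a closed polyline has an empty
boundary.

The normative evaluation is exhaustive grid sampling over the joint
bounding box (deterministic row-major traversal, no randomness).  An
analytic shortcut intersects the very same eps-band regions with exact
set operations; it must — and, on generically placed inputs, does — agree
with sampling, and is the default because it is much faster.

The predicate vocabulary maps onto the flags with a fixed truth table
(see ``TRUTH_TABLE``); converse pairs hold by construction:
``spatialInside(a, b) == spatialContains(b, a)`` and
``spatialCoveredBy(a, b) == spatialCovers(b, a)``.  A ``strict`` mode
delegating to textbook DE-9IM predicates is available for comparison.
``spatialSurround`` is not expressible in the four flags: A (possibly a
composite of several geometries) surrounds B when B lies inside the
convex hull of A's components while A and B share no interior.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import shapely
from shapely.geometry import LineString, Point as ShapelyPoint, Polygon
from shapely.ops import unary_union

from .errors import DegenerateGeometryError, ValidationError, VocabularyError

__all__ = [
    "CircleGeom",
    "PolygonGeom",
    "PolylineGeom",
    "SegmentGeom",
    "Geometry",
    "IntersectionState",
    "SpatialConfig",
    "PREDICATES",
    "TRUTH_TABLE",
    "intersection_state",
    "spatial_predicate",
    "classify",
    "classify_point",
    "geometry_to_shapely",
    "geometry_to_dict",
    "geometry_from_dict",
    "load_scene_json",
    "dump_scene_json",
]

#: Number of segments per quarter circle when discretizing circles.
_CIRCLE_QUAD_SEGS = 64


@dataclass(frozen=True)
class CircleGeom:
    center: tuple[float, float]
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValidationError(f"circle radius must be > 0, got {self.radius}")


@dataclass(frozen=True)
class PolygonGeom:
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if len(self.vertices) < 3:
            raise ValidationError("a polygon needs at least 3 vertices")
        if not Polygon(self.vertices).is_simple:
            raise ValidationError("polygon must be simple (non-self-intersecting)")


@dataclass(frozen=True)
class PolylineGeom:
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if len(self.vertices) < 2:
            raise ValidationError("a polyline needs at least 2 vertices")

    @property
    def closed(self) -> bool:
        return self.vertices[0] == self.vertices[-1]


@dataclass(frozen=True)
class SegmentGeom:
    start: tuple[float, float]
    end: tuple[float, float]

    def __post_init__(self):
        if self.start == self.end:
            raise ValidationError("segment endpoints must differ")


Geometry = Union[CircleGeom, PolygonGeom, PolylineGeom, SegmentGeom]


@dataclass(frozen=True)
class IntersectionState:
    """The four boundary/interior intersection flags for an ordered pair.

    Swapping the arguments maps ``bb <-> bb``, ``ii <-> ii`` and
    ``bi <-> ib``.
    """

    bb: bool
    ii: bool
    bi: bool
    ib: bool

    def swapped(self) -> "IntersectionState":
        return IntersectionState(bb=self.bb, ii=self.ii, bi=self.ib, ib=self.bi)

    def as_tuple(self) -> tuple[bool, bool, bool, bool]:
        return (self.bb, self.ii, self.bi, self.ib)


@dataclass(frozen=True)
class SpatialConfig:
    """Evaluation parameters.

    resolution
        Grid step, in scene units.  The sampling grid covers the joint
        bounding box expanded by ``2 * eps``.
    eps
        Half-width of the boundary band; defaults to ``2 * resolution``
        (tangency detection therefore depends on eps).
    method
        ``"analytic"`` (default) or ``"grid"`` — both evaluate the same
        eps-band regions; grid is the normative sampling oracle.
    strict
        Use textbook DE-9IM predicates instead of the four-flag truth
        table.
    """

    resolution: float = 0.01
    eps: Optional[float] = None
    method: str = "analytic"
    strict: bool = False

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValidationError(f"resolution must be > 0, got {self.resolution}")
        if self.eps is not None and self.eps <= 0:
            raise ValidationError(f"eps must be > 0, got {self.eps}")
        if self.method not in ("analytic", "grid"):
            raise ValidationError(f"unknown method {self.method!r}")

    @property
    def effective_eps(self) -> float:
        return self.eps if self.eps is not None else 2.0 * self.resolution


def geometry_to_shapely(g: Geometry):
    """Convert to a shapely geometry (circles become fine polygon buffers)."""
    if isinstance(g, CircleGeom):
        return ShapelyPoint(g.center).buffer(g.radius, quad_segs=_CIRCLE_QUAD_SEGS)
    if isinstance(g, PolygonGeom):
        return Polygon(g.vertices)
    if isinstance(g, PolylineGeom):
        return LineString(g.vertices)
    if isinstance(g, SegmentGeom):
        return LineString([g.start, g.end])
    raise ValidationError(f"unsupported geometry {type(g).__name__}")


def _is_areal(g: Geometry) -> bool:
    return isinstance(g, (CircleGeom, PolygonGeom))


def _regions(g: Geometry, eps: float):
    """(boundary_region, interior_region) as 2-D shapely sets.

    These regions define point classification for both the grid oracle and
    the analytic shortcut, so the two evaluation paths see the same sets.
    """
    sg = geometry_to_shapely(g)
    if _is_areal(g):
        boundary = sg.boundary.buffer(eps)
        interior = sg.difference(boundary)
        return boundary, interior
    # curve: boundary = endpoint disks; interior = the rest of the eps-tube
    if isinstance(g, PolylineGeom) and g.closed:
        endpoints = []
    elif isinstance(g, PolylineGeom):
        endpoints = [g.vertices[0], g.vertices[-1]]
    else:
        endpoints = [g.start, g.end]
    boundary = unary_union([ShapelyPoint(p).buffer(eps) for p in endpoints]) if endpoints else Polygon()
    interior = sg.buffer(eps).difference(boundary)
    return boundary, interior


def classify_point(g: Geometry, point: Sequence[float], eps: float) -> str:
    """Classify a query point as ``"interior"``, ``"boundary"`` (within
    eps) or ``"exterior"`` with respect to a geometry."""
    p = ShapelyPoint(point)
    boundary, interior = _regions(g, eps)
    if boundary.covers(p):
        return "boundary"
    if interior.covers(p):
        return "interior"
    return "exterior"


def _extent(g: Geometry) -> float:
    sg = geometry_to_shapely(g)
    minx, miny, maxx, maxy = sg.bounds
    return max(maxx - minx, maxy - miny)


def _check_degenerate(g: Geometry, resolution: float) -> None:
    if _extent(g) < 2.0 * resolution:
        raise DegenerateGeometryError(
            f"geometry extent {_extent(g):.4g} is below 2x resolution "
            f"({2 * resolution:.4g}); refine the resolution"
        )


def _grid_axes(a: Geometry, b: Geometry, resolution: float, eps: float):
    """Deterministic sampling axes over the joint bounding box expanded by
    ``2*eps`` — shared by the sampling oracle and the analytic shortcut so
    both refer to the same grid."""
    ga, gb = geometry_to_shapely(a), geometry_to_shapely(b)
    pad = 3 * eps  # band (eps) plus the mandated 2*eps expansion
    minx = min(ga.bounds[0], gb.bounds[0]) - pad
    miny = min(ga.bounds[1], gb.bounds[1]) - pad
    maxx = max(ga.bounds[2], gb.bounds[2]) + pad
    maxy = max(ga.bounds[3], gb.bounds[3]) + pad
    xs = np.arange(minx, maxx + resolution / 2, resolution)
    ys = np.arange(miny, maxy + resolution / 2, resolution)
    return xs, ys


def _grid_state(a: Geometry, b: Geometry, resolution: float, eps: float) -> IntersectionState:
    ba, ia = _regions(a, eps)
    bb_, ib_ = _regions(b, eps)
    xs, ys = _grid_axes(a, b, resolution, eps)
    gx, gy = np.meshgrid(xs, ys)  # row-major traversal
    gx = gx.ravel()
    gy = gy.ravel()
    mask_ba = shapely.contains_xy(ba, gx, gy)
    mask_bb = shapely.contains_xy(bb_, gx, gy)
    mask_ia = shapely.contains_xy(ia, gx, gy) & ~mask_ba
    mask_ib = shapely.contains_xy(ib_, gx, gy) & ~mask_bb
    return IntersectionState(
        bb=bool((mask_ba & mask_bb).any()),
        ii=bool((mask_ia & mask_ib).any()),
        bi=bool((mask_ba & mask_ib).any()),
        ib=bool((mask_ia & mask_bb).any()),
    )


def _analytic_state(a: Geometry, b: Geometry, resolution: float, eps: float) -> IntersectionState:
    """Exact-set evaluation of the same eps-band regions the grid samples.

    A flag is true when the region intersection would capture a grid
    point: intersections thick enough to contain a disk of radius
    ``resolution`` always do (the nearest grid point lies within
    ``resolution/sqrt(2)`` of any location); thin slivers are resolved by
    testing the actual grid points inside the sliver, so the shortcut
    agrees with sampling by construction.
    """
    ba, ia = _regions(a, eps)
    bb_, ib_ = _regions(b, eps)
    xs, ys = _grid_axes(a, b, resolution, eps)

    def hit(r1, r2) -> bool:
        if not r1.intersects(r2):
            return False
        inter = r1.intersection(r2)
        if inter.area == 0.0:
            return False  # shared curves only (e.g. identical geometries)
        if not inter.buffer(-resolution).is_empty:
            return True
        # borderline sliver: check the sampling grid points it covers
        bxmin, bymin, bxmax, bymax = inter.bounds
        sel_x = xs[(xs >= bxmin) & (xs <= bxmax)]
        sel_y = ys[(ys >= bymin) & (ys <= bymax)]
        if len(sel_x) == 0 or len(sel_y) == 0:
            return False
        gx, gy = np.meshgrid(sel_x, sel_y)
        return bool(shapely.contains_xy(inter, gx.ravel(), gy.ravel()).any())

    return IntersectionState(
        bb=hit(ba, bb_), ii=hit(ia, ib_), bi=hit(ba, ib_), ib=hit(ia, bb_)
    )


def intersection_state(
    a: Geometry,
    b: Geometry,
    resolution: float = 0.01,
    eps: Optional[float] = None,
    method: str = "analytic",
) -> IntersectionState:
    """Compute the four intersection flags for the ordered pair (a, b).

    ``method="grid"`` samples the joint bounding box exhaustively at the
    given resolution; ``"analytic"`` (default) intersects the same
    eps-band regions exactly.  Geometries smaller than twice the
    resolution are rejected as degenerate.
    """
    if resolution <= 0 or (eps is not None and eps <= 0):
        raise ValidationError("resolution and eps must be positive")
    eff_eps = eps if eps is not None else 2.0 * resolution
    _check_degenerate(a, resolution)
    _check_degenerate(b, resolution)
    if method == "grid":
        return _grid_state(a, b, resolution, eff_eps)
    if method == "analytic":
        return _analytic_state(a, b, resolution, eff_eps)
    raise ValidationError(f"unknown method {method!r}")


#: Predicate vocabulary, in fixed output order.
PREDICATES = (
    "spatialDisjoint",
    "spatialOverlap",
    "spatialMeet",
    "spatialEqual",
    "spatialInside",
    "spatialCoveredBy",
    "spatialCovers",
    "spatialContains",
    "spatialSurround",
)

#: flag truth table: predicate -> function of (bb, ii, bi, ib)
TRUTH_TABLE = {
    "spatialDisjoint": lambda bb, ii, bi, ib: not bb and not ii and not bi and not ib,
    "spatialOverlap": lambda bb, ii, bi, ib: bb and ii and bi and ib,
    "spatialMeet": lambda bb, ii, bi, ib: bb and not ii and not bi and not ib,
    "spatialEqual": lambda bb, ii, bi, ib: bb and ii and not bi and not ib,
    "spatialInside": lambda bb, ii, bi, ib: ii and bi and not bb,
    "spatialContains": lambda bb, ii, bi, ib: ii and ib and not bb,
    "spatialCoveredBy": lambda bb, ii, bi, ib: bb and ii and bi,
    "spatialCovers": lambda bb, ii, bi, ib: bb and ii and ib,
}


def _surround(a_components: Iterable[Geometry], b: Geometry, eps: float) -> bool:
    """A surrounds B: B lies inside the convex hull of A's components and
    A and B share no interior (toolkit definition)."""
    comps = [geometry_to_shapely(g) for g in a_components]
    if not comps:
        return False
    union_a = unary_union(comps)
    hull = union_a.convex_hull
    bg = geometry_to_shapely(b)
    if not hull.covers(bg):
        return False
    inter = union_a.intersection(bg)
    return inter.area <= eps * eps and not union_a.crosses(bg)


def _strict_predicate(name: str, a: Geometry, b: Geometry) -> bool:
    """Textbook DE-9IM predicates via shapely (no eps tolerance)."""
    ag, bg = geometry_to_shapely(a), geometry_to_shapely(b)
    if name == "spatialDisjoint":
        return ag.disjoint(bg)
    if name == "spatialMeet":
        return ag.touches(bg)
    if name == "spatialOverlap":
        return ag.overlaps(bg)
    if name == "spatialEqual":
        return ag.equals(bg)
    if name == "spatialCoveredBy":
        return ag.covered_by(bg)
    if name == "spatialCovers":
        return ag.covers(bg)
    if name == "spatialInside":
        return ag.covered_by(bg) and not ag.boundary.intersects(bg.boundary)
    if name == "spatialContains":
        return ag.covers(bg) and not ag.boundary.intersects(bg.boundary)
    raise VocabularyError(f"unknown predicate {name!r}; vocabulary: {PREDICATES}")


def spatial_predicate(
    name: str,
    a: Union[Geometry, Sequence[Geometry]],
    b: Geometry,
    config: Optional[SpatialConfig] = None,
) -> bool:
    """Evaluate one named spatial predicate on the ordered pair (a, b).

    ``spatialSurround`` accepts a composite first argument (a sequence of
    geometries); every other predicate requires single geometries.
    """
    config = config or SpatialConfig()
    if name not in PREDICATES:
        raise VocabularyError(f"unknown predicate {name!r}; vocabulary: {PREDICATES}")
    if name == "spatialSurround":
        comps = a if isinstance(a, (list, tuple)) else [a]
        return _surround(comps, b, config.effective_eps)
    if isinstance(a, (list, tuple)):
        raise ValidationError(f"{name} requires a single geometry as first argument")
    if config.strict:
        return _strict_predicate(name, a, b)
    st = intersection_state(a, b, config.resolution, config.eps, config.method)
    return TRUTH_TABLE[name](*st.as_tuple())


def classify(
    a: Union[Geometry, Sequence[Geometry]],
    b: Geometry,
    config: Optional[SpatialConfig] = None,
) -> list[str]:
    """All predicates that hold for (a, b), in fixed vocabulary order."""
    config = config or SpatialConfig()
    out = []
    composite = isinstance(a, (list, tuple))
    st = None
    if not composite and not config.strict:
        st = intersection_state(a, b, config.resolution, config.eps, config.method)
    for name in PREDICATES:
        if name == "spatialSurround":
            comps = a if composite else [a]
            if _surround(comps, b, config.effective_eps):
                out.append(name)
        elif composite:
            continue
        elif config.strict:
            if _strict_predicate(name, a, b):
                out.append(name)
        else:
            if TRUTH_TABLE[name](*st.as_tuple()):
                out.append(name)
    return out


# ---------------------------------------------------------------------------
# scene-file (JSON) interface

_GEOM_TAGS = {"circle": CircleGeom, "polygon": PolygonGeom, "polyline": PolylineGeom, "segment": SegmentGeom}


def geometry_to_dict(g: Geometry) -> dict:
    if isinstance(g, CircleGeom):
        return {"type": "circle", "center": list(g.center), "radius": g.radius}
    if isinstance(g, PolygonGeom):
        return {"type": "polygon", "vertices": [list(v) for v in g.vertices]}
    if isinstance(g, PolylineGeom):
        return {"type": "polyline", "vertices": [list(v) for v in g.vertices]}
    if isinstance(g, SegmentGeom):
        return {"type": "segment", "start": list(g.start), "end": list(g.end)}
    raise ValidationError(f"unsupported geometry {type(g).__name__}")


def geometry_from_dict(d: dict) -> Geometry:
    kind = d.get("type")
    if kind == "circle":
        return CircleGeom(center=tuple(d["center"]), radius=float(d["radius"]))
    if kind == "polygon":
        return PolygonGeom(vertices=tuple(tuple(v) for v in d["vertices"]))
    if kind == "polyline":
        return PolylineGeom(vertices=tuple(tuple(v) for v in d["vertices"]))
    if kind == "segment":
        return SegmentGeom(start=tuple(d["start"]), end=tuple(d["end"]))
    raise ValidationError(f"unknown geometry type {kind!r}; expected one of {sorted(_GEOM_TAGS)}")


def load_scene_json(path: Union[str, Path]) -> dict[str, Geometry]:
    """Load a scene file: a JSON list of geometry objects, each carrying an
    ``id`` plus the geometry fields."""
    with open(path) as fh:
        data = json.load(fh)
    out: dict[str, Geometry] = {}
    for entry in data:
        gid = entry.get("id")
        if not gid:
            raise ValidationError("every scene geometry needs an 'id'")
        if gid in out:
            raise ValidationError(f"duplicate geometry id {gid!r}")
        out[gid] = geometry_from_dict(entry)
    return out


def dump_scene_json(geometries: dict[str, Geometry], path: Union[str, Path]) -> None:
    data = [dict(id=gid, **geometry_to_dict(g)) for gid, g in geometries.items()]
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)
        fh.write("\n")
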