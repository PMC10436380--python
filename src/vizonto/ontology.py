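"""Builders turning the in-memory vocabulary into ontology models.

:func:`base_model` assembles the base visual-element layer: the element
kinds, the shape taxonomy with named polygons and their *exact* point
cardinalities, the color palette with RGB/hex data properties, stroke,
texture, size, point roles and the spatial-relationship object
properties.  :func:`dermoscopy_model` layers the dermoscopy vocabulary
and the pattern catalog on top, importing the base document by IRI.
"""

from __future__ import annotations

from typing import Optional

from .catalog import (
    BODY_POSITIONS,
    Catalog,
    RELATIONSHIPS,
    RELATIVE_POSITIONS,
    shipped_catalog,
)
from .geometry import PREDICATES
from .model import (
    BASE_SPATIAL_PATTERNS,
    DERMOSCOPY_SPATIAL_PATTERNS,
    ELEMENT_KINDS,
    DERMOSCOPY_ONLY_KINDS,
    LINE_STYLES,
    POINT_ROLES,
    POLYGON_CARDINALITY,
    SHAPE_KINDS,
    SIZES,
    STROKE_WIDTH_CATEGORIES,
    TEXTURES,
    DERMOSCOPY_ONLY_TEXTURES,
    DERMOSCOPY_ONLY_WIDTHS,
)
from .owl_io import (
    BASE_IRI,
    DERMOSCOPY_IRI,
    OntologyModel,
    PropertyDecl,
    Restriction,
)
from .palette import default_palette


def base_model() -> OntologyModel:
    """The base visual-element ontology layer."""
    m = OntologyModel(iri=BASE_IRI)
    m.add_class("Visual Element")
    for kind in ELEMENT_KINDS:
        if kind in DERMOSCOPY_ONLY_KINDS:
            continue
        label = {"SpatialPattern": "Spatial Pattern", "SpatialRelationship": "Spatial Relationship"}.get(kind, kind)
        m.add_class(label, parents=["VisualElement"])
    m.add_class("Visualization")
    m.add_class("Multi-Color", parents=["Color"])

    for kind in SHAPE_KINDS:
        if kind == "Path":
            continue  # Path is its own element kind
        m.add_class(kind, parents=["Shape"])
    for style in LINE_STYLES:
        m.add_class(f"{style} Line", parents=["Line"])
    for poly, n in POLYGON_CARDINALITY.items():
        m.add_class(poly, parents=["Polygon"])
        m.add_restriction(Restriction(on_class=poly, prop="hasPoints", kind="exactly", n=n, filler="Point"))

    for role in POINT_ROLES:
        if role != "Unspecified":
            m.add_class(f"{role} Point", parents=["Point"])
    for t in TEXTURES:
        if t not in DERMOSCOPY_ONLY_TEXTURES:
            m.add_class(f"{t} Texture", parents=["Texture"])
    for s in SIZES:
        m.add_class(f"{s} Size", parents=["Size"])
    for w in STROKE_WIDTH_CATEGORIES:
        if w not in DERMOSCOPY_ONLY_WIDTHS:
            m.add_class(f"{w} Width", parents=["Stroke"])
    for sp in BASE_SPATIAL_PATTERNS:
        m.add_class(sp, parents=["SpatialPattern"])
    for name, color in default_palette().items():
        if color.symbolic:
            continue  # skin-relative colors belong to the dermoscopy layer
        frag = m.add_class(name, parents=["Color"])

    obj = [
        PropertyDecl("hasShape", "object", domain="Pattern", range="Shape"),
        PropertyDecl("hasPattern", "object", domain="Pattern", range="Pattern"),  # non-functional
        PropertyDecl("hasSpatialPattern", "object", domain="Pattern", range="SpatialPattern"),
        PropertyDecl("hasColorFill", "object", domain="Shape", range="Color"),
        PropertyDecl("hasStroke", "object", domain="Shape", range="Stroke"),
        PropertyDecl("hasStrokeColor", "object", domain="Stroke", range="Color"),
        PropertyDecl("hasVisualTexture", "object", domain="Shape", range="Texture"),
        PropertyDecl("hasQualitativeSize", "object", domain="Shape", range="Size"),
        PropertyDecl("hasCategoryWidth", "object", domain="Stroke", range="Stroke"),
        PropertyDecl("hasPoints", "object", domain="Shape", range="Point"),
        PropertyDecl("hasMultipleColors", "object", domain="MultiColor", range="Color", inverse_of="isComposedOfColors"),
        PropertyDecl("isComposedOfColors", "object", domain="Color", range="MultiColor", inverse_of="hasMultipleColors"),
        PropertyDecl("hasSpatialRelationship", "object", domain="Shape", range="SpatialRelationship"),
    ]
    for pred in PREDICATES:
        if pred == "spatialSurround":
            continue  # dermoscopy-layer extension
        obj.append(PropertyDecl(pred, "object", domain="Shape", range="Shape"))
    for p in obj:
        m.add_property(p)
    # numeric data properties (typed numeric ranges, never plain literals)
    m.add_property(PropertyDecl("strokeWidth", "data", pref_label="stroke-width", domain="Stroke", range="xsd:integer"))
    m.add_property(PropertyDecl("rgbRed", "data", domain="Color", range="xsd:integer"))
    m.add_property(PropertyDecl("rgbGreen", "data", domain="Color", range="xsd:integer"))
    m.add_property(PropertyDecl("rgbBlue", "data", domain="Color", range="xsd:integer"))
    m.add_property(PropertyDecl("hexValue", "data", domain="Color", range="xsd:string"))
    return m


def dermoscopy_model(catalog: Optional[Catalog] = None) -> OntologyModel:
    """The dermoscopy layer: vocabulary extensions plus one class per
    catalog term, importing the base layer by IRI."""
    if catalog is None:
        catalog = shipped_catalog()
    m = OntologyModel(iri=DERMOSCOPY_IRI, imports=(BASE_IRI,))
    for kind in sorted(DERMOSCOPY_ONLY_KINDS):
        label = {"RelativePosition": "Relative Position", "BodyPosition": "Body Position"}.get(kind, kind)
        m.add_class(label, parents=["VisualElement"])
    for t in sorted(DERMOSCOPY_ONLY_TEXTURES):
        m.add_class(f"{t} Texture", parents=["Texture"])
    for w in sorted(DERMOSCOPY_ONLY_WIDTHS):
        m.add_class(f"{w} Width", parents=["Stroke"])
    for sp in DERMOSCOPY_SPATIAL_PATTERNS:
        m.add_class(sp, parents=["SpatialPattern"])
    for rel in RELATIONSHIPS:
        m.add_class(f"{rel} Spatial Relationship", parents=["SpatialRelationship"])
    for rp in RELATIVE_POSITIONS:
        m.add_class(rp, parents=["RelativePosition"])
    for bp in BODY_POSITIONS:
        m.add_class(bp, parents=["BodyPosition"])
    for name in ("Non-pigmented Color", "Hypopigmented Color", "Pigmented Color",
                 "Dark Color", "Uniform Color", "Variable Color"):
        m.add_class(name, parents=["Color"])
    m.add_property(PropertyDecl("hasRelativePosition", "object", domain="Shape", range="RelativePosition"))
    m.add_property(PropertyDecl("locatedAtBodyPosition", "object", domain="Pattern", range="BodyPosition"))
    m.add_property(PropertyDecl("spatialSurround", "object", domain="Shape", range="Shape"))

    for term in catalog.terms():
        d = catalog.definitions[term]
        parents = ["Pattern"]
        if d.group is not None:
            parents = [d.group]
        annotations = tuple(("note", a) for a in d.annotations)
        m.add_class(term, parents=parents, alt_labels=d.alt_labels, annotations=annotations)
        for c in d.clauses:
            if c.role == "subpattern-reference":
                m.add_restriction(
                    Restriction(on_class=camel(term), prop="hasPattern", kind="some",
                                filler=camel(c.pattern_ref))
                )
            elif c.role == "shape-requirement":
                m.add_restriction(
                    Restriction(on_class=camel(term), prop="hasShape", kind="some",
                                filler=c.shape_kind)
                )
        if d.body_position is not None:
            m.add_restriction(
                Restriction(on_class=camel(term), prop="locatedAtBodyPosition", kind="some",
                            filler=d.body_position)
            )
    m.add_property(PropertyDecl("note", "data", range="xsd:string"))
    return m


def camel(label: str) -> str:
    from .owl_io import camel_fragment

    return camel_fragment(label)
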