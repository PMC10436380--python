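"""OWL2 serialization of the visual-element model and pattern catalog.

The in-memory :class:`OntologyModel` is a typed container of declarations
and axioms: classes with preferred/alternative labels (SKOS), subclass
axioms, object/data properties with domain/range/inverse/functional
characteristics, qualified cardinality restrictions (polygon point counts
are *exact* cardinalities) and existential restrictions.  Documents are
exchanged as RDF/XML or Turtle through rdflib.

IRI scheme: one base namespace per layer with fragment = CamelCase label
(the base visual-element layer and the dermoscopy layer, which imports
it).  Restriction nodes are skolemized with deterministic fragment IRIs
instead of blank nodes so that export -> import -> export is
byte-identical.  Triples not recognized by the importer are preserved
verbatim and re-emitted.

No reasoner is bundled: :func:`check_consistency` performs structural
checks (cardinality clashes on the same class/property, cyclic subclass
chains); hook an external DL reasoner onto the exported document for full
consistency checking.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from rdflib import BNode, Graph, Literal, Namespace, RDF, RDFS, URIRef, XSD
from rdflib.namespace import OWL, SKOS

from .errors import ValidationError

BASE_IRI = "https://vizonto.dev/base"
DERMOSCOPY_IRI = "https://vizonto.dev/dermoscopy"

_CAMEL_STRIP = re.compile(r"[^0-9A-Za-z ]+")


def camel_fragment(label: str) -> str:
    """CamelCase IRI fragment for a human label.

    >>> camel_fragment("Pigment Network")
    'PigmentNetwork'
    """
    cleaned = _CAMEL_STRIP.sub(" ", label).strip()
    if not cleaned:
        raise ValidationError(f"label {label!r} yields an empty IRI fragment")
    return "".join(w[0].upper() + w[1:] for w in cleaned.split())


@dataclass(frozen=True)
class ClassDecl:
    name: str  # fragment
    pref_label: str
    alt_labels: tuple[str, ...] = ()
    parents: tuple[str, ...] = ()  # fragments
    annotations: tuple[tuple[str, str], ...] = ()  # (property fragment or CURIE, text)


@dataclass(frozen=True)
class PropertyDecl:
    name: str
    kind: str  # "object" | "data"
    pref_label: Optional[str] = None
    domain: Optional[str] = None
    range: Optional[str] = None  # class fragment or xsd datatype CURIE like "xsd:integer"
    inverse_of: Optional[str] = None
    functional: bool = False


@dataclass(frozen=True)
class Restriction:
    """A subclass-of-restriction axiom on ``on_class``."""

    on_class: str
    prop: str
    kind: str  # "exactly" | "max" | "min" | "some"
    n: Optional[int] = None
    filler: Optional[str] = None  # class fragment or xsd datatype CURIE

    def __post_init__(self):
        if self.kind in ("exactly", "max", "min") and self.n is None:
            raise ValidationError(f"{self.kind} restriction needs a cardinality")
        if self.kind == "some" and self.filler is None:
            raise ValidationError("existential restriction needs a filler class")


@dataclass
class OntologyModel:
    """Typed in-memory ontology document."""

    iri: str = BASE_IRI
    imports: tuple[str, ...] = ()
    classes: dict[str, ClassDecl] = field(default_factory=dict)
    properties: dict[str, PropertyDecl] = field(default_factory=dict)
    restrictions: list[Restriction] = field(default_factory=list)
    extra_triples: list[tuple] = field(default_factory=list)  # preserved opaque triples

    # -- construction helpers ------------------------------------------------
    def add_class(
        self,
        label: str,
        parents: Iterable[str] = (),
        alt_labels: Iterable[str] = (),
        annotations: Iterable[tuple[str, str]] = (),
    ) -> str:
        """Declare a class by human label; returns its fragment name.

        Every class carries exactly one SKOS preferred label (the human
        label) and any number of alternative labels.
        """
        name = camel_fragment(label)
        parent_frags = tuple(camel_fragment(p) if " " in p or not p.isidentifier() else p for p in parents)
        decl = ClassDecl(
            name=name,
            pref_label=label,
            alt_labels=tuple(alt_labels),
            parents=parent_frags,
            annotations=tuple(annotations),
        )
        if name in self.classes and self.classes[name] != decl:
            existing = self.classes[name]
            merged = replace(
                existing,
                parents=tuple(dict.fromkeys(existing.parents + decl.parents)),
                alt_labels=tuple(dict.fromkeys(existing.alt_labels + decl.alt_labels)),
                annotations=tuple(dict.fromkeys(existing.annotations + decl.annotations)),
            )
            self.classes[name] = merged
        else:
            self.classes[name] = decl
        return name

    def add_property(self, decl: PropertyDecl) -> str:
        if decl.kind not in ("object", "data"):
            raise ValidationError(f"property kind must be object or data, got {decl.kind!r}")
        self.properties[decl.name] = decl
        return decl.name

    def add_restriction(self, r: Restriction) -> None:
        self.restrictions.append(r)

    # -- interrogation -------------------------------------------------------
    def axioms(self) -> list[tuple]:
        """Deterministic (lexicographically sorted) axiom listing."""
        out: list[tuple] = []
        for name in sorted(self.classes):
            c = self.classes[name]
            out.append(("Declaration", "Class", name))
            for p in sorted(c.parents):
                out.append(("SubClassOf", name, p))
        for name in sorted(self.properties):
            p = self.properties[name]
            out.append(("Declaration", f"{p.kind.capitalize()}Property", name))
            if p.domain:
                out.append(("Domain", name, p.domain))
            if p.range:
                out.append(("Range", name, p.range))
            if p.inverse_of:
                out.append(("InverseOf", name, p.inverse_of))
            if p.functional:
                out.append(("Functional", name))
        for r in sorted(self.restrictions, key=lambda r: (r.on_class, r.prop, r.kind, r.n or 0, r.filler or "")):
            out.append(("SubClassOfRestriction", r.on_class, r.prop, r.kind, r.n, r.filler))
        return out


def entity_counts(model: OntologyModel, include_imports: bool = False,
                  imported: Iterable[OntologyModel] = ()) -> tuple[int, int, int]:
    """(classes, object properties, data properties) declared in the model.

    With ``include_imports=True`` the declarations of the supplied
    imported models are added, shared declarations counted once.
    """
    classes = set(model.classes)
    obj = {n for n, p in model.properties.items() if p.kind == "object"}
    dat = {n for n, p in model.properties.items() if p.kind == "data"}
    if include_imports:
        for m in imported:
            classes |= set(m.classes)
            obj |= {n for n, p in m.properties.items() if p.kind == "object"}
            dat |= {n for n, p in m.properties.items() if p.kind == "data"}
    return (len(classes), len(obj), len(dat))


def diff(a: OntologyModel, b: OntologyModel) -> dict[str, list[tuple]]:
    """Axioms only in ``a`` (``removed``) and only in ``b`` (``added``)."""
    sa, sb = set(a.axioms()), set(b.axioms())
    return {
        "removed": sorted(sa - sb, key=repr),
        "added": sorted(sb - sa, key=repr),
    }


def axiom_equivalent(a: OntologyModel, b: OntologyModel) -> bool:
    d = diff(a, b)
    return not d["added"] and not d["removed"]


# ---------------------------------------------------------------------------
# serialization

_DIALECTS = {"turtle": "turtle", "ttl": "turtle", "rdfxml": "xml", "xml": "xml", "rdf/xml": "xml"}

_XSD_CURIE = {
    "xsd:integer": XSD.integer,
    "xsd:string": XSD.string,
    "xsd:decimal": XSD.decimal,
    "xsd:float": XSD.float,
}
_XSD_BACK = {v: k for k, v in _XSD_CURIE.items()}

_RESTR_KIND_PRED = {
    "exactly": OWL.qualifiedCardinality,
    "max": OWL.maxQualifiedCardinality,
    "min": OWL.minQualifiedCardinality,
}


def _ns(model: OntologyModel) -> Namespace:
    return Namespace(model.iri + "#")


def _range_term(ns: Namespace, value: str):
    return _XSD_CURIE.get(value, ns[value])


def export_owl(model: OntologyModel, dialect: str = "turtle") -> str:
    """Serialize a model as OWL2 in the requested dialect.

    Restriction nodes get deterministic skolem IRIs, so repeated exports
    of equal models are byte-identical.
    """
    fmt = _DIALECTS.get(dialect.lower())
    if fmt is None:
        raise ValidationError(f"unknown dialect {dialect!r}; expected one of {sorted(set(_DIALECTS))}")
    ns = _ns(model)
    g = Graph()
    g.bind("", ns)
    g.bind("owl", OWL)
    g.bind("skos", SKOS)
    g.bind("xsd", XSD)
    onto = URIRef(model.iri)
    g.add((onto, RDF.type, OWL.Ontology))
    for imp in sorted(model.imports):
        g.add((onto, OWL.imports, URIRef(imp)))
    for name in sorted(model.classes):
        c = model.classes[name]
        iri = ns[name]
        g.add((iri, RDF.type, OWL.Class))
        g.add((iri, SKOS.prefLabel, Literal(c.pref_label)))
        for alt in sorted(c.alt_labels):
            g.add((iri, SKOS.altLabel, Literal(alt)))
        for p in sorted(c.parents):
            g.add((iri, RDFS.subClassOf, ns[p]))
        for prop, text in sorted(c.annotations):
            g.add((iri, ns[prop], Literal(text)))
    for name in sorted(model.properties):
        p = model.properties[name]
        iri = ns[name]
        g.add((iri, RDF.type, OWL.ObjectProperty if p.kind == "object" else OWL.DatatypeProperty))
        if p.pref_label:
            g.add((iri, SKOS.prefLabel, Literal(p.pref_label)))
        if p.domain:
            g.add((iri, RDFS.domain, ns[p.domain]))
        if p.range:
            g.add((iri, RDFS.range, _range_term(ns, p.range)))
        if p.inverse_of:
            g.add((iri, OWL.inverseOf, ns[p.inverse_of]))
        if p.functional:
            g.add((iri, RDF.type, OWL.FunctionalProperty))
    for r in sorted(model.restrictions, key=lambda r: (r.on_class, r.prop, r.kind, r.n or 0, r.filler or "")):
        # deterministic skolem IRI in place of a blank node
        tag = f"_r{camel_fragment(r.on_class)}{camel_fragment(r.prop)}{r.kind.capitalize()}"
        if r.n is not None:
            tag += str(r.n)
        if r.filler is not None:
            tag += camel_fragment(r.filler.replace("xsd:", "Xsd"))
        node = ns[tag]
        g.add((ns[r.on_class], RDFS.subClassOf, node))
        g.add((node, RDF.type, OWL.Restriction))
        g.add((node, OWL.onProperty, ns[r.prop]))
        if r.kind == "some":
            g.add((node, OWL.someValuesFrom, _range_term(ns, r.filler)))
        else:
            g.add((node, _RESTR_KIND_PRED[r.kind], Literal(r.n, datatype=XSD.nonNegativeInteger)))
            if r.filler:
                g.add((node, OWL.onClass, _range_term(ns, r.filler)))
    for t in model.extra_triples:
        g.add(t)
    return g.serialize(format=fmt)


def import_owl(document: str, dialect: Optional[str] = None) -> OntologyModel:
    """Parse an OWL2 document back into an :class:`OntologyModel`.

    ``dialect`` may be omitted: Turtle is tried first, then RDF/XML.
    Recognized axioms populate the typed fields; everything else is kept
    in ``extra_triples`` and survives re-export.
    """
    g = Graph()
    if dialect is not None:
        fmt = _DIALECTS.get(dialect.lower())
        if fmt is None:
            raise ValidationError(f"unknown dialect {dialect!r}")
        g.parse(data=document, format=fmt)
    else:
        try:
            g.parse(data=document, format="turtle")
        except Exception:
            g = Graph()
            g.parse(data=document, format="xml")

    onto = next(g.subjects(RDF.type, OWL.Ontology), None)
    iri = str(onto) if onto is not None else BASE_IRI
    model = OntologyModel(iri=iri)
    ns = _ns(model)
    consumed: set[tuple] = set()

    def frag(term) -> Optional[str]:
        s = str(term)
        if s.startswith(model.iri + "#"):
            return s[len(model.iri) + 1 :]
        return None

    if onto is not None:
        consumed.add((onto, RDF.type, OWL.Ontology))
        imports = []
        for _, _, o in g.triples((onto, OWL.imports, None)):
            imports.append(str(o))
            consumed.add((onto, OWL.imports, o))
        model.imports = tuple(sorted(imports))

    restriction_nodes = set(g.subjects(RDF.type, OWL.Restriction))

    for s in sorted(set(g.subjects(RDF.type, OWL.Class)), key=str):
        name = frag(s)
        if name is None or s in restriction_nodes:
            continue
        consumed.add((s, RDF.type, OWL.Class))
        pref = next(g.objects(s, SKOS.prefLabel), None)
        if pref is not None:
            consumed.add((s, SKOS.prefLabel, pref))
        alts = sorted(str(o) for o in g.objects(s, SKOS.altLabel))
        for o in g.objects(s, SKOS.altLabel):
            consumed.add((s, SKOS.altLabel, o))
        parents = []
        annotations = []
        for o in g.objects(s, RDFS.subClassOf):
            if o in restriction_nodes:
                continue  # handled below
            pf = frag(o)
            if pf is not None:
                parents.append(pf)
                consumed.add((s, RDFS.subClassOf, o))
        for p, o in g.predicate_objects(s):
            pf = frag(p)
            if pf is not None and isinstance(o, Literal):
                annotations.append((pf, str(o)))
                consumed.add((s, p, o))
        model.classes[name] = ClassDecl(
            name=name,
            pref_label=str(pref) if pref is not None else name,
            alt_labels=tuple(alts),
            parents=tuple(sorted(parents)),
            annotations=tuple(sorted(annotations)),
        )

    for rdf_kind, kind in ((OWL.ObjectProperty, "object"), (OWL.DatatypeProperty, "data")):
        for s in sorted(set(g.subjects(RDF.type, rdf_kind)), key=str):
            name = frag(s)
            if name is None:
                continue
            consumed.add((s, RDF.type, rdf_kind))
            pref = next(g.objects(s, SKOS.prefLabel), None)
            if pref is not None:
                consumed.add((s, SKOS.prefLabel, pref))
            dom = next(g.objects(s, RDFS.domain), None)
            rng = next(g.objects(s, RDFS.range), None)
            inv = next(g.objects(s, OWL.inverseOf), None)
            functional = (s, RDF.type, OWL.FunctionalProperty) in g
            for pred, val in ((RDFS.domain, dom), (RDFS.range, rng), (OWL.inverseOf, inv)):
                if val is not None:
                    consumed.add((s, pred, val))
            if functional:
                consumed.add((s, RDF.type, OWL.FunctionalProperty))
            model.properties[name] = PropertyDecl(
                name=name,
                kind=kind,
                pref_label=str(pref) if pref is not None else None,
                domain=frag(dom) if dom is not None else None,
                range=(_XSD_BACK.get(rng) or frag(rng)) if rng is not None else None,
                inverse_of=frag(inv) if inv is not None else None,
                functional=functional,
            )

    for node in sorted(restriction_nodes, key=str):
        holders = [s for s in g.subjects(RDFS.subClassOf, node)]
        prop = next(g.objects(node, OWL.onProperty), None)
        if not holders or prop is None:
            continue
        consumed.add((node, RDF.type, OWL.Restriction))
        consumed.add((node, OWL.onProperty, prop))
        some = next(g.objects(node, OWL.someValuesFrom), None)
        kind = None
        n = None
        filler = None
        if some is not None:
            kind, filler = "some", (_XSD_BACK.get(some) or frag(some))
            consumed.add((node, OWL.someValuesFrom, some))
        else:
            for k, pred in _RESTR_KIND_PRED.items():
                lit = next(g.objects(node, pred), None)
                if lit is not None:
                    kind, n = k, int(lit)
                    consumed.add((node, pred, lit))
                    break
            on_class = next(g.objects(node, OWL.onClass), None)
            if on_class is not None:
                filler = _XSD_BACK.get(on_class) or frag(on_class)
                consumed.add((node, OWL.onClass, on_class))
        if kind is None:
            continue
        for holder in holders:
            hf = frag(holder)
            if hf is None:
                continue
            consumed.add((holder, RDFS.subClassOf, node))
            model.restrictions.append(
                Restriction(on_class=hf, prop=frag(prop), kind=kind, n=n, filler=filler)
            )

    model.restrictions.sort(key=lambda r: (r.on_class, r.prop, r.kind, r.n or 0, r.filler or ""))
    for t in g:
        if t not in consumed and not isinstance(t[0], BNode):
            model.extra_triples.append(t)
    model.extra_triples.sort(key=repr)
    return model


def check_consistency(model: OntologyModel) -> list[str]:
    """Structural consistency checks (not a DL reasoner).

    Flags conflicting cardinality restrictions on the same class/property
    and subclass cycles.
    """
    problems = []
    seen: dict[tuple[str, str], Restriction] = {}
    for r in model.restrictions:
        if r.kind not in ("exactly", "max", "min"):
            continue
        key = (r.on_class, r.prop)
        prev = seen.get(key)
        if prev is not None:
            bad = (
                (prev.kind == "exactly" and r.kind == "exactly" and prev.n != r.n)
                or (prev.kind == "exactly" and r.kind == "max" and r.n < prev.n)
                or (prev.kind == "max" and r.kind == "exactly" and prev.n < r.n)
                or (prev.kind == "min" and r.kind == "max" and r.n < prev.n)
                or (prev.kind == "max" and r.kind == "min" and r.n > prev.n)
            )
            if bad:
                problems.append(f"cardinality clash on {r.on_class}.{r.prop}: {prev.kind} {prev.n} vs {r.kind} {r.n}")
        else:
            seen[key] = r
    # subclass cycles
    import networkx as nx

    g = nx.DiGraph()
    for c in model.classes.values():
        for p in c.parents:
            g.add_edge(c.name, p)
    try:
        cyc = nx.find_cycle(g)
        problems.append("subclass cycle: " + " < ".join(e[0] for e in cyc))
    except nx.NetworkXNoCycle:
        pass
    return problems
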