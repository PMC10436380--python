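"""Semiotic quality scoring for ontologies.

Quality is scored on three layers with leaf metrics in [0, 1]:

* syntactic — *richness* (fraction of a fixed inventory of OWL2
  construct kinds the ontology uses) and *lawfulness* (fraction of
  syntactically clean statements);
* semantic — *clarity*, *consistency*, *interpretability*: these require
  an external word-sense inventory and are accepted as externally
  supplied leaf scores (CSV) behind a pluggable lexical-oracle interface
  with a stub default, never recomputed here;
* pragmatic — *comprehensiveness* (element count relative to the largest
  ontology in a comparison corpus).

Composites are weighted means (uniform by default): syntactic from
richness and lawfulness, semantic from its three leaves, pragmatic equals
comprehensiveness, overall from the three composites.  Cross-ontology
z-scores use the sample standard deviation (n - 1 denominator).  Raw
values are kept at full precision; display rounding is half-to-even.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ValidationError
from .owl_io import OntologyModel

#: Fixed inventory of OWL2 construct kinds for the richness metric.
CONSTRUCT_INVENTORY = (
    "ClassDeclaration",
    "ObjectPropertyDeclaration",
    "DataPropertyDeclaration",
    "SubClassOf",
    "ObjectPropertyDomain",
    "ObjectPropertyRange",
    "DataPropertyDomain",
    "DataPropertyRange",
    "InverseObjectProperties",
    "FunctionalProperty",
    "ExactCardinality",
    "MaxCardinality",
    "MinCardinality",
    "ExistentialRestriction",
    "AnnotationAssertion",
    "Imports",
)

LEAF_NAMES = ("richness", "lawfulness", "clarity", "consistency", "interpretability", "comprehensiveness")


@dataclass(frozen=True)
class LeafScores:
    richness: Optional[float] = None
    lawfulness: Optional[float] = None
    clarity: Optional[float] = None
    consistency: Optional[float] = None
    interpretability: Optional[float] = None
    comprehensiveness: Optional[float] = None

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValidationError(f"leaf score {f.name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class CompositeScores:
    syntactic: float
    semantic: float
    pragmatic: float
    overall: float


@dataclass(frozen=True)
class MetricWeights:
    """Non-negative weights, normalized within each composite."""

    syntactic: tuple[float, float] = (1.0, 1.0)  # richness, lawfulness
    semantic: tuple[float, float, float] = (1.0, 1.0, 1.0)  # clarity, consistency, interpretability
    overall: tuple[float, float, float] = (1.0, 1.0, 1.0)  # syntactic, semantic, pragmatic

    def __post_init__(self):
        for f in fields(self):
            w = getattr(self, f.name)
            if any(x < 0 for x in w) or sum(w) <= 0:
                raise ValidationError(f"weights {f.name} must be non-negative with positive sum")


def _wmean(values: Sequence[float], weights: Sequence[float]) -> float:
    w = np.asarray(weights, dtype=float)
    return float(np.average(np.asarray(values, dtype=float), weights=w))


def constructs_used(model: OntologyModel) -> set[str]:
    used: set[str] = set()
    if model.classes:
        used.add("ClassDeclaration")
    for c in model.classes.values():
        if c.parents:
            used.add("SubClassOf")
        if c.annotations or c.alt_labels or c.pref_label:
            used.add("AnnotationAssertion")
    for p in model.properties.values():
        used.add("ObjectPropertyDeclaration" if p.kind == "object" else "DataPropertyDeclaration")
        if p.domain:
            used.add("ObjectPropertyDomain" if p.kind == "object" else "DataPropertyDomain")
        if p.range:
            used.add("ObjectPropertyRange" if p.kind == "object" else "DataPropertyRange")
        if p.inverse_of:
            used.add("InverseObjectProperties")
        if p.functional:
            used.add("FunctionalProperty")
    for r in model.restrictions:
        used.add({
            "exactly": "ExactCardinality",
            "max": "MaxCardinality",
            "min": "MinCardinality",
            "some": "ExistentialRestriction",
        }[r.kind])
    if model.imports:
        used.add("Imports")
    return used


def richness(model: OntologyModel, construct_inventory: Sequence[str] = CONSTRUCT_INVENTORY) -> float:
    """Fraction of the construct inventory the ontology actually uses."""
    if not construct_inventory:
        raise ValidationError("construct inventory must be non-empty")
    inv = set(construct_inventory)
    return len(constructs_used(model) & inv) / len(inv)


def lawfulness(document: str, dialect: str = "turtle") -> float:
    """1 minus the fraction of syntactically violating statements.

    A document that parses cleanly scores 1 (an empty document scores 1
    by convention: no violations).  For Turtle input that fails a strict
    parse, statements are re-tried one at a time (with the document's
    prefix header) and the violating fraction is counted; a malformed
    RDF/XML document scores 0.
    """
    from rdflib import Graph

    if document is None:
        raise ValidationError("unreadable document")
    if not document.strip():
        return 1.0
    try:
        Graph().parse(data=document, format={"turtle": "turtle"}.get(dialect, dialect))
        return 1.0
    except Exception:
        if dialect not in ("turtle", "ttl"):
            return 0.0
    # lenient statement-by-statement turtle check
    header_lines = []
    statements: list[str] = []
    current: list[str] = []
    for line in document.splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if stripped.startswith(("@prefix", "@base", "PREFIX", "BASE")):
            header_lines.append(line)
            continue
        current.append(line)
        if stripped.endswith("."):
            statements.append("\n".join(current))
            current = []
    if current:
        statements.append("\n".join(current))
    if not statements:
        return 1.0
    header = "\n".join(header_lines)
    bad = 0
    for st in statements:
        try:
            Graph().parse(data=header + "\n" + st, format="turtle")
        except Exception:
            bad += 1
    return 1.0 - bad / len(statements)


def element_count(model: OntologyModel) -> int:
    """Ontology elements: classes plus object and data properties."""
    return len(model.classes) + len(model.properties)


def comprehensiveness(
    model_or_count: Union[OntologyModel, int],
    corpus: Iterable[Union[OntologyModel, int]],
) -> float:
    """Element count normalized by the largest ontology in
    corpus + {ontology}: the largest scores 1."""
    def count(x) -> int:
        return x if isinstance(x, int) else element_count(x)

    corpus = list(corpus)
    if not corpus:
        raise ValidationError("corpus must be non-empty")
    own = count(model_or_count)
    peak = max([own] + [count(c) for c in corpus])
    return own / peak if peak else 1.0


def aggregate(leaf: LeafScores, w: Optional[MetricWeights] = None) -> CompositeScores:
    """Composite scores from leaves: syntactic = weighted mean of
    (richness, lawfulness); semantic = weighted mean of (clarity,
    consistency, interpretability); pragmatic = comprehensiveness;
    overall = weighted mean of the three composites.  Uniform weights by
    default; a missing required leaf raises an error naming it.
    """
    w = w or MetricWeights()
    for name in ("richness", "lawfulness", "comprehensiveness"):
        if getattr(leaf, name) is None:
            raise ValidationError(f"missing leaf score: {name}")
    syntactic = _wmean((leaf.richness, leaf.lawfulness), w.syntactic)
    semantic_leaves = (leaf.clarity, leaf.consistency, leaf.interpretability)
    for name, v in zip(("clarity", "consistency", "interpretability"), semantic_leaves):
        if v is None:
            raise ValidationError(f"missing leaf score: {name}")
    semantic = _wmean(semantic_leaves, w.semantic)
    pragmatic = leaf.comprehensiveness
    overall = _wmean((syntactic, semantic, pragmatic), w.overall)
    return CompositeScores(syntactic=syntactic, semantic=semantic, pragmatic=pragmatic, overall=overall)


def zscores(values: Union[Mapping[str, float], Sequence[float]]) -> Union[dict[str, float], list[float]]:
    """Standard scores across ontologies: (x - mean) / sample sd (n - 1).

    Raises on fewer than two values or zero variance.
    """
    keys = None
    if isinstance(values, Mapping):
        keys = list(values)
        vec = np.asarray([values[k] for k in keys], dtype=float)
    else:
        vec = np.asarray(list(values), dtype=float)
    if vec.size < 2:
        raise ValidationError("z-scores need at least 2 values")
    sd = float(np.std(vec, ddof=1))
    if sd == 0.0:
        raise ValidationError("zero variance: z-scores undefined for identical values")
    z = (vec - vec.mean()) / sd
    if keys is not None:
        return {k: float(v) for k, v in zip(keys, z)}
    return [float(v) for v in z]


def round_half_even(x: float, digits: int) -> float:
    """Display rounding, half to even, on the decimal (printed) value —
    0.6925 rounds to 0.692 regardless of its binary neighborhood."""
    import decimal

    d = decimal.Decimal(repr(float(x))).quantize(
        decimal.Decimal(1).scaleb(-digits), rounding=decimal.ROUND_HALF_EVEN
    )
    return float(d)


# ---------------------------------------------------------------------------
# lexical oracle stub and report table


class LexicalOracle:
    """Interface for the external word-sense machinery behind the semantic
    leaves.  The stub refuses to score, making the external dependency
    explicit; supply leaf CSVs or a real oracle instead."""

    def semantic_leaves(self, model: OntologyModel) -> tuple[float, float, float]:
        raise NotImplementedError(
            "semantic leaves (clarity, consistency, interpretability) require an "
            "external sense inventory; supply them via a leaf-score CSV"
        )


def load_leaf_table(path) -> pd.DataFrame:
    """Leaf-score CSV: rows = ontologies, columns = leaf metrics."""
    df = pd.read_csv(path, index_col=0)
    unknown = set(df.columns) - set(LEAF_NAMES)
    if unknown:
        raise ValidationError(f"unknown leaf metrics in table: {sorted(unknown)}")
    return df


def score_report(leaf_table: pd.DataFrame, w: Optional[MetricWeights] = None,
                 digits: int = 3) -> pd.DataFrame:
    """Composite scores and cross-ontology z-scores for a leaf table.

    Returns a table with one row per ontology: the six leaves, the four
    composites and a z-score per composite (computed across the table's
    ontologies).  Values are rounded half-to-even for display.
    """
    rows = {}
    for name, leaf_row in leaf_table.iterrows():
        leaf = LeafScores(**{k: leaf_row.get(k) for k in LEAF_NAMES if pd.notna(leaf_row.get(k))})
        comp = aggregate(leaf, w)
        rows[name] = {
            **{k: getattr(leaf, k) for k in LEAF_NAMES},
            "syntactic": comp.syntactic,
            "semantic": comp.semantic,
            "pragmatic": comp.pragmatic,
            "overall": comp.overall,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    for comp in ("syntactic", "semantic", "pragmatic", "overall"):
        z = zscores({k: rows[k][comp] for k in rows})
        df[f"z_{comp}"] = pd.Series(z)
    return df.map(lambda v: round_half_even(v, digits) if pd.notna(v) else v)
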