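"""Semiotic metrics: leaves, aggregation, z-scores."""

import numpy as np
import pandas as pd
import pytest

from vizonto.errors import ValidationError
from vizonto.metrics import (
    CONSTRUCT_INVENTORY,
    LeafScores,
    LexicalOracle,
    MetricWeights,
    aggregate,
    comprehensiveness,
    constructs_used,
    lawfulness,
    richness,
    round_half_even,
    score_report,
    zscores,
)
from vizonto.owl_io import OntologyModel, PropertyDecl, Restriction


class TestRichness:
    def test_empty_model_scores_zero(self):
        assert richness(OntologyModel()) == 0.0

    def test_full_inventory_scores_one(self, dermoscopy, base):
        # a model using every construct kind in the inventory
        m = OntologyModel(imports=("x",))
        m.add_class("A")
        m.add_class("B", parents=["A"])
        m.add_property(PropertyDecl("o", "object", domain="A", range="A", inverse_of="o", functional=True))
        m.add_property(PropertyDecl("d", "data", domain="A", range="xsd:integer"))
        for kind, n in (("exactly", 1), ("max", 2), ("min", 1), ("some", None)):
            m.add_restriction(Restriction(on_class="A", prop="o", kind=kind, n=n, filler="A"))
        assert constructs_used(m) == set(CONSTRUCT_INVENTORY)
        assert richness(m) == 1.0

    def test_partial_inventory_is_a_ratio(self):
        m = OntologyModel()
        m.add_class("A")
        m.add_class("B", parents=["A"])  # declarations + subclass + annotations
        m.add_property(PropertyDecl("d", "data"))
        assert constructs_used(m) == {
            "ClassDeclaration", "SubClassOf", "AnnotationAssertion", "DataPropertyDeclaration",
        }
        # 4 of a 16-kind inventory
        assert richness(m, CONSTRUCT_INVENTORY) == 4 / 16 == 0.25

    def test_empty_inventory_rejected(self):
        with pytest.raises(ValidationError):
            richness(OntologyModel(), ())


class TestLawfulness:
    def test_clean_document_scores_one(self, base):
        from vizonto.owl_io import export_owl

        assert lawfulness(export_owl(base, "turtle")) == 1.0

    def test_half_violating_statements(self):
        doc = (
            "@prefix : <http://example.org/> .\n"
            ":a :b :c .\n"
            ":d :e 'unterminated\n"
        )
        assert lawfulness(doc) == 0.5

    def test_empty_document_scores_one_by_convention(self):
        assert lawfulness("") == 1.0

    def test_unreadable_document_rejected(self):
        with pytest.raises(ValidationError):
            lawfulness(None)


class TestComprehensiveness:
    def test_largest_in_corpus_scores_one(self):
        assert comprehensiveness(500, [50, 120, 500]) == 1.0

    def test_singleton_corpus_same_ontology(self):
        m = OntologyModel()
        m.add_class("A")
        assert comprehensiveness(m, [m]) == 1.0

    def test_ratio_against_corpus_max(self):
        assert comprehensiveness(50, [500, 100]) == 0.1

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValidationError):
            comprehensiveness(10, [])


# Published side-by-side comparison table for four dermatology ontologies:
# leaves (richness, lawfulness, clarity, consistency, interpretability,
# comprehensiveness) per ontology.
TABLE = {
    "DEVO": (0.564, 1.0, 0.988, 1.0, 0.964, 0.02),
    "DL": (0.333, 0.501, 0.999, 0.0004, 1.0, 0.22),
    "HDDO": (0.154, 1.0, 0.998, 0.934, 0.901, 0.065),
    "SPO": (0.385, 1.0, 0.983, 0.981, 0.575, 0.006),
}
PRINTED_SYNTACTIC = {"DEVO": 0.782, "DL": 0.417, "HDDO": 0.577, "SPO": 0.692}
PRINTED_OVERALL = {"DEVO": 0.597, "DL": 0.436, "HDDO": 0.53, "SPO": 0.516}


def leaf(name):
    r, l, cl, co, it, cm = TABLE[name]
    return LeafScores(richness=r, lawfulness=l, clarity=cl, consistency=co,
                      interpretability=it, comprehensiveness=cm)


class TestAggregate:
    @pytest.mark.parametrize("name", sorted(TABLE))
    def test_syntactic_composite_reproduces_printed_value(self, name):
        comp = aggregate(leaf(name))
        assert round_half_even(comp.syntactic, 3) == PRINTED_SYNTACTIC[name]

    def test_all_ones_gives_all_ones(self):
        comp = aggregate(LeafScores(1, 1, 1, 1, 1, 1))
        assert (comp.syntactic, comp.semantic, comp.pragmatic, comp.overall) == (1, 1, 1, 1)

    def test_missing_leaf_named_in_error(self):
        with pytest.raises(ValidationError, match="lawfulness"):
            aggregate(LeafScores(richness=0.5, comprehensiveness=0.1,
                                 clarity=1, consistency=1, interpretability=1))

    def test_weights_are_validated(self):
        with pytest.raises(ValidationError):
            MetricWeights(syntactic=(-1.0, 1.0))

    def test_custom_weights_shift_composite(self):
        w = MetricWeights(syntactic=(1.0, 3.0))
        comp = aggregate(leaf("DEVO"), w)
        assert comp.syntactic == pytest.approx((0.564 + 3 * 1.0) / 4)

    def test_leaf_scores_bounded(self):
        with pytest.raises(ValidationError):
            LeafScores(richness=1.2)


class TestZScores:
    def test_overall_row(self):
        z = zscores({k: PRINTED_OVERALL[k] for k in ("DEVO", "DL", "HDDO", "SPO")})
        assert z["DEVO"] == pytest.approx(1.17, abs=0.005)

    def test_pragmatic_row(self):
        z = zscores({"DEVO": 0.02, "DL": 0.22, "HDDO": 0.065, "SPO": 0.006})
        assert z["DEVO"] == pytest.approx(-0.589, abs=0.005)
        assert z["DL"] == pytest.approx(1.45, abs=0.005)

    def test_richness_row(self):
        z = zscores([0.564, 0.333, 0.154, 0.385])
        assert z[0] == pytest.approx(1.22, abs=0.005)

    def test_zscores_sum_to_zero(self):
        z = zscores([0.1, 0.5, 0.9, 0.42])
        assert abs(sum(z)) < 1e-9

    def test_identical_values_rejected(self):
        with pytest.raises(ValidationError):
            zscores([0.5, 0.5, 0.5])

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValidationError):
            zscores([0.5])


class TestReport:
    def test_report_layout_and_zscores(self):
        df = pd.DataFrame.from_dict(
            {k: dict(zip(("richness", "lawfulness", "clarity", "consistency",
                          "interpretability", "comprehensiveness"), v))
             for k, v in TABLE.items()}, orient="index")
        rep = score_report(df)
        assert rep.loc["DEVO", "syntactic"] == 0.782
        assert rep.loc["DEVO", "z_overall"] == pytest.approx(1.17, abs=0.005)
        assert set(rep.index) == set(TABLE)

    def test_lexical_oracle_stub_refuses(self):
        with pytest.raises(NotImplementedError):
            LexicalOracle().semantic_leaves(OntologyModel())

    def test_round_half_even(self):
        assert round_half_even(0.6925, 3) == 0.692
        assert round_half_even(0.8166666, 2) == 0.82
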