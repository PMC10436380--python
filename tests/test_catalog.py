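"""Pattern catalog: registration, decomposition, groups, coverage audit."""

import pytest

from vizonto.catalog import (
    AUDIT_CATEGORIES,
    Catalog,
    ElementClause,
    PatternDefinition,
    audit_category_coverage,
    decompose,
    definition_from_dict,
    groups,
    load_catalog,
    register_pattern,
    shipped_catalog,
    validate_catalog,
)
from vizonto.errors import UnknownTermError, ValidationError, VocabularyError


def shape_clause(**kw):
    return ElementClause(role="shape-requirement", **kw)


class TestRegistration:
    def test_register_under_group(self):
        cat = Catalog()
        register_pattern(PatternDefinition("Streaks Pattern", (ElementClause(role="annotation", text="group"),)), cat)
        register_pattern(
            PatternDefinition("Pseudopods", (shape_clause(shape_kind="Circle"),), group="Streaks Pattern"), cat
        )
        assert groups(cat) == {"Streaks Pattern": ["Pseudopods"]}

    def test_duplicate_term_rejected(self):
        cat = Catalog()
        d = PatternDefinition("X", (shape_clause(shape_kind="Circle"),))
        register_pattern(d, cat)
        with pytest.raises(ValidationError, match="already registered"):
            register_pattern(d, cat)

    def test_dangling_group_rejected(self):
        cat = Catalog()
        with pytest.raises(ValidationError, match="Nonexistent"):
            register_pattern(
                PatternDefinition("X", (shape_clause(shape_kind="Circle"),), group="Nonexistent"), cat
            )

    def test_unknown_vocabulary_in_clause_rejected(self):
        cat = Catalog()
        with pytest.raises(VocabularyError):
            register_pattern(PatternDefinition("X", (shape_clause(shape_kind="Blob"),)), cat)

    def test_clause_role_field_licensing(self):
        with pytest.raises(ValidationError):
            ElementClause(role="annotation", text="t", shape_kind="Circle")

    def test_round_trip_register_then_decompose(self):
        cat = Catalog()
        clauses = (
            shape_clause(shape_kind="Circle", color=("Brown",), size="Small"),
            ElementClause(role="relation-assertion", subject="Circle", predicate="spatialMeet", object="Circle"),
        )
        register_pattern(PatternDefinition("Toy", clauses), cat)
        assert tuple(decompose("Toy", cat)) == clauses


class TestShippedCatalog:
    def test_validates_with_no_dangling_identifiers(self, catalog):
        assert validate_catalog(catalog) == []

    def test_six_higher_level_groups(self, catalog):
        g = groups(catalog)
        assert {k: len(v) for k, v in g.items()} == {
            "Blotch Pattern": 2,
            "Globules Pattern": 4,
            "Dots Pattern": 2,
            "Streaks Pattern": 3,
            "Shiny White Structures": 3,
            "Network Pattern": 2,
        }

    def test_network_group_members(self, catalog):
        assert set(groups(catalog)["Network Pattern"]) == {"Pigment Network", "Negative Network"}

    def test_empty_catalog_has_no_groups(self):
        assert groups(Catalog()) == {}

    def test_pseudopods_decomposition(self, catalog):
        clauses = decompose("Pseudopods", catalog)
        kinds = {(c.role, c.shape_kind) for c in clauses if c.role == "shape-requirement"}
        assert ("shape-requirement", "Circle") in kinds and ("shape-requirement", "Line") in kinds
        circle = next(c for c in clauses if c.shape_kind == "Circle")
        assert circle.relative_position == "Periphery"
        line = next(c for c in clauses if c.shape_kind == "Line")
        assert line.relationship == "Radial"
        rel = next(c for c in clauses if c.role == "relation-assertion")
        assert (rel.subject, rel.predicate, rel.object) == ("Circle", "spatialMeet", "Line")

    def test_rosettes_decomposition(self, catalog):
        clauses = decompose("Rosettes", catalog)
        circle = next(c for c in clauses if c.role == "shape-requirement")
        assert "Bright White" in circle.color or "White" in circle.color
        assert any(c.role == "spatial-pattern" and c.value == "SquareFormation" for c in clauses)

    def test_pigment_network_decomposition(self, catalog):
        clauses = decompose("Pigment Network", catalog)
        line = next(c for c in clauses if c.shape_kind == "Line")
        assert line.color == ("Pigmented",) and line.relationship == "Interconnecting"
        circle = next(c for c in clauses if c.shape_kind == "Circle")
        assert circle.color == ("Hypopigmented",) and circle.size == "Large"
        rel = next(c for c in clauses if c.role == "relation-assertion")
        assert rel.predicate == "spatialSurround"

    def test_starburst_expands_through_pseudopods(self, catalog):
        expanded = decompose("Starburst", catalog)
        assert any(c.role == "relation-assertion" and c.predicate == "spatialMeet" for c in expanded)

    def test_alias_resolution_is_unique(self, catalog):
        for term, d in catalog.definitions.items():
            for label in (term, *d.alt_labels):
                assert catalog.resolve(label) == term

    def test_unknown_term_suggests_neighbours(self, catalog):
        with pytest.raises(UnknownTermError, match="Pseudopods"):
            catalog.resolve("Psuedopods")

    def test_imaging_modality_lives_only_in_annotations(self, catalog):
        # non-visual information (polarized-light detection) never leaks
        # into clauses
        d = catalog.definitions["Rainbow Pattern"]
        assert any("polarized light" in a for a in d.annotations)
        for c in d.clauses:
            assert c.role != "annotation" or "polarized" not in (c.text or "")
        for term in ("Rosettes", "Shiny White Streaks"):
            dd = catalog.definitions[term]
            assert any("polarized" in a for a in dd.annotations)


class TestAudit:
    def test_missing_category_named(self):
        cat = Catalog()
        register_pattern(PatternDefinition("A", (shape_clause(shape_kind="Circle", color=("Brown",)),)), cat)
        register_pattern(PatternDefinition("B", (shape_clause(shape_kind="Line"),)), cat)
        report = audit_category_coverage(cat)
        assert report["color"] == ["B"]

    def test_complete_coverage_is_empty_for_category(self):
        cat = Catalog()
        register_pattern(PatternDefinition("A", (shape_clause(shape_kind="Circle", color=("Brown",)),)), cat)
        register_pattern(PatternDefinition("B", (shape_clause(shape_kind="Line", color=("Black",)),)), cat)
        assert "color" not in audit_category_coverage(cat)

    def test_shipped_report_is_deterministic(self, catalog):
        r1 = audit_category_coverage(catalog)
        r2 = audit_category_coverage(shipped_catalog())
        assert r1 == r2
        assert list(r1) == [c for c in AUDIT_CATEGORIES if c in r1]


class TestYamlLoading:
    def test_schema_error_reports_line(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text("- term: Broken\n  clauses:\n    - role: shape-requirement\n      shape_kind: Blob\n")
        with pytest.raises(ValidationError, match=r"line \d+"):
            load_catalog(bad)

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValidationError, match="unknown keys"):
            definition_from_dict({"term": "X", "clauses": [], "shape": "Circle"})

    def test_user_catalog_extends_shipped(self, tmp_path, catalog):
        extra = tmp_path / "extra.yaml"
        extra.write_text(
            "- term: Leaflike Areas\n"
            "  clauses:\n"
            "    - role: shape-requirement\n"
            "      shape_kind: Polygon\n"
            "      color: Brown\n"
            "    - role: spatial-pattern\n"
            "      value: LeaflikePattern\n"
        )
        cat = shipped_catalog()
        load_catalog(extra, into=cat)
        assert "Leaflike Areas" in cat
        assert len(cat) == len(catalog) + 1
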