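"""Feature queries: matching semantics, brute-force equivalence, parsing."""

import pytest

from vizonto.catalog import decompose
from vizonto.errors import UnknownTermError, ValidationError, VocabularyError
from vizonto.palette import COLOR_SUBSUMPTION
from vizonto.query import (
    FeatureQuery,
    QUERY_CATEGORIES,
    features_of,
    find_patterns,
    parse_query,
)


def brute_force_terms(catalog, category, value, mode="subsumes"):
    """Independent oracle: scan every term's expanded clauses directly."""

    def color_ok(clause_colors):
        if value in clause_colors:
            return True
        if mode != "subsumes":
            return False
        # transitive closure by repeated direct lookup
        frontier, seen = {value}, set()
        while frontier:
            nxt = set()
            for v in frontier:
                for sub in COLOR_SUBSUMPTION.get(v, ()):
                    if sub not in seen:
                        seen.add(sub)
                        nxt.add(sub)
            frontier = nxt
        return bool(seen & set(clause_colors))

    hits = set()
    for term in catalog.terms():
        clauses = decompose(term, catalog)
        d = catalog.definitions[term]
        for c in clauses:
            if category in ("shape", "color", "size", "texture", "relative position"):
                if c.role != "shape-requirement":
                    continue
                ok = {
                    "shape": c.shape_kind == value,
                    "color": color_ok(c.color),
                    "size": c.size == value,
                    "texture": c.texture == value,
                    "relative position": c.relative_position == value,
                }[category]
            elif category == "relationship":
                ok = c.role == "shape-requirement" and c.relationship == value
            else:  # body position
                ok = (c.role == "body-position" and c.value == value) or d.body_position == value
            if ok:
                hits.add(term)
                break
    return hits


def all_single_constraint_queries():
    from vizonto.catalog import BODY_POSITIONS, RELATIONSHIPS, RELATIVE_POSITIONS
    from vizonto.model import SHAPE_KINDS, SIZES, TEXTURES
    from vizonto.palette import default_palette

    vocab = {
        "shape": SHAPE_KINDS,
        "color": tuple(default_palette()),
        "size": SIZES,
        "texture": TEXTURES,
        "relationship": RELATIONSHIPS,
        "relative position": RELATIVE_POSITIONS,
        "body position": BODY_POSITIONS,
    }
    for cat, values in vocab.items():
        for v in values:
            yield cat, v


def query_for(category, value, mode="subsumes"):
    field = {
        "shape": "shape",
        "color": "color",
        "size": "size",
        "texture": "texture",
        "relationship": "relationship",
        "relative position": "relative_position",
        "body position": "body_position",
    }[category]
    return FeatureQuery(**{field: value}, match_mode=mode)


class TestFindPatterns:
    def test_empty_query_matches_all(self, catalog):
        assert {t for t, _ in find_patterns(FeatureQuery(), catalog)} == set(catalog.terms())

    def test_equivalence_with_brute_force_scan(self, catalog):
        for cat, value in all_single_constraint_queries():
            got = {t for t, _ in find_patterns(query_for(cat, value), catalog)}
            expected = brute_force_terms(catalog, cat, value)
            assert got == expected, (cat, value)

    def test_dark_circles_walks_color_hierarchy(self, catalog):
        hits = {t for t, _ in find_patterns(FeatureQuery(shape="Circle", color="Dark"), catalog)}
        # Gray Brown / Brown circles are dark-colored circles
        assert "Annular Granular Pattern" in hits
        assert "Globules Regular" in hits
        # Rosettes are bright white circles: never dark
        assert "Rosettes" not in hits

    def test_white_lines_finds_shiny_white_streaks(self, catalog):
        hits = {t for t, _ in find_patterns(FeatureQuery(shape="Line", color="White"), catalog)}
        assert "Shiny White Streaks" in hits

    def test_exact_mode_does_not_subsume(self, catalog):
        subsumed = {t for t, _ in find_patterns(FeatureQuery(color="Dark"), catalog)}
        exact = {t for t, _ in find_patterns(FeatureQuery(color="Dark", match_mode="exact"), catalog)}
        assert exact <= subsumed
        assert "Annular Granular Pattern" in subsumed - exact

    def test_appearance_constraints_must_share_a_clause(self, catalog):
        # pigment network has pigmented lines and hypopigmented circles,
        # but no pigmented circle in any single clause
        hits = {t for t, _ in find_patterns(FeatureQuery(shape="Circle", color="Pigmented",
                                                         match_mode="exact"), catalog)}
        assert "Pigment Network" not in hits

    def test_monotonicity_adding_constraints_never_enlarges(self, catalog):
        base = {t for t, _ in find_patterns(FeatureQuery(shape="Circle"), catalog)}
        for extra in (FeatureQuery(shape="Circle", size="Small"),
                      FeatureQuery(shape="Circle", color="White"),
                      FeatureQuery(shape="Circle", relationship="Clustered")):
            assert {t for t, _ in find_patterns(extra, catalog)} <= base

    def test_deterministic_ordering(self, catalog):
        r1 = find_patterns(FeatureQuery(shape="Line"), catalog)
        r2 = find_patterns(FeatureQuery(shape="Line"), catalog)
        assert r1 == r2
        counts = [len(cs) for _, cs in r1]
        assert counts == sorted(counts, reverse=True) or all(
            c1 > c2 or (c1 == c2 and t1 < t2)
            for (t1, c1), (t2, c2) in zip(
                [(t, len(c)) for t, c in r1], [(t, len(c)) for t, c in r1][1:]
            )
        )

    def test_unknown_value_suggests(self, catalog):
        with pytest.raises(VocabularyError, match="did you mean"):
            find_patterns(FeatureQuery(color="Brwon"), catalog)


class TestFeaturesOf:
    def test_pseudopods_listing(self, catalog):
        f = features_of("Pseudopods", catalog)
        assert set(f["shape"]) == {"Circle", "Line"}
        assert f["relative position"] == ["Periphery"]
        assert f["relationship"] == ["Radial"]

    def test_rosettes_has_square_formation(self, catalog):
        assert features_of("Rosettes", catalog)["spatial pattern"] == ["SquareFormation"]

    def test_unknown_term_rejected(self, catalog):
        with pytest.raises(UnknownTermError):
            features_of("Leopard Print", catalog)

    def test_listing_is_deterministic(self, catalog):
        for term in catalog.terms():
            assert features_of(term, catalog) == features_of(term, catalog)


class TestParseQuery:
    def test_dark_circles(self):
        q = parse_query("dark circles")
        assert q.shape == "Circle" and q.color == "Dark"

    def test_white_lines(self):
        q = parse_query("white lines")
        assert q.shape == "Line" and q.color == "White"

    def test_alias_nouns_fold(self):
        assert parse_query("brown dots").shape == "Circle"
        assert parse_query("brown globules").shape == "Circle"

    def test_multiword_colors(self):
        assert parse_query("gray brown circles").color == "Gray Brown"

    def test_free_text_rejected_with_pointer_to_structured_form(self):
        with pytest.raises(ValidationError, match="structured"):
            parse_query("patterns suggestive of melanoma")
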