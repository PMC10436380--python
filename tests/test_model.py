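"""Typed visual-element model: colors, shapes, patterns, composition."""

import pytest
from hypothesis import given, strategies as st

from vizonto.errors import CardinalityError, CycleError, ValidationError, VocabularyError
from vizonto.model import (
    POLYGON_CARDINALITY,
    Visualization,
    elements_of,
    make_color,
    make_multicolor,
    make_pattern,
    make_shape,
    make_size,
    make_stroke,
    make_texture,
    point_cardinality,
    resolve_shape_alias,
)


class TestColor:
    def test_canonical_black(self):
        c = make_color("Black", (0, 0, 0), "#000000")
        assert c.rgb == (0, 0, 0) and c.hex == "#000000"

    def test_inconsistent_encodings_rejected(self):
        with pytest.raises(ValidationError, match="#00FF00"):
            make_color("X", (255, 0, 0), "#00FF00")

    @pytest.mark.parametrize("rgb,hex", [((256, 0, 0), "#FF0000"), ((0, 0, 0), "000000"), ((0, 0), "#000000")])
    def test_malformed_encodings_rejected(self, rgb, hex):
        with pytest.raises(ValidationError):
            make_color("X", rgb, hex)

    @given(st.tuples(st.integers(0, 255), st.integers(0, 255), st.integers(0, 255)))
    def test_hex_rgb_consistency_roundtrip(self, rgb):
        hex = "#{:02X}{:02X}{:02X}".format(*rgb)
        c = make_color("C", rgb, hex)
        assert tuple(int(c.hex[i : i + 2], 16) for i in (1, 3, 5)) == c.rgb

    def test_symbolic_color_carries_no_rgb(self):
        c = make_color("Pigmented", symbolic=True)
        assert c.symbolic and c.rgb is None


class TestMultiColor:
    def test_inverse_navigation(self):
        blue = make_color("Blue", (0, 0, 255), "#0000FF")
        gray = make_color("Gray", (128, 128, 128), "#808080")
        mc = make_multicolor([blue, gray])
        assert len(mc.components) == 2
        assert mc in blue.composed_of() and mc in gray.composed_of()

    def test_singleton_rejected(self):
        red = make_color("Red", (255, 0, 0), "#FF0000")
        with pytest.raises(ValidationError):
            make_multicolor([red])

    def test_duplicates_deduplicated_then_rejected(self):
        red = make_color("Red", (255, 0, 0), "#FF0000")
        with pytest.raises(ValidationError):
            make_multicolor([red, red])


class TestShape:
    def test_dot_is_a_small_circle(self):
        s = make_shape("dot", fill=make_color("Brown", (165, 42, 42), "#A52A2A"))
        assert s.shape_kind == "Circle" and s.size.value == "Small"

    @pytest.mark.parametrize("alias,kind,size", [
        ("dot", "Circle", "Small"),
        ("clod", "Circle", None),
        ("globule", "Circle", None),
        ("ellipse", "Circle", "Long"),
    ])
    def test_descriptive_aliases(self, alias, kind, size):
        assert resolve_shape_alias(alias) == (kind, size)

    def test_unqualified_line_is_straight(self):
        assert make_shape("Line").line_style == "Straight"

    def test_line_style_on_non_line_rejected(self):
        with pytest.raises(ValidationError):
            make_shape("Circle", line_style="Wavy")

    def test_polygon_cardinality_enforced(self):
        from vizonto.model import make_point

        pts3 = [make_point() for _ in range(3)]
        assert make_shape("Triangle", points=pts3).polygon_sides == 3
        with pytest.raises(CardinalityError):
            make_shape("Decagon", points=[make_point() for _ in range(9)])

    @pytest.mark.parametrize("kind,n", sorted(POLYGON_CARDINALITY.items()))
    def test_every_named_polygon_requires_exactly_its_count(self, kind, n):
        from vizonto.model import make_point

        assert make_shape(kind, points=[make_point() for _ in range(n)]).polygon_sides == n
        with pytest.raises(CardinalityError):
            make_shape(kind, points=[make_point() for _ in range(n + 1)])


class TestPointCardinality:
    def test_triangle_exactly_three(self):
        assert point_cardinality("Triangle") == 3

    def test_decagon_exactly_ten(self):
        assert point_cardinality("Decagon") == 10

    def test_circle_has_no_vertex_cardinality(self):
        with pytest.raises(VocabularyError):
            point_cardinality("Circle")


class TestModes:
    def test_shiny_texture_is_dermoscopy_only(self):
        assert make_texture("Shiny").value == "Shiny"
        with pytest.raises(VocabularyError):
            make_texture("Shiny", mode="base")

    def test_uniform_width_is_dermoscopy_only(self):
        assert make_stroke(qualitative_width="Uniform").qualitative_width == "Uniform"
        with pytest.raises(VocabularyError):
            make_stroke(qualitative_width="Variable", mode="base")

    def test_stroke_width_must_be_positive(self):
        with pytest.raises(ValidationError):
            make_stroke(width=0)


class TestPattern:
    def test_starburst_contains_subpattern(self):
        pseudopods = make_pattern("Pseudopods", shapes=[make_shape("Circle"), make_shape("Line")])
        starburst = make_pattern("Starburst Pattern", subpatterns=[pseudopods])
        assert pseudopods in starburst.subpatterns

    def test_empty_composite_rejected(self):
        with pytest.raises(ValidationError):
            make_pattern("P")

    def test_cycle_rejected(self):
        p1 = make_pattern("P1", shapes=[make_shape("Circle")])
        # simulate a self-referential composite via manual construction
        from vizonto.model import Pattern

        p2 = Pattern(name="P2", shapes=(), subpatterns=(p1,))
        bad = Pattern(name="P1", shapes=(), subpatterns=(p2,))
        with pytest.raises(CycleError):
            make_pattern("Root", subpatterns=[bad])

    def test_multiple_subpatterns_permitted(self):
        subs = [make_pattern(f"S{i}", shapes=[make_shape("Circle")]) for i in range(3)]
        assert len(make_pattern("Multi", subpatterns=subs).subpatterns) == 3


class TestVisualization:
    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            Visualization(elements=())

    def test_recursive_enumeration(self):
        p = make_pattern("P", shapes=[make_shape("Circle"), make_shape("Line")])
        v = Visualization(elements=(p,))
        elems = elements_of(v)
        assert len(elems) == 3 and elems[0] is p

    def test_enumeration_stable_and_idempotent(self):
        p = make_pattern(
            "P",
            shapes=[make_shape("Circle")],
            subpatterns=[make_pattern("Q", shapes=[make_shape("Line"), make_shape("Triangle")])],
        )
        v = Visualization(elements=(p, make_size("Small")))
        assert elements_of(v) == elements_of(v)
        assert len(elements_of(v)) == 6
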