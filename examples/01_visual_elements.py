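"""Build typed visual elements: colors, shapes, patterns.

The descriptive dermoscopy vocabulary reduces everything to a handful of
basic elements; a "dot" is nothing but a small circle, a "globule" a
circle, and named polygons carry exact vertex counts.
"""

from vizonto import (
    make_color,
    make_multicolor,
    make_pattern,
    make_shape,
    point_cardinality,
    resolve_shape_alias,
)

brown = make_color("Brown", (165, 42, 42), "#A52A2A")
blue = make_color("Blue", (0, 0, 255), "#0000FF")
white = make_color("White", (255, 255, 255), "#FFFFFF")

# "Blue White" as a mix of two colors, with inverse navigation
blue_white = make_multicolor([blue, white])
print(f"multi-color {blue_white.name!r} has {len(blue_white.components)} components;")
print(f"  Blue knows it belongs to {len(blue.composed_of())} multi-color(s)")

# a dot is a small circle
dot = make_shape("dot", fill=brown)
print(f"'dot' resolves to {resolve_shape_alias('dot')}: shape={dot.shape_kind}, size={dot.size.value}")

# exact polygon point cardinalities
for poly in ("Triangle", "Pentagon", "Decagon"):
    print(f"a {poly.lower()} has exactly {point_cardinality(poly)} points")

# patterns compose shapes and other patterns
pseudopods = make_pattern("Pseudopods", shapes=[make_shape("Circle"), make_shape("Line")])
starburst = make_pattern("Starburst Pattern", subpatterns=[pseudopods])
print(f"{starburst.name} contains the sub-pattern {starburst.subpatterns[0].name}")
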