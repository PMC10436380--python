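"""Synthetic scenes: render a pattern's clauses as geometry + SVG and
verify the clauses hold.

Scene generation is fully seeded, so (term, seed) pairs are
reproducible byte-for-byte; every generated configuration is checked
back through the spatial predicates.
"""

from vizonto import (
    SpatialConfig,
    parse_svg,
    render_scene,
    sample_relation_pair,
    spatial_predicate,
)

cfg = SpatialConfig()

scene, svg = render_scene("Pseudopods", seed=7)
print(f"Pseudopods scene: {len(scene.geometries)} geometries, SVG {len(svg)} bytes")
circles = {k: v for k, v in scene.geometries.items() if k.startswith("circle")}
lines = {k: v for k, v in scene.geometries.items() if k.startswith("line")}
meets = [spatial_predicate("spatialMeet", circles[f"circle{i}"], lines[f"line{i}"], cfg)
         for i in range(1, len(circles) + 1)]
print(f"each peripheral circle meets its radial line: {all(meets)}")

back = parse_svg(svg)
print(f"SVG round trip recovers {len(back)} geometries")

for relation in ("spatialMeet", "spatialInside", "spatialSurround"):
    a, b = sample_relation_pair(relation, seed=3)
    print(f"{relation}: generated pair verifies -> {spatial_predicate(relation, a, b, cfg)}")
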