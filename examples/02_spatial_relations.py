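"""Spatial predicates between plane geometries.

Each relation is decided from four boundary/interior intersection flags
(bb, ii, bi, ib): e.g. two shapes *meet* when only their boundaries
touch, and one is *inside* another when the interiors overlap and its
boundary runs through the other's interior without boundary contact.
"""

from vizonto import CircleGeom, classify, intersection_state, spatial_predicate

pairs = {
    "far apart": (CircleGeom((0, 0), 1), CircleGeom((5, 0), 1)),
    "externally tangent": (CircleGeom((0, 0), 1), CircleGeom((2, 0), 1)),
    "small inside big": (CircleGeom((0.5, 0), 1), CircleGeom((0, 0), 3)),
    "crossing": (CircleGeom((0, 0), 1), CircleGeom((1, 0), 1)),
    "identical": (CircleGeom((0, 0), 1), CircleGeom((0, 0), 1)),
}

for name, (a, b) in pairs.items():
    st = intersection_state(a, b, resolution=0.01, eps=0.02)
    preds = classify(a, b)
    print(f"{name:20s} flags(bb,ii,bi,ib)={st.as_tuple()}  ->  {preds}")

# the flags line up with the converse structure of the vocabulary
print("inside(a,b) == contains(b,a):",
      spatial_predicate("spatialInside", *pairs["small inside big"])
      == spatial_predicate("spatialContains", *pairs["small inside big"][::-1]))
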