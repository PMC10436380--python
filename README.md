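# vizonto

A visual-element ontology toolkit for dermoscopic terminology.

Dermoscopy — non-invasive, in-vivo imaging of skin lesions — carries two
competing vocabularies: a *metaphoric* terminology ("pigment network",
"pseudopods", "leaf-like areas") that is memorable but ambiguous, and a
*descriptive* terminology built from a handful of basic elements (lines,
circles, dots, clods, pseudopods, structureless areas). `vizonto` makes the
bridge between the two executable: every metaphoric pattern term is
decomposed into typed **visual elements** — shapes with color fill, stroke,
texture and size, arranged by spatial patterns and pairwise spatial
relationships — so that both clinicians and software agents can reason over
the same machine-readable definitions.

The toolkit is aimed at ontology engineers, dermatology informatics
researchers and anyone building image-analysis or education tools that need
standardized dermoscopic feature definitions.

## What is in the box

- **Typed domain model** (`vizonto.model`) — a visualization *VZ* is a
  composite of visual elements *VE* ∈ {S, T, C, P, SP, SK, PT, SR, SZ, PH}
  (shapes, textures, colors, patterns, spatial patterns, strokes, points,
  spatial relationships, sizes, paths), extended in dermoscopy mode by
  relative position (RP) and body position (BP). A shape *S* satisfies
  `hasColorFill(S, C) ∧ hasStroke(S, SK) ∧ hasVisualTexture(S, T) ∧
  hasSize(S, SZ)`; named polygons carry *exact* point cardinalities
  (a triangle exactly 3, a decagon exactly 10); a "dot" is a small circle.
- **Spatial calculus** (`vizonto.geometry`) — the nine predicate labels
  (`spatialDisjoint`, `spatialMeet`, `spatialOverlap`, `spatialEqual`,
  `spatialInside`/`spatialContains`, `spatialCoveredBy`/`spatialCovers`,
  `spatialSurround`) are decided from a four-flag abstraction of the
  DE-9IM intersection model — boundary∩boundary, interior∩interior,
  boundary∩interior and interior∩boundary, evaluated with an ε-tolerant
  boundary band by exhaustive grid sampling or an exactly-agreeing
  analytic shortcut.
- **Pattern catalog** (`vizonto.catalog`) — declarative clause sets for
  metaphoric terms ("interconnecting pigmented lines surrounding large
  hypopigmented circles"), six higher-level groups, alias resolution,
  strict YAML schema validation and a category-coverage audit.
- **OWL2 I/O** (`vizonto.owl_io` / `vizonto.ontology`) — two-layer
  export (the dermoscopy layer imports the base layer by IRI) in Turtle
  and RDF/XML with SKOS preferred/alternative labels; byte-stable
  round trips; entity counts and diffs.
- **Verbalizer** (`vizonto.verbalize`) — fixed-template English review
  sentences ("every ellipse is a shape") plus rater-agreement statistics
  over Y/N/X rating matrices (Y→1, N/X→0).
- **Semiotic metrics** (`vizonto.metrics`) — richness, lawfulness and
  comprehensiveness computed; clarity/consistency/interpretability
  accepted as external leaves; weighted-mean composites and
  cross-ontology z-scores (sample sd).
- **Query engine** (`vizonto.query`) — "dark circles" / "white lines"
  style feature queries with color-hierarchy subsumption.
- **Synthetic scenes** (`vizonto.scenes`) — seeded geometric
  instantiations of catalog terms, self-verified against the spatial
  predicates, with SVG round trips.

## Worked example

```python
>>> from vizonto import shipped_catalog, decompose, FeatureQuery, find_patterns
>>> catalog = shipped_catalog()
>>> for c in decompose("Pigment Network", catalog):
...     print(c.role, c.shape_kind or f"{c.subject} {c.predicate} {c.object}")
shape-requirement Line
shape-requirement Circle
relation-assertion Line spatialSurround Circle
>>> [t for t, _ in find_patterns(FeatureQuery(shape="Circle", color="Dark"), catalog)]
['Annular Granular Pattern', 'Globules Regular', 'Rim of Brown Globules']
```

The pigment network decomposes into interconnecting pigmented lines plus
large hypopigmented circles, with the lines *surrounding* the circles; the
"dark circles" query walks the color hierarchy (Dark ⊒ Brown, Gray Brown,
Black, ...) and returns the three shipped terms whose clauses contain a
dark-colored circle.

Spatial semantics are geometric, not symbolic:

```python
>>> from vizonto import CircleGeom, classify
>>> classify(CircleGeom((0, 0), 1), CircleGeom((2, 0), 1))
['spatialMeet']
>>> classify(CircleGeom((0.5, 0), 1), CircleGeom((0, 0), 3))
['spatialInside']
```

The `examples/` directory holds one short narrative script per
capability (run them with `python examples/01_visual_elements.py` etc.),
and the `vizonto` console script exposes the same operations from the
shell (`vizonto query --shape Circle --color Dark`,
`vizonto render Pseudopods --seed 7`, `vizonto owl export`, ...).

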