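# Methods

This note records the models, conventions and numerical choices behind
`vizonto`, and what the test suite does and does not establish.

## The two-layer element model

The model treats every visualization as a non-empty composite of typed
visual elements. The *base* layer carries the generic vocabulary:
shapes (circle, ellipse, line, polygon, polyline, rectangle, path,
structureless), colors with paired RGB/hex encodings, multi-colors
(≥ 2 distinct components with inverse navigation from each component),
strokes (integer relative width ≥ 1 plus a qualitative category),
perceived visual textures, sizes, points with begin/middle/end roles and
spatial patterns. The *dermoscopy* layer extends it with vocabulary the
skin-lesion domain needs: shiny texture (milia-like cysts), uniform and
variable stroke widths (typical vs atypical pigment networks), the
skin-relative colors (pigmented, hypopigmented, non-pigmented, dark),
polygon/square/leaf-like formations, the twelve arrangement
relationships, relative position within the lesion and body position
(face, volar). Constructors take a `mode` argument; `"base"` rejects
dermoscopy-only values so documents can be validated against either
layer.

Decisions worth calling out:

- **Aliases, not classes.** "Dot" (= small circle), "clod", "globule"
  (= circle) and "ellipse" (= elongated circle) are resolved to
  circle-based shapes and kept as alternative labels. The circle concept
  is deliberately loose — a rounded shape that need not have uniform
  radius — because no real lesion is a perfect circle.
- **Exact polygon cardinalities.** A named polygon (triangle … decagon)
  has *exactly* its defining number of points, enforced at construction
  and encoded as exact qualified cardinality in OWL. A "max N" reading
  would admit degenerate polygons.
- **Patterns are DAGs.** A pattern may contain any number of
  sub-patterns (`hasPattern` is not functional), but never itself,
  directly or transitively; registration runs a cycle check.
- **Uniform/Variable color.** The color inventory lists Uniform and
  Variable alongside real colors; they are modeled as symbolic colors
  with a qualifier flag because they describe a *collection* of
  elements, not a hue. The same reading applies to Uniform/Variable
  size. This is an interpretation choice; the source material is
  ambiguous here.
- **Medium width** exists in the base layer's width categories; the
  dermoscopy layer's own definitions only ever use Thin/Thick plus
  Uniform/Variable, but Medium is not rejected in dermoscopy mode.
- Coordinates are dimensionless 2-D, x rightward, y downward (SVG
  convention), since the whole element vocabulary is SVG-informed.

## Spatial semantics

Spatial predicates are decided from four boundary/interior intersection
flags (a four-flag abstraction of DE-9IM, without per-cell dimension
values): `bb` (boundaries share points), `ii` (interiors share points),
`bi` (A's boundary meets B's interior), `ib` (A's interior meets B's
boundary). The truth table is:

| predicate        | condition              |
|------------------|------------------------|
| spatialDisjoint  | ¬bb ∧ ¬ii ∧ ¬bi ∧ ¬ib  |
| spatialOverlap   | bb ∧ ii ∧ bi ∧ ib      |
| spatialMeet      | bb ∧ ¬ii ∧ ¬bi ∧ ¬ib   |
| spatialEqual     | bb ∧ ii ∧ ¬bi ∧ ¬ib    |
| spatialInside    | ii ∧ bi ∧ ¬bb          |
| spatialContains  | ii ∧ ib ∧ ¬bb          |
| spatialCoveredBy | bb ∧ ii ∧ bi           |
| spatialCovers    | bb ∧ ii ∧ ib           |

The table is built so the converse pairs hold structurally:
inside(a, b) ⇔ contains(b, a) and coveredBy(a, b) ⇔ covers(b, a). Note
two deliberate deviations from textbook DE-9IM, both documented rather
than hidden: the overlap definition demands *all four* properties
(standard "overlaps" does not require boundary-boundary contact — with
the ε-band below the two rarely differ in practice), and equality is
ε-tolerant (two boundaries within ε count as shared). A `strict=True`
config delegates to shapely's exact DE-9IM predicates for comparison.

`spatialSurround` has no flag characterization; the toolkit defines it
as: A (possibly a composite of several geometries, e.g. the line
segments of a network) surrounds B iff B lies inside the convex hull of
A's components and A and B share no interior.

**Evaluation.** Boundaries are fattened into an ε-band (default
ε = 2 × grid resolution; resolution defaults to 0.01 scene units): a
query point within ε of the topological boundary is *boundary*, inside
but outside the band is *interior*. For curves (segments, polylines)
the topological boundary is the endpoint set; a closed polyline has
none. The normative evaluation samples the joint bounding box (expanded
by 2ε) exhaustively on a deterministic row-major grid. The analytic
shortcut intersects the very same ε-band regions with exact set
operations and, for borderline slivers thinner than a grid cell, tests
the actual grid points inside the sliver — so it agrees with sampling
by construction rather than by luck. Geometries smaller than twice the
resolution are rejected as degenerate. Tangency detection necessarily
depends on ε; both are configurable.

## Pattern catalog

Each metaphoric term is a set of clauses: shape requirements (kind,
acceptable colors, size, texture, stroke, relative position,
arrangement relationship), sub-pattern references (expanded recursively
and cycle-safely on decomposition; `expand: false` keeps the
reference), pairwise relation assertions over the spatial vocabulary,
an overall spatial pattern, a body position and free-text annotations.
Non-visual facts (e.g. that shiny white structures and the rainbow
pattern are seen under polarized light) live *only* in annotations.

The shipped catalog contains the terms whose decompositions the
published consensus descriptions fix (pseudopods: peripheral circles
meeting radial lines; pigment network: interconnecting pigmented lines
surrounding large hypopigmented circles; rosettes: bright white circles
in square formation; etc.) plus the remaining members of the six
higher-level groups — Blotch (2), Globules (4), Dots (2), Streaks (3),
Shiny White Structures (3), Network (2). Definitions that are only
*named*, not spelled out, in the source material follow their group's
stated structure and carry a `provisional` annotation. Stroke appears
only in the pigment-network definitions (uniform vs variable width),
reflecting reviewer feedback that outlines describe lesion demarcation
poorly. The category-coverage audit uses the fixed inventory {shape,
color, size, texture, spatial relationship, relative position, body
position} in that order, so reports are deterministic.

Grey-brown is included for the annular granular pattern and "skin
lines" for the ridge pattern (volar body position), both following
expert-reviewer corrections to the original definitions. The leaf-like
arrangement is modeled as a spatial pattern, not a standalone term.

## OWL2 serialization

One namespace per layer, fragment = CamelCase label, SKOS
`prefLabel`/`altLabel` for names. Restriction nodes are *skolemized*
with deterministic fragment IRIs instead of blank nodes: rdflib assigns
fresh blank-node labels on every parse, which would break the
export → import → export byte-identity the toolkit guarantees. Data
properties have typed numeric ranges (`xsd:integer` for stroke-width
and RGB channels), never plain literals. Unrecognized triples parsed
from foreign documents are preserved verbatim and re-emitted. No
reasoner is bundled; `check_consistency` covers structural clashes
(conflicting cardinalities, subclass cycles) and full DL checking is
left to an external reasoner run on the exported document.

## Verbalization and agreement

Templates are fixed and lower-case ("every ellipse is a shape", "every
decagon is something that has exactly 10 points"); identical axioms
always yield identical sentences. Ratings are Y/N/X; recoding maps Y→1
and both N and X→0 on the reasoning that an unclear axiom cannot be
counted as correct. Mean agreement is the unweighted mean of per-rater
proportions of 1s. Pairwise agreement is simple percent agreement
(not chance-corrected kappa) averaged over rater pairs, computed on
recoded values by default; a raw mode distinguishes N from X because it
is not recorded which convention the original computation used.
Contested statements are those with at least a threshold (default 2)
number of recoded zeros.

## Semiotic metrics

Richness = |distinct OWL2 construct kinds used| / |fixed 16-kind
inventory|. Lawfulness = 1 − violating statements / total statements
(clean parse ⇒ 1; empty document ⇒ 1 by convention; for Turtle a failed
strict parse falls back to statement-by-statement counting).
Comprehensiveness = element count / maximum element count in the
comparison corpus including the ontology itself. Clarity, consistency
and interpretability require an external word-sense inventory; they are
accepted from leaf-score CSVs behind a `LexicalOracle` interface whose
default stub refuses to score — recomputing them is explicitly out of
scope. Composites are weighted means, uniform by default. The uniform
mean reproduces all four published syntactic composites exactly; the
published semantic and overall composites deviate slightly from uniform
means of their printed leaves (0.986 vs 0.984, 0.597 vs 0.596), so the
weights are configurable and semantic/overall reproduction is treated
as approximate rather than guessed at. Z-scores use the sample standard
deviation (n − 1); display rounding is half-to-even on the decimal
value, with raw values retained internally.

## Query engine

A query is a conjunction over {shape, color, size, texture,
relationship, relative position, body position}. Appearance constraints
(shape, color, size, texture, relative position) must be co-satisfied
by a *single* shape clause — a "dark circle" is one clause that is both
dark and a circle — while relationship and body position may be
satisfied anywhere in the expanded clause set. `subsumes` mode walks
the color hierarchy downward (Dark ⊒ Black, Brown, Gray Brown, Light
Brown, Blue Gray, Indigo; Pigmented and Hypopigmented similarly); the
mapping from skin-relative categories to absolute colors is a pragmatic
toolkit reading, since those categories are defined relative to the
individual's skin tone. Result order is matched-clause count
descending, then term ascending. Free text is parsed only by the fixed
"color-adjective + shape-noun" grammar with plural folding; anything
richer must be a structured query (no NLP is attempted). Disease
association queries are out of scope: the catalog carries no disease
links.

## Synthetic scenes

The generator emulates the *geometric skeleton* of dermoscopic
patterns on the unit canvas: placement honors the clauses (periphery =
centroid further than 0.35 from the canvas center, center = closer
than 0.15; small/large circle radii 0.03/0.12, default 0.06; radial,
parallel, orthogonal and grid line arrangements; square formations;
square frames of segments realizing surround assertions; radial spokes
stopping ε/2 short of their tip circles so the meet stays robustly
inside the boundary band). It does **not** emulate photographic
realism: no texture, no color calibration, no irregular lesion
outlines, no noise. Passing generator–checker tests therefore shows
that the spatial calculus and the catalog semantics cohere, not that
the toolkit recognizes real dermoscopic images. Structureless areas
have no geometric realization and are rejected explicitly. All
randomness flows through `numpy.random.default_rng` seeded with
(seed, CRC32(term)), so identical (term, seed) pairs give identical
SVG bytes.

## Problem sizes and test design

The suites use the sizes the properties call for: 200 random
circle/polygon pairs for grid-vs-analytic oracle agreement (resolution
0.01 of the scene diameter), 20 seeds per relation for the
generator–checker closure, all shipped fixtures for OWL round trips,
and every single-constraint query over every vocabulary value for the
query/brute-force equivalence. The whole suite runs in a few seconds
on one CPU. The rater-agreement arithmetic is exercised on a synthetic
100-statement matrix with per-rater endorsement proportions planted at
the published study's values (0.90/0.63/0.92); the original
182-statement annotation data are not published, so the exact pairwise
agreement figure (72.9%) and contested-statement list are outside what
any re-implementation can verify, and are not asserted.

## Known limitations

- The shipped catalog covers the terms whose decompositions are
  printed in the consensus-based descriptions; the full 48-term
  inventory loads from a user-supplied YAML catalog (the loader is
  format-complete without it). Vessel patterns are absent entirely.
- Skin-tone dependence of color categories (e.g. blue-white veil on
  dark skin) is noted in annotations but not modeled.
- `spatialSurround` is a toolkit definition; the name exists in the
  spatial vocabulary without a published formal semantics.
- The entity counts of the released ontology file (1047 classes / 47
  object properties / 16 data properties) require the public download
  and are not reproduced by the shipped two-layer model, which is a
  compact re-encoding rather than a copy.
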