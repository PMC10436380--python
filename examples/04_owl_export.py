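"""OWL2 serialization: export both ontology layers, count entities,
round-trip through Turtle.

The dermoscopy layer imports the base visual-element layer by IRI; all
labels travel as SKOS preferred/alternative labels and polygon point
counts are exact qualified cardinalities.
"""

from vizonto import base_model, dermoscopy_model, entity_counts, export_owl, import_owl
from vizonto.owl_io import axiom_equivalent

base = base_model()
derm = dermoscopy_model()

for name, model in (("base layer", base), ("dermoscopy layer", derm)):
    c, o, d = entity_counts(model)
    print(f"{name}: {c} classes, {o} object properties, {d} data properties")

c, o, d = entity_counts(derm, include_imports=True, imported=[base])
print(f"with import closure: {c} classes, {o} object properties, {d} data properties")

turtle = export_owl(derm, "turtle")
print(f"\nturtle export: {len(turtle)} bytes; imports -> {derm.imports}")

back = import_owl(turtle)
print("import(export(m)) axiom-equivalent:", axiom_equivalent(derm, back))
print("re-export byte-identical:", export_owl(back, "turtle") == turtle)
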