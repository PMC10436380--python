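"""Feature queries over the catalog: "dark circles", "white lines".

The subsumes match mode walks the color hierarchy (Dark covers Black,
Brown, Gray Brown, ...), so a query for dark circles finds every term
whose clauses contain a dark-colored circle.
"""

from vizonto import FeatureQuery, features_of, find_patterns, parse_query, shipped_catalog

catalog = shipped_catalog()

for text in ("dark circles", "white lines"):
    q = parse_query(text)
    hits = find_patterns(q, catalog)
    print(f"{text!r} -> {q.shape} + {q.color}: {[t for t, _ in hits]}")

q = FeatureQuery(relationship="Radial")
print("\nradial arrangements:", [t for t, _ in find_patterns(q, catalog)])

print("\nfeature listing for Pseudopods:")
for category, values in features_of("Pseudopods", catalog).items():
    print(f"  {category}: {', '.join(values)}")
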