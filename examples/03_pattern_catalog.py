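"""The metaphoric-pattern catalog: decomposition, groups, coverage audit.

Every metaphoric dermoscopic term is decomposed into clauses over the
visual-element vocabulary; similar terms are grouped into higher-level
patterns; the audit lists, per feature category, the terms still lacking
a clause for it (a consistency guide for catalog authors).
"""

from vizonto import audit_category_coverage, decompose, groups, shipped_catalog

catalog = shipped_catalog()
print(f"shipped catalog: {len(catalog)} terms\n")

print("higher-level groups:")
for group, members in groups(catalog).items():
    print(f"  {group}: {', '.join(members)}")

print("\nPigment Network decomposes into:")
for clause in decompose("Pigment Network", catalog):
    if clause.role == "shape-requirement":
        bits = [clause.shape_kind] + list(clause.color)
        bits += [x for x in (clause.size, clause.relationship, clause.relative_position) if x]
        print(f"  shape: {' / '.join(bits)}")
    elif clause.role == "relation-assertion":
        print(f"  relation: {clause.subject} {clause.predicate} {clause.object}")

report = audit_category_coverage(catalog)
print("\ncoverage audit (terms still missing a category):")
for category, missing in report.items():
    print(f"  {category}: {len(missing)} terms")
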