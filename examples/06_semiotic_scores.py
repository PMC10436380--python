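"""Semiotic quality scoring and cross-ontology comparison.

Leaf scores (two computable here, three supplied externally) aggregate
into syntactic / semantic / pragmatic composites and an overall score;
z-scores locate each ontology within the comparison corpus.
"""

import pandas as pd

from vizonto import base_model, dermoscopy_model, richness
from vizonto.metrics import comprehensiveness, element_count, score_report

# computable leaves for the shipped model
derm = dermoscopy_model()
print(f"dermoscopy layer richness: {richness(derm):.3f}")
print(f"element count: {element_count(derm)}; vs a 1000-element corpus peak:",
      f"comprehensiveness {comprehensiveness(derm, [1000]):.3f}")

# published comparison table of four dermatology ontologies (leaf scores
# as inputs; composites and z-scores recomputed)
leaves = pd.DataFrame.from_dict(
    {
        "DEVO": dict(richness=0.564, lawfulness=1.0, clarity=0.988, consistency=1.0,
                     interpretability=0.964, comprehensiveness=0.02),
        "DL": dict(richness=0.333, lawfulness=0.501, clarity=0.999, consistency=0.0004,
                   interpretability=1.0, comprehensiveness=0.22),
        "HDDO": dict(richness=0.154, lawfulness=1.0, clarity=0.998, consistency=0.934,
                     interpretability=0.901, comprehensiveness=0.065),
        "SPO": dict(richness=0.385, lawfulness=1.0, clarity=0.983, consistency=0.981,
                    interpretability=0.575, comprehensiveness=0.006),
    },
    orient="index",
)
report = score_report(leaves)
print("\ncomposites and z-scores:")
print(report[["syntactic", "semantic", "pragmatic", "overall", "z_overall"]])
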