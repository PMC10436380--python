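"""Verbalize axioms for expert review and score a rating matrix.

Axioms become fixed-template English sentences reviewers mark Y/N/X;
X (not sure) recodes to 0 alongside N, so the per-rater proportion of
1s measures how much encoded knowledge each reviewer endorses.
"""

import numpy as np
import pandas as pd

from vizonto import agreement_stats, base_model, contested_statements, verbalize_model

statements = verbalize_model(base_model())
print(f"{len(statements)} review sentences, e.g.:")
for s in statements[:3]:
    print(f"  - {s.sentence}")
exact = next(s for s in statements if "exactly 10" in s.sentence)
print(f"  - {exact.sentence}")

# a synthetic review: three raters endorsing 90% / 63% / 92% of statements
rng = np.random.default_rng(0)
n = 100
cols = {}
for j, p in enumerate((0.90, 0.63, 0.92)):
    ones = int(round(p * n))
    col = np.array(["Y"] * ones + ["N"] * ((n - ones) // 2) + ["X"] * (n - ones - (n - ones) // 2))
    rng.shuffle(col)
    cols[f"rater{j + 1}"] = col
matrix = pd.DataFrame(cols)

stats = agreement_stats(matrix)
print("\nper-rater endorsement:", {k: round(v, 2) for k, v in stats["per_rater"].items()})
print("mean agreement:       ", round(stats["mean_agreement"], 2))
print("pairwise agreement:   ", round(stats["pairwise_percent_agreement"], 3))
print("contested statements (>=2 negatives):", len(contested_statements(matrix, threshold=2)))
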