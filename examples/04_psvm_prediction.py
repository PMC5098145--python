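"""Personalized risk prediction by signature-vector matching (PSVM).

Trains the weighted-voting stratifier on one synthetic cohort, encodes
every patient as a rank-weighted prognostic signature vector (PSV), and
assigns each held-out patient the risk class of its Euclidean-nearest
training patient.
"""

import numpy as np

from prognosig import (
    build_reference_psvs,
    fit_swvg,
    predict_psvm,
    simulate_cohort,
    three_class_spec,
)

train = simulate_cohort(three_class_spec(seed=8))
model, awr, classes = fit_swvg(train.expression, train.survival, scheme="C")
references = build_reference_psvs(model, train.expression)

test = simulate_cohort(three_class_spec(seed=9, n_patients=150))
matches = [
    predict_psvm(test.expression[c].to_numpy(), model, references, classes, query_id=c)
    for c in test.expression.columns
]

print("first five query patients:")
for m in matches[:5]:
    print(f"  {m.query_id} -> nearest reference {m.reference_id} "
          f"(distance {m.distance:.1f}) -> predicted {m.predicted_class}")
agree = np.mean([int(m.predicted_class) for m in matches] == test.classes)
print(f"\nagreement with the planted risk classes: {agree:.1%} of 150 held-out patients")
print("Distances are in rank units: disagreeing on a heavily weighted")
print("variable separates two patients more than disagreeing on a marginal one.")
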