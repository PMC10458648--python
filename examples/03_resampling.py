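"""Treat a severely imbalanced feature table with the five SMOTE-family plans.

Reproduces the qualitative count patterns: equalized classes for
SMOTE-Tomek / Borderline-SMOTE / SMOTE-NC, approximately equal for ADASYN,
and deliberately unequal (with a shrunken majority) for SMOTE-ENN.
"""

from lodgetex import generate_feature_table
from lodgetex.resample import METHODS, ResamplePlan, apply_resample
from lodgetex.synth import gaussian_table_spec

means, covs = gaussian_table_spec(m=12, separation=2.0)
table = generate_feature_table(
    {"NL": 964, "ML": 206, "HL": 85, "SL": 11}, means, covs, seed=1
)
print("original:", table.class_counts())
for method in METHODS:
    out = apply_resample(table, ResamplePlan(method, seed=1))
    n_syn = int((out.provenance == "synthetic").sum())
    print(f"{method:17s} {out.class_counts()}  (+{n_syn} synthetic rows)")

# SMOTE-ENN removes boundary samples from every class after oversampling, so
# its counts stay unequal; the other oversamplers target the majority count.
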