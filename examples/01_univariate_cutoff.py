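"""Fit a univariate optimal-cutoff survival classifier (1D-DDg).

Simulates a 200-patient cohort in which the death hazard doubles once a
variable exceeds 5.0, then scans every admissible cutoff and keeps the
one whose binary Cox-Wald p-value is smallest.
"""

import numpy as np

from prognosig import SimSpec, fit_1d_ddg, simulate_cohort

spec = SimSpec(
    n_patients=200, n_variables=1, seed=7,
    cutoffs=5.0, designs=2, log_hrs=np.log(2.0), censoring_rate=0.003,
)
cohort = simulate_cohort(spec)
model = fit_1d_ddg(cohort.expression.iloc[0].to_numpy(), cohort.survival, variable_id="var1")

print(f"planted cutoff      : 5.0 (hazard x2 above it)")
print(f"recovered cutoff    : {model.cutoff:.3f}")
print(f"design              : {model.design} ({model.behaviour})")
print(f"hazard ratio        : {model.hazard_ratio:.2f} (high- vs low-risk group)")
print(f"Wald p              : {model.wald_p:.2e}")
print(f"subgroup sizes      : {model.n_low_risk} low risk / {model.n_high_risk} high risk")
print()
print("The cutoff lands near the planted change point; design 2 means")
print("high values carry the risk, and the HR estimates the planted 2x hazard.")
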