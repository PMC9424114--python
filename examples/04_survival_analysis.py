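"""Survival analysis of a synthetic cohort.

Simulates a clinical cohort under proportional hazards (immune features at
their configured prevalences and multivariable effects), constructs the
5-year relapse-free-survival endpoint with the cohort filters, and fits
the stratified multivariable Cox model plus the bootstrap
variable-retention procedure.
"""

import numpy as np

import tregspatial as ts
from tregspatial.outcome import (
    apply_cohort_filters,
    bootstrap_selection,
    cox_fit,
    km_estimate,
    survival_frame,
)

config = ts.SyntheticConfig(n_patients=1700, seed=8)
records, features = ts.generate_cohort(config)
endpoints = apply_cohort_filters(records, "RFS5")
frame = survival_frame(endpoints, features)

n_excluded = sum(not e.inclusion for e in endpoints)
print(f"{len(records)} patients generated, {n_excluded} excluded by the "
      f"cohort filters, {len(frame)} analyzed, {int(frame['event'].sum())} events")

for level in (True, False):
    sub = frame[frame["mean_cd25_high"] == float(level)]
    _, s60 = km_estimate(sub["time"], sub["event"])
    label = "High" if level else "Low/Negative"
    print(f"mean-CD25 {label}: n={len(sub)}, 5-year RFS = {s60:.3f}")

table, diag = cox_fit(frame)
print(f"\nmultivariable Cox (stratified by cohort), "
      f"c-index {diag['concordance']:.3f}:")
print(table.round(3).to_string(index=False))

retained, freq = bootstrap_selection(
    frame, ["ieCD8_high", "mean_cd25_high", "proximity_significant", "msi", "age"],
    B=60, seed=1)
print("\nbootstrap retention frequencies (retained at >= 30%):")
print(freq.round(2).to_string())
print("retained:", retained)
# The simulated truth puts HR 0.62 on high intraepithelial CD8, 1.35 on the
# mean-CD25-High class and 1.36 on significant CD8/tp-Treg proximity; the
# fitted HRs should straddle those values within sampling error.
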