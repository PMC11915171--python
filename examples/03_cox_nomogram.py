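"""Fit a Cox model, build the 0-100 point nomogram, stratify risk groups.

Reproduces the classical workflow: multivariate Cox fit on the five
retained risk factors, nomogram point table, total-score risk split, and
the log-rank comparison of the resulting Kaplan-Meier curves.
"""

import numpy as np

from opmdml import (
    DEFAULT_SCHEMA,
    cox_fit,
    default_cohort_spec,
    generate_cohort,
    logrank,
    nomogram_from_cox,
    one_hot_encode,
    risk_group_split,
)

cohort = generate_cohort(default_cohort_spec(n=681, seed=0))
schema = DEFAULT_SCHEMA.subset(
    ["lesion_type", "subtype", "site", "oed_first", "oed_followup"])
X = one_hot_encode(cohort, schema, drop_reference=True)
time = np.array([r.time_years for r in cohort])
event = np.array([r.mt_event for r in cohort])

model = cox_fit(X, time, event)
lo, hi = model.confidence_intervals()
print(f"{'factor':22s}{'HR':>8s}{'95% CI':>18s}{'p':>9s}")
for name, hr, l, h, p in zip(model.column_names, model.hazard_ratios,
                             lo, hi, model.p_values()):
    print(f"{name:22s}{hr:8.3f}   ({l:6.3f},{h:7.3f}){p:9.4f}")

nomo = nomogram_from_cox(model, schema)
print("\nnomogram points (widest-range factor spans 0-100):")
for variable, table in nomo.points.items():
    levels = ", ".join(f"{lv}={pts:.0f}" for lv, pts in table.items())
    print(f"  {variable:14s}{levels}")

groups = risk_group_split(nomo, cohort, cutoff_points=113.0)
t_lo = np.array([r.time_years for r in groups["low"]])
e_lo = np.array([r.mt_event for r in groups["low"]])
t_hi = np.array([r.time_years for r in groups["high"]])
e_hi = np.array([r.mt_event for r in groups["high"]])
chi2, p = logrank(t_lo, e_lo, t_hi, e_hi)
print(f"\nrisk split at 113 points: low n={len(t_lo)} "
      f"(MT {e_lo.mean():.1%}), high n={len(t_hi)} (MT {e_hi.mean():.1%})")
print(f"log-rank chi2 = {chi2:.1f}, p = {p:.3g}")
# A large chi-square / tiny p confirms the two nomogram strata have
# clearly separated transformation-free survival.
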