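"""Generate a synthetic OPMD cohort and tabulate it.

Draws a 681-subject cohort under the default study conditions (published
marginal frequencies, multivariate hazard ratios, 6.6% expected event
fraction over 20 years) and prints the per-variable malignant-
transformation (MT) rates, next to the analytic expectation.
"""

from opmdml import (
    default_cohort_spec,
    expected_event_fraction,
    generate_cohort,
    summarize_cohort,
)

spec = default_cohort_spec(n=681, seed=0)
cohort = generate_cohort(spec)
summary = summarize_cohort(cohort)

print(f"cohort size          : {summary['n']}")
print(f"observed MT rate     : {summary['mt_rate_percent']:.3f}%")
print(f"analytic expectation : {100 * expected_event_fraction(spec):.3f}%")
print()
print(f"{'variable':24s}{'level':12s}{'n':>6s}{'MT':>5s}{'rate %':>8s}")
for variable in ("lesion_type", "subtype", "site", "oed_first", "oed_followup"):
    for level, cell in summary["variables"][variable].items():
        if cell["n"]:
            print(f"{variable:24s}{level:12s}{cell['n']:>6d}{cell['mt']:>5d}"
                  f"{cell['mt_rate_percent']:>8.1f}")

# The stratum rates mirror the hazard structure: tongue lesions and OED
# during follow-up carry the largest hazard ratios, so their observed MT
# percentages sit well above the ~6.6% cohort average.
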