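"""Generate a synthetic paired-database diary cohort and summarize it.

Builds the default 50-participant, two-phase, 4-day cohort, then prints
per-nutrient daily means for both databases and the count of planted
anomalies.  App means below the reference means reflect the configured
under-reporting bias and missingness (strongest for cholesterol/sodium).
"""

from nutripair import SyntheticConfig, aggregate_daily_means, audit_log, generate_cohort
from nutripair.nutrients import NUTRIENTS, UNITS, app_col, ref_col

cohort = generate_cohort(SyntheticConfig(seed=2))
log = audit_log(cohort)
daily = aggregate_daily_means(cohort, "T1")

print(f"{len(cohort)} food items across {daily.shape[0]} participants, 2 phases")
print(f"planted anomalies: {log['kind'].value_counts().to_dict()}")
print(f"\n{'nutrient':14s} {'unit':8s} {'ref mean':>9s} {'app mean':>9s}")
for n in NUTRIENTS:
    print(
        f"{n.value:14s} {UNITS[n] + '/day':8s} "
        f"{daily[ref_col(n)].mean():9.1f} {daily[app_col(n)].mean():9.1f}"
    )
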