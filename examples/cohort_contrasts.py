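"""Cohort contrast tables on a simulated two-group cohort.

Simulates unconscious (UWS-like) and minimally conscious (MCS/EMCS-like)
patients, analyses both the uncorrected and corrected datasets and prints the
paired corrected-vs-uncorrected table plus day/night results.
"""

from actirhythm import (
    build_contrast_tables,
    correct_series,
    default_cohort_config,
    generate_cohort,
    summarize_series,
)

patients, cohort = generate_cohort(default_cohort_config(4, 4, days=4), seed=11)

summ_u, summ_c = {}, {}
for p in patients:
    pid = p.recorded.patient_id
    summ_u[pid] = summarize_series(p.recorded)
    summ_c[pid] = summarize_series(correct_series(p.recorded, p.log).series)

tables = build_contrast_tables(summ_c, summ_u, cohort)

cols = ["metric", "z", "p", "r", "effect", "median_corrected", "median_uncorrected"]
print("corrected vs uncorrected (Wilcoxon signed-rank):")
print(tables.paired_datasets[cols].round(3).to_string(index=False))
print()
print("circadian classification per dataset:")
print(tables.circadian_counts.round(1).to_string(index=False))
# Positive bias shows as higher uncorrected medians for IS and a higher
# uncorrected circadian percentage even in this entrained 24-h cohort.
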