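"""Cohort characteristics and the annual reporting trend.

Summarizes the built-in reference cohort (19,630 montelukast primary-suspect
reports with demographics, 2004-2023Q3 profile): counts and exact half-up
percentages by sex, age bin, country, serious outcome and reporter, plus the
peak reporting year.
"""

import pvsignal as pv

cohort = pv.build_reference_cohort()
summary = pv.summarize_cohort(cohort)

print(f"number of events: {summary.n_events}")
for section in ("sex", "age", "outcomes", "reporter"):
    table = getattr(summary, section)
    pcts = summary.percentages(section)
    line = ", ".join(f"{k} {table[k]} ({pcts[k]:.2f}%)" for k in table)
    print(f"{section}: {line}")
print("top countries:", summary.top_countries(5))

trend = pv.annual_trend(cohort)
print(f"peak year: {trend.peak_year} with {trend.peak_count} reports "
      f"({trend.peak_share_pct:.2f}% of all)")
# Serious-outcome percentages use the full cohort as denominator and are not
# mutually exclusive, so they need not sum to 100.
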