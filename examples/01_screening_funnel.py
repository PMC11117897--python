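"""Screening funnel: stratify a cohort by the two Phen1 inclusion criteria.

Builds the deterministic study-funnel cohort (313 screened records) and
classifies it: documented head circumference, HC >= 75th percentile within
the first 24 months, flare assessability, and at least one immune-challenge
flare. Prints the funnel counts and the observed prevalence.
"""

import endophen as ep

cohort = ep.fixture_cohort(seed=0)
res = ep.classify_cohort(cohort)

print(f"screened:                {res.n_screened}")
print(f"documented HC:           {res.n_documented_hc} ({res.pct_documented:.1f}%)")
print(f"HC >= 75th percentile:   {res.n_hc_ge75} ({res.pct_hc_ge75:.1f}%)")
print(f"flare-assessable HC>=75: {res.n_flare_assessable_hc75}")
print(f"Phen1:                   {res.n_phen1}")
print(f"both criteria assessable: {res.n_both_assessable}")
print(f"prevalence: {100 * res.prevalence:.1f}%")
# The prevalence denominator is every patient with both criteria assessable:
# 41 flare-assessable HC>=75 patients plus 43 documented HC<75 patients.

# Comparison (non-Phen1) patients are drawn with an even spread of maximum
# HC percentile across the three lower terciles:
chosen = ep.select_non_phen1(cohort, n=9, seed=0)
print(f"\nselected {len(chosen)} non-Phen1 comparison patients, "
      f"max HC percentiles: {sorted(round(r.max_documented_percentile()) for r in chosen)}")
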