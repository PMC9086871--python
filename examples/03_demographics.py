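"""Demographic tables and HIV-priority jurisdiction overlap.

Summarizes a cohort the way a surveillance report would: users per
state, counties above a minimum count, the five-group age distribution,
and the share of users inside two reference lists — the ten states with
the most new HIV diagnoses, and the Ending the HIV Epidemic (EHE)
priority jurisdictions.
"""

from msmcohort import (
    CorpusSpec,
    generate_corpus,
    load_default_gazetteer,
    load_default_jurisdictions,
    normalize_record,
    run_pipeline,
    summarize,
)

spec = CorpusSpec(n_users=2000, seed=7)
records = [normalize_record(r) for r in generate_corpus(spec)[0]]
cohort = run_pipeline(records).cohort

g = load_default_gazetteer()
jls = load_default_jurisdictions(g)
summary = summarize(
    cohort,
    jurisdictions=[
        (jls["top10_hiv_states"], "state_resolved"),
        (jls["ehe_priority"], "county_resolved"),
    ],
    min_county_count=20,
)

print(f"cohort {summary.n_cohort}; state-resolved {summary.n_state_resolved}; "
      f"county-resolved {summary.n_county_resolved}; aged {summary.n_aged}")
print("\nTop states:\n", summary.state_counts.head(5).to_string())
print("\nCounties with >= 20 users:\n", summary.county_table.to_string(index=False))
print("\nAge distribution:\n", summary.age_table.to_string(index=False))
print("\nAge stats:", summary.age_stats)
for row in summary.overlaps:
    print(f"\n{row['list']}: {row['numerator']}/{row['denominator']} "
          f"= {row['share_pct']}%")
# Shares use nested denominators: county shares over county-resolved
# users, state shares over state-resolved users.
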