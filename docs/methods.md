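# Methods

## The identification model

The pipeline treats cohort membership as a deterministic text-matching
decision with a human-audited error rate, not a probabilistic
classifier. A user enters the cohort when either

* a tweet of theirs contains a first-person self-report of being gay,
  bisexual or MSM that is not reported speech (**tweet channel**), or
* their profile description or display name contains an identity+person
  collocation (**profile channel**; profile text is self-descriptive by
  convention, so no first-person anchor is required).

Users found by both searches are deduplicated into one entry with
evidence `both`. The design is precision-first throughout: patterns
under-match by construction, ambiguity resolves to "no decision", and
the residual error rate is measured by annotation rather than assumed.

### Pattern grammar

Patterns live in `data/patterns.yaml` as term lists plus templates with
`{identity}` / `{person}` / `{person_or_people}` placeholders. Each
template × term combination expands to one surface regex, compiled
case-insensitively with word-boundary anchors (so `bi` never fires
inside "big" or "bird"); the default grammar expands to 312 surface
patterns. Matching returns the leftmost hit; ties are broken by
template list order. The default tweet templates require one of four
first-person anchors (`I'm/I am a(n) …`, `as a(n) …`, `… like me`,
`being a(n) …`) with up to two intervening adjectives.

Default mode intentionally also fires on third-person memorials ("due
to his identity as a gay male") and trans/nonbinary profiles ("gay
trans man … they/them"): the pipeline's measured precision is defined
against exactly that behavior, and the annotation layer — not the
matcher — separates true from false positives. An optional
`mode="strict"` adds exclusions (third-person possessives earlier in
the match sentence; trans/nonbinary profile vocabulary), raising
precision at the cost of recall; it is an extension, not the measured
operating point.

### Noise filtering

Retweet removal is a blanket pre-filter (nested retweet sub-record or
`RT @` prefix). Reported speech is span-conditional — it needs the
candidate match location — so it runs at match time, with three
independently toggleable rules:

1. **quotation** — the span lies inside a double-quote-delimited region
   (straight or curly; an unbalanced opening quote closes at
   end-of-text);
2. **attribution** — the sentence containing the span ends with an
   attribution verb (said/says/told/wrote/tweeted/…, optional subject);
3. **headline** — no first-person pronoun anywhere, the text ends with
   a URL, and title-case density (URLs excluded) exceeds
   `titlecase_threshold`.

`titlecase_threshold` defaults to 0.10. Tweet-embedded headlines are
usually sentence-case ("Gay men say new policy is discriminatory
https://…" has density 1/7), so the density clause is a weak
corroborator; the mandatory URL clause is what keeps the rule from
firing on ordinary prose, and guarantees the detector never fires on
text with no quotes, no attribution verb and no URL. Quote-tweets are
retained and judged by the span rule rather than dropped wholesale.

### Geolocation

Free-text profile locations are split on commas/slashes and matched
case-insensitively against a shipped gazetteer (50 states + DC, the
major metros, the EHE counties, informal aliases like "philly"). The
last state-matching token acts as the disambiguation hint, so
"Washington, DC" resolves to the District and bare "New York" to the
state. Ambiguous city names without a hint ("Springfield") resolve to
nothing — unresolvable is a value, not an error. Structured place
metadata (when present and US) takes priority over profile text. DC is
modeled as both a state-level and county-level unit. Every emitted
(county, state) pair exists in the gazetteer, and county-resolved users
are a subset of state-resolved users by construction.

### Age

Age patterns are first-person anchored ("I'm 24 [years old]",
"turned 30", "my 21st birthday"), with unit/percent guards ("I'm 100%
sure", "I'm 6 feet" never count) and digit boundaries ("1000 years
old" is out of range, not "000"). A bare "N years old" needs a
first-person pronoun in the text. The user's age comes from the most
recent age-bearing tweet (ties: largest value); within a tweet the
largest mention wins. Ages below 13 — the platform floor — are
discarded. Bins: 13–24, 25–34, 35–44, 45–54, 55+ (capped at 130).
Birth-year arithmetic ("born in 1995") is available behind a flag and
off by default.

### Reporting conventions

Percentages use half-up rounding (1 decimal for shares, 2 for
precision); `pct` is exact rational arithmetic via `Decimal`, tested
against a `Fraction` oracle. Denominators are nested: county shares are
over county-resolved users, state shares over state-resolved users.
One published share in this literature, 6240/8756 printed as 71.2%, is
not reachable under any standard rounding (the exact value is 71.27%);
we treat it as a truncation artifact and print 71.3. Jurisdiction
overlap counts a user if their county **or** state is listed; the
top-10-states overlap uses the state-resolved denominator and the EHE
overlap the county-resolved one. The shipped jurisdiction lists
(top-10 new-HIV-diagnosis states; EHE Phase I counties + DC + 7 states,
San Juan PR omitted for gazetteer coverage) are editable fixtures.

### Evaluation

κ is computed from the pre-adjudication labels — that is what
independent dual annotation measures — while precision uses the
post-adjudication finals. κ with both annotators constant and identical
(p_e = 1) is defined as 1.0 with a warning. Channel metrics are absent,
not zero, for an empty channel. Sampling for annotation is per-channel,
uniform without replacement, reproducible from a seed.

## The synthetic corpus

`CorpusSpec` assigns each user one role — tweet-channel TP,
profile-channel TP, both-channel TP, third-person decoy, trans/nonbinary
profile decoy, or negative — by a single categorical draw, so the
analytic precision of a perfect matcher is simply the TP share of the
matchable mass:

    precision = (tt + tp − tb) / (tt + tp − tb + f3 + fnb)

The defaults (tt = 0.37, tp = 0.25, tb = 0.03, f3 = 0.07, fnb = 0.035,
n = 10,043 users) describe a matched population of ≈ 70% of the stream
with analytic precision 0.849 and a ≈ 60/40 tweet/profile channel mix
with per-channel precisions ≈ 0.84 / 0.88 — the operating point a
handwritten-pattern pipeline of this kind realistically reaches.
Geolocation coverage (87.6% state, 71.2% county among located), age
coverage (47.6%), the state mix (large coastal/sun-belt states heavy)
and the five-bin age mix are set to the same regime the pipeline is
meant for. Retweets (30% of users) and quoted/attributed self-reports
(5%) exercise the filters.

Planted items are drawn from the matcher's own template space, so the
generator and pipeline are co-tested: every planted TP matches, every
retweet is dropped, every reported-speech item is span-flagged, and the
cohort equals exactly the matchable set. Consequently recall and the
state/county/age accuracies are 1.0 by construction. What passing these
tests shows is that the machinery is internally consistent at the
stated operating point; what they cannot show is robustness to real
linguistic diversity — paraphrase outside the template families, slang
drift, non-English text, bots — on which real-world recall and coverage
would be strictly lower.

Generation is byte-deterministic under a fixed seed (single
`numpy` generator, ordered iteration). The v1 nested JSON dialect is
written by default, with v2 behind a flag; both normalize to the same
records.

## Problem sizes and numerical choices

The test suite runs decoy-free and adversarial corpora at 200–1,500
users and one law-of-large-numbers check at 10⁴ users with a 3-binomial-SE
tolerance around the analytic mixture value (an exact-0.85 mixture:
tt = tp = 0.425, f3 = fnb = 0.075). The acceptance script runs the
default 10,043-user conditions. Timestamp parsing failures map to a
sentinel epoch with a warning rather than dropping records (silent
cohort shrinkage is worse than a wrong sort key); profile recency ties
break by lexicographically larger tweet id.

## Known limitations

* English only; no learned models; no identification of transgender or
  nonbinary users (explicitly out of scope — they appear only as the
  documented false-positive mode of the default grammar).
* The gazetteer is a curated fixture, not a census product; free-text
  without a comma ("houston tx") or with a bare informal token it does
  not list resolves to nothing.
* Reference numbers from the original 2020–2021 stream deployment
  (cohort magnitudes, κ of 0.81/0.83/0.79, coverage rates, mean/median
  ages) depend on that stream and its annotators; they ship in
  `evaluation.REFERENCE_VALUES` for display and are never recomputed.
* Recall against the real platform population is unmeasured by design.
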