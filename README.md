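# dvconcord

Concordance analysis between mental-illness mentions text-mined from
domestic-violence police narratives and mental-health diagnoses in linked
hospital records.

## The problem

When police attend a domestic-violence event they write a free-text narrative
that often notes the mental health of the person of interest (POI — the
alleged perpetrator) or the victim ("the POI is suffering from dementia",
"the victim takes Valium").  Hospital admissions (APDC) and emergency
presentations (EDDC) independently record mental-health diagnoses as ICD-10,
ICD-9 or SNOMED-CT codes.  Linking the two systems per person and asking how
often they *agree* quantifies how much each surveillance system sees that the
other misses.

`dvconcord` implements that analysis as a reusable pipeline for
epidemiologists working with linked administrative data:

1. **Extraction** — rule-based gazetteer matching over narratives: a role
   anchor (`POI`, `defendant`, `accused` / `victim`, `vic`, `PINOP`), a
   trigger pattern (`suffers from`, `diagnosed with`, `has`, `takes`,
   `is on`, `history of`, …) and a dictionary term in the same sentence yield
   a mention, deduplicated to unique (event, role, level-1 group) triples.
2. **Harmonization** — ICD-9 and SNOMED-CT codes are converted to ICD-10 via
   a one-to-one crosswalk, then every code is rolled up to a closed set of
   26 first-level groups (mood disorders F30–F39, psychoactive-substance
   disorders F10–F19, …, plus special categories such as medication groups
   and unspecified mental illness).
3. **Linkage** — an exact person-ID join restricted to symmetric
   calendar-month windows (±1, 3, 6, 12 months; closed endpoints;
   interval-overlap semantics), a forward-looking 48-hour window, or no
   window.
4. **Concordance** — per event and role, agreement is a nonempty
   intersection of the mention-group and hospital-group sets; the
   event-level 2×2 cross-tabulation (mention yes/no × hospital yes/no) is an
   OR over roles, so mention-for-one-party / record-for-the-other events
   land in BOTH without same-role agreement.  Output tables report the 2×2,
   per-group concordance rates, and mention-only / hospital-only profiles.

Because the source data are confidential, the package ships a synthetic
cohort generator (`dvconcord.synthetic`) that emulates the data *structure* —
role-anchored mention phrases, configurable concordant/discordant code
placement, temporal offsets spanning every window — with gold labels, so the
whole pipeline is testable end to end.

## Worked example

```python
from dvconcord import (CohortConfig, generate_cohort, extract_corpus,
                       harmonize_records, link_events, classify_corpus,
                       tabulate, score_extraction, WindowSpec, Role,
                       default_lexicon, default_crosswalk, default_hierarchy)

lexicon = default_lexicon()
cohort = generate_cohort(CohortConfig(n_events=1000, seed=42), lexicon)
mentions, summary = extract_corpus(cohort.events, lexicon)
print(f"{summary.n_events_with_mention} of {summary.n_events} events have a mention")

records, n_bad = harmonize_records(cohort.records, default_crosswalk(), default_hierarchy())
linked = link_events(cohort.events, records, WindowSpec.months(12))
tables = tabulate(classify_corpus(cohort.events, mentions, linked))
print("2x2 at +-12 months:", {c.value: n for c, n in tables.two_by_two.items()})
print("POI agreement:", tables.per_role_agreement[Role.POI], "of", tables.per_role_both[Role.POI])

scores = score_extraction(mentions, cohort.gold)
print(f"extraction F1 = {scores.overall.f1:.3f}")
```

prints

```
197 of 1000 events have a mention
2x2 at +-12 months: {'BOTH': 52, 'MENTION_ONLY': 145, 'HOSPITAL_ONLY': 60, 'NEITHER': 743}
POI agreement: 30 of 36
extraction F1 = 0.907
```

i.e. 197 narratives carry at least one role-attributed mention; within ±12
months, 52 events have both a mention and a hospital record for either
party; for 30 of the 36 events where the POI has both, the level-1 group
agrees exactly; and the extractor recovers the planted gold mentions with
F1 = 0.907 under the default noise model (recall stays 1.0, precision drops
from negation/hearsay distractors the grammar deliberately does not handle).

The same run is available from the shell:

```bash
dvconcord generate --n-events 1000 --seed 42 --outdir cohort
dvconcord extract cohort/events.csv --out mentions.csv
dvconcord concord cohort/events.csv mentions.csv cohort/hospital.csv --window 12m --outdir tables
dvconcord all --config config.yaml     # full pipeline + manifest
```

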