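# Methods

## Analysis model

The unit of analysis is a police-attended domestic-violence event with
exactly one person of interest (POI) and one victim; events with multiple
parties per role are rejected at load time because role attribution of a
narrative mention would be ambiguous.  Two observation channels exist per
event and role:

* **mention channel** — level-1 ICD-10 mental-illness groups extracted from
  the event narrative by the rule grammar;
* **hospital channel** — level-1 groups of diagnosis codes on admission/ED
  records linked to the same person within a temporal window around the
  event date.

Concordance for a role is defined as a nonempty intersection of the two
group sets — "the same first-level diagnosis group recorded by both
systems, irrespective of how many other diagnoses either system holds".
The event-level 2×2 (mention yes/no × hospital yes/no) takes an OR over
roles; this is deliberate, so that events where the police mention concerns
one party and the hospital record the other are counted as overlap between
the systems even though neither role agrees.

All comparisons happen at the *first* level of the ICD-10 mental-illness
grouping.  The closed group set has 26 labels: the chapter-V blocks
(F00–F09 … F99), selected non-chapter-V blocks that carry mental-health
relevance in this setting (R40–R46 cognition/perception symptoms, S06
traumatic brain injury, T14 unspecified-region injury, X60–X84 intentional
self-harm, G10–G14 / G30–G32 / other G codes, Q90–Q99), and reserved
special categories with no ICD-10 home: four psychotropic-medication groups
(antidepressants, antipsychotics, antianxiety, neuroleptics), unspecified
substance abuse, unspecified drug-induced disorder, prescription-drug
abuse, and unspecified mental disorder.  Special categories are encoded as
uppercase tokens (`MED_ANTIDEPRESSANT`, `SUBSTANCE_ABUSE`, …) that roll up
to themselves; they can occur only in the mention channel, since hospital
records carry real diagnosis codes.

## Extraction grammar

A mention requires, within one sentence: a role anchor, a lexicon term, and
a trigger pattern between anchor and term (or a generic "bare" phrase such
as *mental health issues*, which needs only the anchor).  Matching is
case-insensitive, word-bounded, longest-phrase-first; narratives are
whitespace-normalized before offsets are computed, and every mention's
character span slices back to its surface form.  Sentences are split on
`.!?` followed by whitespace; anchors never associate across sentence
boundaries.

Design choices where the grammar was genuinely open:

* **Nearest-anchor attribution.**  When both role anchors occur in a
  sentence, a term is attributed to the anchor nearest by character
  distance; ties break to the anchor preceding the term.
* **No negation handling.**  "The POI denied any history of depression"
  yields a (false) mention.  This is a documented limitation of
  gazetteer-style extraction and is exploited by the synthetic noise model
  to create realistic false positives.
* **No stemming or fuzzy matching.**  The lexicon lists inflected variants
  explicitly; fuzzy matching would make gold recall ill-defined in tests.

The shipped lexicon (258 surface forms over all 26 groups) and the
ICD-9/SNOMED-CT → ICD-10 crosswalk (94 rows) are curated reconstructions,
versioned with the package and user-replaceable; each (code, scheme) pair
maps to exactly one ICD-10 code, so harmonization is deterministic.
Unmappable codes flag the record, which is excluded downstream and counted
in the run manifest — never silently dropped.

## Temporal windows

Month windows are symmetric (±1, 3, 6, 12 calendar months) with closed
endpoints.  Calendar shifting clamps the day of month (Jan 31 − 1 month →
Dec 31).  Two semantics are implemented because administrative-data
practice varies:

* `overlap` (default): the admission interval [start, end] intersects the
  window — an admission spanning the window edge plausibly relates to the
  event;
* `start`: only the admission start date must fall in the window.

The 48-hour window is forward-looking from the event date at start of day
and tests the admission start only, reading "a record within 48 hours of
the event" as post-event presentation.  Both choices are switchable in
`RunConfig`.

Percentages are rounded half-up to 2 decimal places via `decimal.Decimal`
(binary floating-point `round()` is avoided because it rounds half-even).
Zero denominators are reported as rate 0 with an explicit flag and a
warning rather than omitted, keeping the output schema stable.

## Synthetic cohort generator

The generator emulates the *structure* of the linked data, not its
population statistics.  Per event it draws, from a single seeded
`random.Random` stream:

* a mention per role with probability `mention_prevalence` (defaults
  POI 0.12, victim 0.04, reflecting that police record mental illness for
  POIs far more often than for victims), with the group drawn from
  role-specific weights whose rank order follows the observed mention
  profiles (unspecified > mood > childhood-onset > substance use >
  psychotic for POIs; anxiety elevated for victims);
* with probability `concordant_fraction` (default 0.3), a hospital record
  for the same person with a code of the same group, its start date offset
  from the event by a mixture over day bins (±30, ±31–90, ±91–180,
  ±181–365, ±366–540; weights 0.30/0.20/0.15/0.15/0.20) so that every
  window catches a different share of records;
* with probability `cross_role_fraction` (default 0.1), a record for the
  *other* party, producing the BOTH-without-agreement pattern;
* hospital-only records per role at `hospital_only_rate` (default 0.06),
  with substance-use-dominated group weights reflecting admission profiles.

Two construction rules make gold labels exact rather than probabilistic:
planted phrases are composed from the grammar's own anchors, triggers and
lexicon surfaces, so clean-cohort recall is 1 by construction; and
hospital-only / cross-role draws exclude the target person's own mentioned
groups, so same-role agreement occurs exactly when a concordant record was
planted and the window catches it (hence `concordant_fraction = 0` forces
zero agreement at every window).

The noise model (`distractor_rate`, default 0.3) adds filler sentences,
whole-sentence casing changes, and — in about 1 in 8 noisy events —
negation/hearsay trap sentences that the grammar knowingly mismatches.
Noise therefore lowers precision but never recall.  Passing tests on these
cohorts show that the pipeline is internally consistent and that the
grammar behaves as specified on its own pattern inventory; they do **not**
show field performance on real police narratives, whose spelling errors,
abbreviations, and cross-sentence references the generator does not model.

`expected_tables` computes the tables the pipeline should produce under
perfect extraction directly from the gold labels and the generator's
per-record true groups, using its own inline window check — bypassing
extraction, harmonization and the linkage join, so it serves as the
parameter-recovery oracle for those stages.  The tabulation step itself is
cross-checked separately against a brute-force per-(event, role, group)
enumeration in the test suite.

## Problem sizes

The test suite uses cohorts of 20–1,000 events (1,000 for oracle
equivalence and extraction-fidelity checks, 100 × ~50 for conservation,
20 × ~100 for monotonicity); `scripts/acceptance.py` uses 20,000 events,
at which the binomial noise on reported percentages is small relative to
their magnitude.  These sizes are the package's defaults and complete in
seconds on one CPU.

## Known limitations

* The lexicon and crosswalk are curated reconstructions, not the original
  production dictionaries; coverage of every level-1 group, not lexical
  completeness, is the design goal.
* Negation, coreference, and multi-party events are out of scope for the
  grammar (see above).
* Identity resolution is assumed perfect (exact person-ID join);
  linkage-error modelling is out of scope.
* Only descriptive statistics are produced; inferential measures (kappa,
  confidence intervals) are a documented extension point of
  `SummaryTables`, not implemented.
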