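"""Synthetic labelled cohorts: events with narratives, hospital records, gold.

The generator emulates the *structure* of linked police/health data — police
narratives carrying role-anchored mention phrases, and hospital records with
configurable temporal offsets and concordant/discordant diagnosis codes — so
every pipeline stage can be tested without access to confidential data.  It
makes no attempt at clinical-language realism or population-scale realism.

Key construction guarantees (the gold labels depend on them):

* every planted mention phrase is composed from the extraction grammar's own
  anchor/trigger inventory and the shipped lexicon, so gold recall is
  well-defined and extraction on a clean cohort (``distractor_rate=0``) is
  perfect by construction;
* hospital-only and cross-role records never reuse a group already mentioned
  for the same person, so same-role agreement occurs exactly when a
  concordant record was planted and the window catches it (in particular,
  ``concordant_fraction=0`` forces zero same-role agreement at every window);
* the noise model is limited to casing changes, filler clauses, and distractor
  sentences (including negation traps the grammar knowingly mismatches), so
  noise can lower precision but never gold recall.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from dateutil.relativedelta import relativedelta

from .concordance import EventConcordance, EventPair, SummaryTables, tabulate
from .extraction import DVEvent, Role
from .lexicon import GROUP_LABELS, Lexicon, Scheme, default_lexicon
from .linkage import HospitalRecord, Source, WindowKind, WindowSpec

__all__ = [
    "CohortConfig",
    "GoldLabel",
    "Cohort",
    "generate_cohort",
    "expected_tables",
    "write_gold",
    "load_gold",
]

#: Representative diagnosis codes per level-1 group (short key), as
#: (raw_code, scheme) pairs consistent with the shipped crosswalk/hierarchy.
#: Groups absent here (medication groups and the unspecified special
#: categories other than UNSPECIFIED_MI) have no hospital-side codes and can
#: therefore never be concordant — they only ever appear as police mentions.
HOSPITAL_CODES: dict[str, list[tuple[str, str]]] = {
    "physiological": [("F03", "ICD10"), ("F05.9", "ICD10"), ("290.0", "ICD9"), ("52448006", "SNOMED")],
    "substance_use": [("F10.2", "ICD10"), ("F10.1", "ICD10"), ("F19.2", "ICD10"), ("F11.2", "ICD10"), ("303.9", "ICD9"), ("305.0", "ICD9"), ("7200002", "SNOMED")],
    "psychotic": [("F20.0", "ICD10"), ("F20.9", "ICD10"), ("F25.9", "ICD10"), ("F23", "ICD10"), ("295.3", "ICD9"), ("58214004", "SNOMED")],
    "mood": [("F31.1", "ICD10"), ("F32.9", "ICD10"), ("F33.9", "ICD10"), ("F30.9", "ICD10"), ("296.2", "ICD9"), ("311", "ICD9"), ("35489007", "SNOMED"), ("13746004", "SNOMED")],
    "anxiety": [("F41.1", "ICD10"), ("F41.9", "ICD10"), ("F43.1", "ICD10"), ("F40.0", "ICD10"), ("300.00", "ICD9"), ("309.81", "ICD9"), ("197480006", "SNOMED")],
    "behavioral_syndromes": [("F50.0", "ICD10"), ("F51.0", "ICD10"), ("307.1", "ICD9"), ("56882008", "SNOMED")],
    "personality": [("F60.3", "ICD10"), ("F60.2", "ICD10"), ("301.83", "ICD9"), ("33449004", "SNOMED")],
    "intellectual": [("F70", "ICD10"), ("F79", "ICD10"), ("317", "ICD9"), ("110359009", "SNOMED")],
    "developmental": [("F84.0", "ICD10"), ("F81.9", "ICD10"), ("299.0", "ICD9"), ("408856003", "SNOMED")],
    "childhood": [("F90.0", "ICD10"), ("F91.3", "ICD10"), ("314.01", "ICD9"), ("406506008", "SNOMED")],
    "unspecified": [("F99", "ICD10"), ("74732009", "SNOMED")],
    "self_harm": [("X84", "ICD10"), ("X78", "ICD10"), ("E958.9", "ICD9"), ("248062006", "SNOMED")],
    "symptoms_signs": [("R44.3", "ICD10"), ("R41.0", "ICD10"), ("780.1", "ICD9"), ("55342001", "SNOMED")],
    "tbi": [("S06.9", "ICD10"), ("854.0", "ICD9"), ("127295002", "SNOMED")],
    "injury_unspec": [("T14.9", "ICD10"), ("959.9", "ICD9")],
    "degenerative": [("G30.9", "ICD10"), ("331.0", "ICD9"), ("26929004", "SNOMED")],
    "atrophies": [("G10", "ICD10"), ("333.4", "ICD9"), ("58756001", "SNOMED")],
    "nervous_system": [("G40.9", "ICD10"), ("345.9", "ICD9"), ("84757009", "SNOMED")],
    "chromosomal": [("Q90.9", "ICD10"), ("758.0", "ICD9")],
}

#: Default mention group weights, echoing the rank order of the observed
#: mention profiles (unspecified and mood dominate; anxiety elevated for
#: victims) without matching exact proportions.
_POI_WEIGHTS = {
    "unspecified": 0.29, "mood": 0.22, "childhood": 0.13, "substance_use": 0.10,
    "psychotic": 0.08, "anxiety": 0.05, "self_harm": 0.04, "substance_abuse": 0.03,
    "developmental": 0.02, "intellectual": 0.02, "personality": 0.02,
    "physiological": 0.01, "med_antidepressant": 0.01, "tbi": 0.01,
    "symptoms_signs": 0.01,
}
_VICTIM_WEIGHTS = {
    "unspecified": 0.24, "mood": 0.26, "anxiety": 0.13, "childhood": 0.10,
    "substance_use": 0.07, "psychotic": 0.06, "intellectual": 0.05,
    "self_harm": 0.05, "physiological": 0.03, "developmental": 0.02,
    "personality": 0.02, "substance_abuse": 0.02, "med_anxiolytic": 0.01,
    "symptoms_signs": 0.01,
}
#: Hospital-record group weights (substance use dominates admissions).
_HOSPITAL_WEIGHTS = {
    "substance_use": 0.42, "mood": 0.19, "anxiety": 0.12, "psychotic": 0.09,
    "personality": 0.05, "physiological": 0.03, "childhood": 0.02,
    "self_harm": 0.02, "symptoms_signs": 0.02, "unspecified": 0.02,
    "intellectual": 0.01, "developmental": 0.01,
}

#: Record start-date offsets from the event date, in days: (lo, hi, weight)
#: bins spanning the inside and outside of every month window.
_OFFSET_BINS = [
    (-30, 30, 0.30),
    (-90, -31, 0.10), (31, 90, 0.10),
    (-180, -91, 0.075), (91, 180, 0.075),
    (-365, -181, 0.075), (181, 365, 0.075),
    (-540, -366, 0.10), (366, 540, 0.10),
]

_RELATIONSHIPS = [
    "spouse/partner", "boy/girlfriend", "parent/guardian", "child",
    "sibling", "other member of family", "carer",
]

_POI_SURFACES = ["POI", "person of interest", "defendant", "accused"]
_VICTIM_SURFACES = ["victim", "vic", "PINOP", "person in need of protection"]

# Sentence frames composing anchor + trigger + lexicon term; the trigger in
# each frame is drawn from the extraction grammar's trigger inventory.
_DIAGNOSIS_FRAMES = [
    "The {a} is suffering from {t}.",
    "The {a} suffers from {t}.",
    "The {a} was diagnosed with {t}.",
    "The {a} has been diagnosed with {t}.",
    "The {a} has a history of {t}.",
    "The {a} has {t}.",
    "Police noted the {a} suffers from {t}.",
    "The {a} stated they had been diagnosed with {t}.",
    "The {a} is being treated for {t}.",
    "The {a} has a long history of {t}.",
]
_MEDICATION_FRAMES = [
    "The {a} takes {t}.",
    "The {a} is on {t}.",
    "The {a} is taking {t} daily.",
    "The {a} takes a number of {t}.",
]
_FILLERS = [
    "Neighbours reported loud shouting coming from the premises.",
    "Police attended the address shortly after the call.",
    "Both parties were spoken to separately.",
    "The argument began over household finances.",
    "A neighbour contacted triple zero.",
    "No injuries were observed at the scene.",
    "Children were present during the incident.",
    "An AVO application was submitted.",
    "Police conducted a walkthrough of the residence.",
    "The parties have been in a relationship for several years.",
    "Officers observed a broken window in the kitchen.",
    "The dispute was verbal only.",
    "Police provided referral information before leaving.",
    "The incident occurred in the early evening.",
]
# Negation/hearsay traps: the grammar has no negation handling, so these
# produce deliberate false positives under noise.
_TRAP_FRAMES = [
    "The {a} denied any history of {t}.",
    "The {a} stated the {o} has {t}.",
]
_TRAP_TERMS = ["depression", "schizophrenia", "anxiety", "bipolar disorder", "ptsd"]

_WINDOW_LABELS = ("1m", "3m", "6m", "12m", "48h", "none")


def _normalize(weights: dict[str, float], what: str) -> dict[str, float]:
    for k, v in weights.items():
        if v < 0:
            raise ValueError(f"{what}: negative weight for {k!r}")
        if k not in GROUP_LABELS:
            raise ValueError(f"{what}: unknown group key {k!r}")
    total = sum(weights.values())
    if total <= 0:
        raise ValueError(f"{what}: weights sum to zero")
    return {k: v / total for k, v in weights.items()}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Probabilities are per event; group weights are distributions over the
    short group keys of :data:`dvconcord.lexicon.GROUP_LABELS` and are
    normalized at construction.
    """

    n_events: int = 1000
    mention_prevalence: dict[str, float] = field(
        default_factory=lambda: {"POI": 0.12, "VICTIM": 0.04}
    )
    group_weights: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"POI": dict(_POI_WEIGHTS), "VICTIM": dict(_VICTIM_WEIGHTS)}
    )
    hospital_group_weights: dict[str, float] = field(
        default_factory=lambda: dict(_HOSPITAL_WEIGHTS)
    )
    concordant_fraction: float = 0.3
    cross_role_fraction: float = 0.1
    hospital_only_rate: dict[str, float] = field(
        default_factory=lambda: {"POI": 0.06, "VICTIM": 0.06}
    )
    window_offset_distribution: list[tuple[int, int, float]] = field(
        default_factory=lambda: list(_OFFSET_BINS)
    )
    distractor_rate: float = 0.3
    date_range: tuple[date, date] = (date(2006, 1, 1), date(2016, 12, 31))
    seed: int = 0

    def __post_init__(self):
        if self.n_events <= 0:
            raise ValueError("n_events must be positive")
        for role in ("POI", "VICTIM"):
            p = self.mention_prevalence[role]
            if not 0 <= p <= 1:
                raise ValueError(f"mention_prevalence[{role}] out of [0,1]: {p}")
            q = self.hospital_only_rate[role]
            if not 0 <= q <= 1:
                raise ValueError(f"hospital_only_rate[{role}] out of [0,1]: {q}")
            self.group_weights[role] = _normalize(
                self.group_weights[role], f"group_weights[{role}]"
            )
        for name, p in (
            ("concordant_fraction", self.concordant_fraction),
            ("cross_role_fraction", self.cross_role_fraction),
            ("distractor_rate", self.distractor_rate),
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} out of [0,1]: {p}")
        self.hospital_group_weights = _normalize(
            self.hospital_group_weights, "hospital_group_weights"
        )
        bad = [g for g in self.hospital_group_weights if g not in HOSPITAL_CODES]
        if bad:
            raise ValueError(f"hospital_group_weights for code-less group(s): {bad}")
        total = sum(w for _, _, w in self.window_offset_distribution)
        if total <= 0:
            raise ValueError("window_offset_distribution weights sum to zero")
        if self.date_range[0] >= self.date_range[1]:
            raise ValueError("empty date_range")


@dataclass(frozen=True)
class GoldLabel:
    """One planted mention and the windows at which it should be concordant."""

    event_id: str
    role: Role
    level1_group: str
    planted_phrase: str
    expected_concordant_at: frozenset[str]

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.event_id, self.role.value, self.level1_group)


@dataclass
class Cohort:
    """A generated cohort: events, records, per-record true groups, gold."""

    config: CohortConfig
    events: list[DVEvent]
    records: list[HospitalRecord]
    record_groups: list[str]  # true level-1 group of records[i], by construction
    gold: list[GoldLabel]


def _window_hit(event_date: date, start: date, end: date, label: str) -> bool:
    """Generator-side window check (closed, interval-overlap months; forward
    start-only 48h).  Written independently of :func:`dvconcord.linkage.in_window`."""
    if label == "none":
        return True
    if label == "48h":
        return event_date <= start <= event_date + timedelta(days=2)
    months = int(label[:-1])
    lo = event_date - relativedelta(months=months)
    hi = event_date + relativedelta(months=months)
    return start <= hi and end >= lo


def _weighted_choice(rng: random.Random, weights: dict[str, float]) -> str:
    keys = sorted(weights)
    return rng.choices(keys, weights=[weights[k] for k in keys], k=1)[0]


def _draw_offset(rng: random.Random, bins: Sequence[tuple[int, int, float]]) -> int:
    lo, hi, _ = rng.choices(list(bins), weights=[w for _, _, w in bins], k=1)[0]
    return rng.randint(lo, hi)


def _mention_sentence(rng: random.Random, role: Role, group_key: str, lexicon: Lexicon) -> str:
    surfaces = _POI_SURFACES if role is Role.POI else _VICTIM_SURFACES
    anchor = rng.choice(surfaces)
    entries = lexicon.entries_for_group(GROUP_LABELS[group_key])
    if not entries:
        raise ValueError(f"lexicon has no surface forms for group {group_key!r}")
    term = rng.choice(sorted(e.surface_form for e in entries))
    frames = _MEDICATION_FRAMES if group_key.startswith("med_") else _DIAGNOSIS_FRAMES
    return rng.choice(frames).format(a=anchor, t=term)


def _record_for_group(
    rng: random.Random, person_id: str, group_key: str, event_date: date, cfg: CohortConfig
) -> tuple[HospitalRecord, str]:
    offset = _draw_offset(rng, cfg.window_offset_distribution)
    start = event_date + timedelta(days=offset)
    end = start + timedelta(days=rng.randint(0, 5))
    raw, scheme = rng.choice(HOSPITAL_CODES[group_key])
    source = Source.APDC if scheme == "ICD10" and rng.random() < 0.5 else Source.EDDC
    rec = HospitalRecord(
        person_id=person_id,
        source=source,
        start_date=start,
        end_date=end,
        raw_code=raw,
        scheme=Scheme(scheme),
    )
    return rec, GROUP_LABELS[group_key]


def generate_cohort(
    config: CohortConfig, lexicon: Optional[Lexicon] = None
) -> Cohort:
    """Generate a deterministic labelled cohort from ``config.seed``."""
    rng = random.Random(config.seed)
    lexicon = lexicon if lexicon is not None else default_lexicon()
    d0, d1 = config.date_range
    # Keep every record date inside date_range: offsets reach +-540 days and
    # admissions last up to 5 days, so event dates stay 546 days off each edge.
    margin = 546
    span = (d1 - d0).days - 2 * margin
    if span <= 0:
        raise ValueError("date_range too narrow for the offset distribution")

    events: list[DVEvent] = []
    records: list[HospitalRecord] = []
    record_groups: list[str] = []
    gold: list[GoldLabel] = []

    for i in range(config.n_events):
        event_id = f"E{i:06d}"
        poi_id, victim_id = f"P{i:06d}", f"V{i:06d}"
        event_date = d0 + timedelta(days=margin + rng.randrange(span + 1))
        person = {Role.POI: poi_id, Role.VICTIM: victim_id}

        mention_groups: dict[Role, Optional[str]] = {Role.POI: None, Role.VICTIM: None}
        mention_phrases: dict[Role, str] = {}
        sentences: list[str] = [rng.choice(_FILLERS)]
        for role in (Role.POI, Role.VICTIM):
            if rng.random() < config.mention_prevalence[role.value]:
                gkey = _weighted_choice(rng, config.group_weights[role.value])
                mention_groups[role] = gkey
                phrase = _mention_sentence(rng, role, gkey, lexicon)
                mention_phrases[role] = phrase
                sentences.append(phrase)

        # Concordant record: same person, same group, offset-dated.
        ev_records: list[tuple[HospitalRecord, str]] = []
        expected: dict[Role, frozenset[str]] = {}
        for role in (Role.POI, Role.VICTIM):
            gkey = mention_groups[role]
            windows: frozenset[str] = frozenset()
            if (
                gkey is not None
                and gkey in HOSPITAL_CODES
                and rng.random() < config.concordant_fraction
            ):
                rec, label = _record_for_group(rng, person[role], gkey, event_date, config)
                ev_records.append((rec, label))
                windows = frozenset(
                    w for w in _WINDOW_LABELS
                    if _window_hit(event_date, rec.start_date, rec.end_date, w)
                )
            expected[role] = windows

        # Cross-role record: a mention for one party, a (different-group)
        # record for the other party.
        mentioned = [r for r in Role if mention_groups[r] is not None]
        if mentioned and rng.random() < config.cross_role_fraction:
            src = rng.choice(sorted(mentioned, key=lambda r: r.value))
            other = Role.VICTIM if src is Role.POI else Role.POI
            pool = {
                k: w for k, w in config.hospital_group_weights.items()
                if k != mention_groups[other]
            }
            gkey = _weighted_choice(rng, pool)
            rec, label = _record_for_group(rng, person[other], gkey, event_date, config)
            ev_records.append((rec, label))

        # Hospital-only records: never reuse the person's own mentioned group,
        # so they cannot create accidental same-role agreement.
        for role in (Role.POI, Role.VICTIM):
            if rng.random() < config.hospital_only_rate[role.value]:
                pool = {
                    k: w for k, w in config.hospital_group_weights.items()
                    if k != mention_groups[role]
                }
                gkey = _weighted_choice(rng, pool)
                rec, label = _record_for_group(rng, person[role], gkey, event_date, config)
                ev_records.append((rec, label))

        # Distractor noise: benign fillers, negation/hearsay traps, casing.
        if rng.random() < config.distractor_rate:
            if rng.random() < 0.125:
                frame = rng.choice(_TRAP_FRAMES)
                a_role = rng.choice((Role.POI, Role.VICTIM))
                a = rng.choice(_POI_SURFACES) if a_role is Role.POI else rng.choice(_VICTIM_SURFACES)
                o = rng.choice(_VICTIM_SURFACES) if a_role is Role.POI else rng.choice(_POI_SURFACES)
                sentences.append(frame.format(a=a, o=o, t=rng.choice(_TRAP_TERMS)))
            else:
                extra = rng.choice(_FILLERS)
                if rng.random() < 0.3:
                    extra = extra.upper()
                sentences.append(extra)
        rng.shuffle(sentences)

        events.append(
            DVEvent(
                event_id=event_id,
                event_date=event_date,
                poi_id=poi_id,
                victim_id=victim_id,
                narrative=" ".join(sentences),
                relationship_flag=rng.choice(_RELATIONSHIPS),
            )
        )
        for rec, label in ev_records:
            records.append(rec)
            record_groups.append(label)
        for role in (Role.POI, Role.VICTIM):
            gkey = mention_groups[role]
            if gkey is not None:
                gold.append(
                    GoldLabel(
                        event_id=event_id,
                        role=role,
                        level1_group=GROUP_LABELS[gkey],
                        planted_phrase=mention_phrases[role],
                        expected_concordant_at=expected[role],
                    )
                )

    return Cohort(
        config=config,
        events=events,
        records=records,
        record_groups=record_groups,
        gold=gold,
    )


def expected_tables(
    config: CohortConfig, cohort: Cohort, window: WindowSpec
) -> SummaryTables:
    """Tables the pipeline should produce under perfect extraction.

    Mention sets come from the gold labels (bypassing text extraction);
    hospital sets come from the generator's own per-record true groups and an
    independent window check, bypassing code harmonization and
    :func:`dvconcord.linkage.link_events`.
    """
    label = window.label
    gold_by_event: dict[tuple[str, Role], set[str]] = {}
    for g in cohort.gold:
        gold_by_event.setdefault((g.event_id, g.role), set()).add(g.level1_group)

    by_person: dict[str, list[tuple[HospitalRecord, str]]] = {}
    for rec, grp in zip(cohort.records, cohort.record_groups):
        by_person.setdefault(rec.person_id, []).append((rec, grp))

    pairs: list[EventPair] = []
    for ev in cohort.events:
        parts = {}
        for role, pid in ((Role.POI, ev.poi_id), (Role.VICTIM, ev.victim_id)):
            h_groups = frozenset(
                grp
                for rec, grp in by_person.get(pid, ())
                if _window_hit(ev.event_date, rec.start_date, rec.end_date, label)
            )
            parts[role] = EventConcordance(
                ev.event_id,
                role,
                frozenset(gold_by_event.get((ev.event_id, role), set())),
                h_groups,
            )
        pairs.append(EventPair(ev.event_id, poi=parts[Role.POI], victim=parts[Role.VICTIM]))
    return tabulate(pairs)


GOLD_COLUMNS = ["event_id", "role", "level1_group", "phrase", "windows"]


def write_gold(gold: Sequence[GoldLabel], path: Union[str, Path]) -> None:
    pd.DataFrame(
        [
            {
                "event_id": g.event_id,
                "role": g.role.value,
                "level1_group": g.level1_group,
                "phrase": g.planted_phrase,
                "windows": "|".join(sorted(g.expected_concordant_at)),
            }
            for g in gold
        ],
        columns=GOLD_COLUMNS,
    ).to_csv(path, index=False)


def load_gold(path: Union[str, Path]) -> list[GoldLabel]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        GoldLabel(
            event_id=r.event_id,
            role=Role(r.role),
            level1_group=r.level1_group,
            planted_phrase=r.phrase,
            expected_concordant_at=frozenset(
                w for w in r.windows.split("|") if w
            ),
        )
        for r in df.itertuples()
    ]
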