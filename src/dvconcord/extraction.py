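"""Rule-based extraction of role-attributed mental-illness mentions.

A mention is emitted when, inside a single sentence of an event narrative,
a role anchor (for the person of interest: "POI", "person of interest",
"defendant", "accused"; for the victim: "victim", "vic", "PINOP", "person in
need of protection") co-occurs with a lexicon term, connected by a trigger
pattern ("suffers from", "diagnosed with", "has", "takes", "is on",
"history of", ...).  A small set of generic bare terms ("mental health
issues", ...) match with an anchor alone.  Mentions are deduplicated to
unique (role, level-1 group) pairs per event.

Negation is deliberately not handled ("no history of depression" still
matches); this mirrors a plain gazetteer-plus-pattern grammar and is a
documented limitation.
"""

from __future__ import annotations

import logging
import math
import re
import warnings
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .lexicon import Lexicon

logger = logging.getLogger(__name__)

__all__ = [
    "Role",
    "DVEvent",
    "Mention",
    "Grammar",
    "DEFAULT_GRAMMAR",
    "extract_mentions",
    "extract_corpus",
    "CorpusSummary",
    "score_extraction",
    "PRF",
    "ExtractionScores",
    "load_events",
    "write_mentions",
]


class Role(str, Enum):
    POI = "POI"
    VICTIM = "VICTIM"


@dataclass(frozen=True)
class DVEvent:
    """One police-attended domestic-violence event (single POI, single victim)."""

    event_id: str
    event_date: date
    poi_id: str
    victim_id: str
    narrative: str
    relationship_flag: str = ""

    def __post_init__(self):
        if self.poi_id == self.victim_id:
            raise ValueError(
                f"event {self.event_id}: POI and victim share person ID {self.poi_id!r}"
            )


@dataclass(frozen=True)
class Mention:
    """An extracted mention: role attribution plus level-1 group.

    ``char_span`` is a half-open [start, end) span into the whitespace-
    normalized narrative; slicing the normalized text with it reproduces
    ``surface``.
    """

    event_id: str
    role: Role
    surface: str
    anchor: str
    trigger: str
    level1_group: str
    char_span: tuple[int, int]

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.event_id, self.role.value, self.level1_group)


@dataclass
class Grammar:
    """Anchor sets, trigger patterns, and bare-term list of the mention grammar."""

    poi_anchors: tuple[str, ...] = (
        "person of interest",
        "poi",
        "defendant",
        "accused",
    )
    victim_anchors: tuple[str, ...] = (
        "person in need of protection",
        "pinop",
        "victim",
        "vic",
    )
    triggers: tuple[str, ...] = (
        "suffers from",
        "suffering from",
        "diagnosed with",
        "history of",
        "is taking",
        "is on",
        "takes",
        "treated for",
        "has",
        "had",
    )
    #: Generic surfaces that may match on an anchor alone, without a trigger.
    bare_terms: frozenset[str] = frozenset(
        {
            "mental health issues",
            "mental health problems",
            "mental health concerns",
            "mental illness",
            "mental health history",
            "mental health condition",
        }
    )
    _anchor_re: re.Pattern = field(init=False, repr=False)
    _trigger_re: re.Pattern = field(init=False, repr=False)
    _roles: dict[str, Role] = field(init=False, repr=False)

    def __post_init__(self):
        poi = set(a.casefold() for a in self.poi_anchors)
        vic = set(a.casefold() for a in self.victim_anchors)
        overlap = poi & vic
        if overlap:
            raise ValueError(f"anchor(s) in both role sets: {sorted(overlap)}")
        self._roles = {a: Role.POI for a in poi}
        self._roles.update({a: Role.VICTIM for a in vic})
        anchors = sorted(poi | vic, key=len, reverse=True)
        self._anchor_re = _phrase_alternation(anchors)
        trig = sorted((t.casefold() for t in self.triggers), key=len, reverse=True)
        self._trigger_re = _phrase_alternation(trig)

    def anchor_role(self, anchor_surface: str) -> Role:
        return self._roles[anchor_surface.casefold()]


def _phrase_alternation(phrases: Sequence[str]) -> re.Pattern:
    """Word-bounded, case-insensitive alternation; longest phrase wins."""
    body = "|".join(re.escape(p) for p in phrases)
    return re.compile(rf"\b(?:{body})\b", re.IGNORECASE)


DEFAULT_GRAMMAR = Grammar()

_SENT_BOUNDARY = re.compile(r"[.!?]+(?:\s+|$)")


def normalize_narrative(text: str) -> str:
    """Collapse all whitespace runs to single spaces and strip the ends."""
    return " ".join(text.split())


def _sentences(text: str) -> list[tuple[int, int]]:
    """Half-open spans of sentences in ``text`` (split on .!? + whitespace)."""
    spans, start = [], 0
    for m in _SENT_BOUNDARY.finditer(text):
        spans.append((start, m.end()))
        start = m.end()
    if start < len(text):
        spans.append((start, len(text)))
    return spans


def _term_pattern(lexicon: Lexicon) -> Optional[re.Pattern]:
    forms = lexicon.surface_forms()
    if not forms:
        return None
    return _phrase_alternation(forms)


def extract_mentions(
    event: DVEvent,
    lexicon: Lexicon,
    grammar: Grammar = DEFAULT_GRAMMAR,
    *,
    _term_re: Optional[re.Pattern] = None,
) -> list[Mention]:
    """Extract deduplicated role-attributed mentions from one narrative.

    Within each sentence, every lexicon-term match is attributed to the
    nearest role anchor (ties break to the anchor preceding the term) and kept
    when a trigger lies between anchor and term, or when the term is a bare
    generic phrase.  Results keep sentence order; (role, level-1 group)
    duplicates after the first are dropped.
    """
    text = normalize_narrative(event.narrative)
    if not text:
        logger.warning("event %s: empty narrative", event.event_id)
        return []
    term_re = _term_re if _term_re is not None else _term_pattern(lexicon)
    if term_re is None:
        return []

    out: list[Mention] = []
    seen: set[tuple[Role, str]] = set()
    for s_start, s_end in _sentences(text):
        sent = text[s_start:s_end]
        anchors = [(m.start(), m.end(), m.group(0)) for m in grammar._anchor_re.finditer(sent)]
        if not anchors:
            continue
        for tm in term_re.finditer(sent):
            entry = lexicon.lookup(tm.group(0))
            if entry is None:  # pragma: no cover - alternation built from lexicon
                continue
            # Skip term matches that are themselves anchor matches (defensive).
            t_start, t_end = tm.start(), tm.end()
            best = None
            for a_start, a_end, a_text in anchors:
                if a_start < t_end and t_start < a_end:
                    continue  # overlapping spans cannot anchor themselves
                if a_end <= t_start:
                    dist, precedes = t_start - a_end, True
                else:
                    dist, precedes = a_start - t_end, False
                cand = (dist, not precedes, a_start, a_end, a_text)
                if best is None or cand < best:
                    best = cand
            if best is None:
                continue
            _, _, a_start, a_end, a_text = best
            trigger: Optional[str] = None
            if a_end <= t_start:
                between = sent[a_end:t_start]
                trig_m = grammar._trigger_re.search(between)
                if trig_m:
                    trigger = trig_m.group(0).casefold()
            if trigger is None and tm.group(0).casefold() in grammar.bare_terms:
                trigger = "bare"
            if trigger is None:
                continue
            role = grammar.anchor_role(a_text)
            key = (role, entry.level1_group)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                Mention(
                    event_id=event.event_id,
                    role=role,
                    surface=text[s_start + t_start : s_start + t_end],
                    anchor=a_text,
                    trigger=trigger,
                    level1_group=entry.level1_group,
                    char_span=(s_start + t_start, s_start + t_end),
                )
            )
    return out


@dataclass
class CorpusSummary:
    """Per-corpus extraction tallies."""

    n_events: int
    n_events_with_mention: int
    n_events_with_poi_mention: int
    n_events_with_victim_mention: int
    n_mentions: int


def extract_corpus(
    events: Sequence[DVEvent],
    lexicon: Lexicon,
    grammar: Grammar = DEFAULT_GRAMMAR,
) -> tuple[list[Mention], CorpusSummary]:
    """Run extraction over a validated corpus; deterministic given inputs."""
    ids = [e.event_id for e in events]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate event_id(s) in corpus: {dup[:5]}")
    term_re = _term_pattern(lexicon)
    mentions: list[Mention] = []
    with_poi = with_vic = with_any = 0
    for ev in events:
        ms = extract_mentions(ev, lexicon, grammar, _term_re=term_re)
        mentions.extend(ms)
        roles = {m.role for m in ms}
        if roles:
            with_any += 1
        if Role.POI in roles:
            with_poi += 1
        if Role.VICTIM in roles:
            with_vic += 1
    summary = CorpusSummary(
        n_events=len(events),
        n_events_with_mention=with_any,
        n_events_with_poi_mention=with_poi,
        n_events_with_victim_mention=with_vic,
        n_mentions=len(mentions),
    )
    return mentions, summary


@dataclass(frozen=True)
class PRF:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int


@dataclass(frozen=True)
class ExtractionScores:
    overall: PRF
    by_role: dict[Role, PRF]


def _prf(tp: int, fp: int, fn: int) -> PRF:
    if tp + fp == 0:
        warnings.warn("no predictions: precision undefined", stacklevel=3)
        p = math.nan
    else:
        p = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("empty gold: recall undefined", stacklevel=3)
        r = math.nan
    else:
        r = tp / (tp + fn)
    if math.isnan(p) or math.isnan(r) or p + r == 0:
        f1 = math.nan if (math.isnan(p) or math.isnan(r)) else 0.0
    else:
        f1 = 2 * p * r / (p + r)
    return PRF(p, r, f1, tp, fp, fn)


def score_extraction(
    predicted: Iterable, gold: Iterable
) -> ExtractionScores:
    """Precision/recall/F1 on unique (event_id, role, level1_group) keys.

    ``predicted`` and ``gold`` may be :class:`Mention` objects, objects with a
    ``key`` attribute, or raw key tuples.  Scores are micro-averaged overall
    and stratified per role.
    """

    def as_key(x) -> tuple[str, str, str]:
        if hasattr(x, "key"):
            e, r, g = x.key
        else:
            e, r, g = x
        r = r.value if isinstance(r, Role) else str(r)
        return (str(e), r, str(g))

    pred = {as_key(x) for x in predicted}
    gld = {as_key(x) for x in gold}
    by_role: dict[Role, PRF] = {}
    for role in Role:
        p_r = {k for k in pred if k[1] == role.value}
        g_r = {k for k in gld if k[1] == role.value}
        tp = len(p_r & g_r)
        by_role[role] = _prf(tp, len(p_r) - tp, len(g_r) - tp)
    tp = len(pred & gld)
    return ExtractionScores(
        overall=_prf(tp, len(pred) - tp, len(gld) - tp), by_role=by_role
    )


# ---------------------------------------------------------------------------
# Delimited-text I/O

EVENT_COLUMNS = ["event_id", "event_date", "poi_id", "victim_id", "relationship_flag", "narrative"]
MENTION_COLUMNS = ["event_id", "role", "level1_group", "surface", "start", "end", "trigger"]


def load_events(path: Union[str, Path]) -> list[DVEvent]:
    """Load the event table; rejects duplicate IDs and shared person IDs."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != EVENT_COLUMNS:
        raise ValueError(f"event header must be {EVENT_COLUMNS}, got {list(df.columns)}")
    if df["event_id"].duplicated().any():
        dup = sorted(df.loc[df["event_id"].duplicated(), "event_id"].unique())
        raise ValueError(f"duplicate event_id(s): {dup[:5]}")
    events = []
    for r in df.itertuples():
        events.append(
            DVEvent(
                event_id=r.event_id,
                event_date=date.fromisoformat(r.event_date),
                poi_id=r.poi_id,
                victim_id=r.victim_id,
                narrative=r.narrative,
                relationship_flag=r.relationship_flag,
            )
        )
    return events


def write_events(events: Sequence[DVEvent], path: Union[str, Path]) -> None:
    pd.DataFrame(
        [
            {
                "event_id": e.event_id,
                "event_date": e.event_date.isoformat(),
                "poi_id": e.poi_id,
                "victim_id": e.victim_id,
                "relationship_flag": e.relationship_flag,
                "narrative": e.narrative,
            }
            for e in events
        ],
        columns=EVENT_COLUMNS,
    ).to_csv(path, index=False)


def write_mentions(mentions: Sequence[Mention], path: Union[str, Path]) -> None:
    pd.DataFrame(
        [
            {
                "event_id": m.event_id,
                "role": m.role.value,
                "level1_group": m.level1_group,
                "surface": m.surface,
                "start": m.char_span[0],
                "end": m.char_span[1],
                "trigger": m.trigger,
            }
            for m in mentions
        ],
        columns=MENTION_COLUMNS,
    ).to_csv(path, index=False)


def load_mentions(path: Union[str, Path]) -> list[Mention]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        Mention(
            event_id=r.event_id,
            role=Role(r.role),
            surface=r.surface,
            anchor="",
            trigger=r.trigger,
            level1_group=r.level1_group,
            char_span=(int(r.start), int(r.end)),
        )
        for r in df.itertuples()
    ]
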