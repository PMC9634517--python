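"""Event-level concordance between narrative mentions and hospital diagnoses.

For each event and role the two level-1 group sets (text-mined mentions vs
linked hospital diagnoses) are intersected; agreement means a nonempty
intersection.  The event-level 2×2 cross-tabulation uses an OR over roles
("mention yes" if either party has a mention, "hospital yes" if either has a
linked record), so an event where the police mention concerns one individual
and the hospital record the other lands in the BOTH cell without same-role
agreement.

Per-group concordance rates use, as denominator, the total number of events
with a text-mined mention of that group for that role.  Percentages are
rounded half-up to 2 decimal places.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .extraction import DVEvent, Mention, Role
from .lexicon import LEVEL1_GROUPS
from .linkage import HospitalRecord, LinkedSets

logger = logging.getLogger(__name__)

__all__ = [
    "Cell",
    "EventConcordance",
    "EventPair",
    "SummaryTables",
    "classify_event",
    "classify_corpus",
    "tabulate",
    "rate",
]


class Cell(str, Enum):
    BOTH = "BOTH"
    MENTION_ONLY = "MENTION_ONLY"
    HOSPITAL_ONLY = "HOSPITAL_ONLY"
    NEITHER = "NEITHER"


def _cell(has_mention: bool, has_hospital: bool) -> Cell:
    if has_mention and has_hospital:
        return Cell.BOTH
    if has_mention:
        return Cell.MENTION_ONLY
    if has_hospital:
        return Cell.HOSPITAL_ONLY
    return Cell.NEITHER


@dataclass(frozen=True)
class EventConcordance:
    """Concordance state of one (event, role) pair."""

    event_id: str
    role: Role
    mention_groups: frozenset[str]
    hospital_groups: frozenset[str]

    @property
    def matched_groups(self) -> frozenset[str]:
        return self.mention_groups & self.hospital_groups

    @property
    def agreement(self) -> bool:
        return bool(self.matched_groups)

    @property
    def cell(self) -> Cell:
        return _cell(bool(self.mention_groups), bool(self.hospital_groups))


@dataclass(frozen=True)
class EventPair:
    """Both roles' concordance plus the event-level (OR over roles) cell."""

    event_id: str
    poi: EventConcordance
    victim: EventConcordance

    def for_role(self, role: Role) -> EventConcordance:
        return self.poi if role is Role.POI else self.victim

    @property
    def event_cell(self) -> Cell:
        return _cell(
            bool(self.poi.mention_groups) or bool(self.victim.mention_groups),
            bool(self.poi.hospital_groups) or bool(self.victim.hospital_groups),
        )


def rate(numerator: int, denominator: int) -> float:
    """Percentage ``100 * numerator / denominator`` rounded half-up to 2 dp.

    A zero denominator is flagged with a warning and rendered as 0.0.
    """
    if denominator == 0:
        warnings.warn("rate() with zero denominator; reporting 0", stacklevel=2)
        return 0.0
    pct = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def classify_event(
    event: DVEvent,
    mentions: Sequence[Mention],
    linked: Mapping[tuple[str, Role], Sequence[HospitalRecord]],
) -> EventPair:
    """Build both roles' group sets from mentions and linked records."""
    parts = {}
    for role in Role:
        m_groups = frozenset(
            m.level1_group for m in mentions if m.event_id == event.event_id and m.role is role
        )
        h_groups = frozenset(
            r.level1_group
            for r in linked.get((event.event_id, role), ())
            if r.level1_group is not None
        )
        parts[role] = EventConcordance(event.event_id, role, m_groups, h_groups)
    return EventPair(event.event_id, poi=parts[Role.POI], victim=parts[Role.VICTIM])


def classify_corpus(
    events: Sequence[DVEvent],
    mentions: Sequence[Mention],
    linked: LinkedSets,
) -> list[EventPair]:
    by_event: dict[str, list[Mention]] = {}
    for m in mentions:
        by_event.setdefault(m.event_id, []).append(m)
    return [classify_event(ev, by_event.get(ev.event_id, ()), linked) for ev in events]


@dataclass
class SummaryTables:
    """All summary outputs for one cohort × window.

    ``two_by_two``: event counts per cell (OR-over-roles convention).
    ``per_role_both``/``per_role_agreement``: events where the same individual
    has both a mention and a linked record / a level-1 agreement.
    ``per_group_concordance``: per (group, role), total events with a mention
    of the group, events agreeing on the group, and the rate (zero
    denominators flagged).
    ``mention_only_profile``/``hospital_only_profile``: per-group counts among
    events falling in the corresponding 2×2 cell, with percentages of the
    per-role event counts in that cell.
    """

    n_events: int
    two_by_two: dict[Cell, int]
    per_role_both: dict[Role, int]
    per_role_agreement: dict[Role, int]
    per_group_concordance: pd.DataFrame
    mention_only_profile: pd.DataFrame
    hospital_only_profile: pd.DataFrame
    mention_only_role_n: dict[Role, int] = field(default_factory=dict)
    hospital_only_role_n: dict[Role, int] = field(default_factory=dict)

    def two_by_two_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hospital_record": ["yes", "yes", "no", "no"],
                "police_mention": ["yes", "no", "yes", "no"],
                "n_events": [
                    self.two_by_two[Cell.BOTH],
                    self.two_by_two[Cell.HOSPITAL_ONLY],
                    self.two_by_two[Cell.MENTION_ONLY],
                    self.two_by_two[Cell.NEITHER],
                ],
            }
        )

    def write(self, outdir: Union[str, Path]) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.two_by_two_frame().to_csv(outdir / "table_2x2.csv", index=False)
        self.per_group_concordance.to_csv(
            outdir / "table_concordance_by_group.csv", index=False
        )
        self.mention_only_profile.to_csv(outdir / "table_mention_only.csv", index=False)
        self.hospital_only_profile.to_csv(outdir / "table_hospital_only.csv", index=False)


def tabulate(pairs: Sequence[EventPair]) -> SummaryTables:
    """Aggregate per-event concordance into the cohort summary tables."""
    two = {c: 0 for c in Cell}
    role_both = {r: 0 for r in Role}
    role_agree = {r: 0 for r in Role}
    # per (group, role): [events with mention of group, events agreeing on group]
    conc: dict[tuple[str, Role], list[int]] = {
        (g, r): [0, 0] for g in LEVEL1_GROUPS for r in Role
    }
    m_only: dict[tuple[str, Role], int] = {(g, r): 0 for g in LEVEL1_GROUPS for r in Role}
    h_only: dict[tuple[str, Role], int] = {(g, r): 0 for g in LEVEL1_GROUPS for r in Role}
    m_only_role_n = {r: 0 for r in Role}
    h_only_role_n = {r: 0 for r in Role}

    for pair in pairs:
        two[pair.event_cell] += 1
        for role in Role:
            ec = pair.for_role(role)
            if ec.cell is Cell.BOTH:
                role_both[role] += 1
            if ec.agreement:
                role_agree[role] += 1
            for g in ec.mention_groups:
                conc[(g, role)][0] += 1
            for g in ec.matched_groups:
                conc[(g, role)][1] += 1
        if pair.event_cell is Cell.MENTION_ONLY:
            for role in Role:
                ec = pair.for_role(role)
                if ec.mention_groups:
                    m_only_role_n[role] += 1
                for g in ec.mention_groups:
                    m_only[(g, role)] += 1
        elif pair.event_cell is Cell.HOSPITAL_ONLY:
            for role in Role:
                ec = pair.for_role(role)
                if ec.hospital_groups:
                    h_only_role_n[role] += 1
                for g in ec.hospital_groups:
                    h_only[(g, role)] += 1

    conc_rows = []
    for g in LEVEL1_GROUPS:
        for role in Role:
            total, agree = conc[(g, role)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pct = rate(agree, total)
            conc_rows.append(
                {
                    "level1_group": g,
                    "role": role.value,
                    "total_with_mention": total,
                    "n_concordant": agree,
                    "concordance_rate_pct": pct,
                    "zero_denominator": total == 0,
                }
            )

    def profile_frame(counts, role_n):
        rows = []
        for g in LEVEL1_GROUPS:
            for role in Role:
                n = counts[(g, role)]
                denom = role_n[role]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pct = rate(n, denom)
                rows.append(
                    {
                        "level1_group": g,
                        "role": role.value,
                        "n_events": n,
                        "pct_of_role": pct,
                        "zero_denominator": denom == 0,
                    }
                )
        return pd.DataFrame(rows)

    return SummaryTables(
        n_events=len(pairs),
        two_by_two=two,
        per_role_both=role_both,
        per_role_agreement=role_agree,
        per_group_concordance=pd.DataFrame(conc_rows),
        mention_only_profile=profile_frame(m_only, m_only_role_n),
        hospital_only_profile=profile_frame(h_only, h_only_role_n),
        mention_only_role_n=m_only_role_n,
        hospital_only_role_n=h_only_role_n,
    )
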