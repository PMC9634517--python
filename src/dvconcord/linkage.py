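"""Linkage of events to hospital records by person ID and temporal window.

Identity resolution is assumed done upstream (the person ID is an opaque
exact-match key), so linkage is an exact join on person ID restricted by a
window around the event date:

* ``MONTHS`` windows are symmetric calendar-month intervals (±1/3/6/12
  months); by default a record links when its admission interval
  [start_date, end_date] intersects the closed window, with calendar-month
  shifting and day-of-month clamping (Jan 31 − 1 month → Dec 31).
* ``HOURS`` windows support the 48-hour sub-analysis: forward-looking from
  the event date at start of day, testing the admission start only.
* ``NONE`` lifts the temporal restriction entirely.

Records whose diagnosis codes cannot be harmonized to a level-1 ICD-10 group
are excluded and counted, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from datetime import date, datetime, timedelta
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from dateutil.relativedelta import relativedelta

from .extraction import DVEvent, Role
from .lexicon import Crosswalk, Hierarchy, Scheme

logger = logging.getLogger(__name__)

__all__ = [
    "Source",
    "HospitalRecord",
    "WindowKind",
    "WindowSpec",
    "in_window",
    "link_events",
    "harmonize_records",
    "load_hospital_records",
    "write_hospital_records",
    "write_linked",
]


class Source(str, Enum):
    APDC = "APDC"  # admitted patients: ICD-10 only
    EDDC = "EDDC"  # emergency departments: ICD-10, ICD-9 or SNOMED-CT


@dataclass(frozen=True)
class HospitalRecord:
    """One admission/presentation with a mental-health diagnosis code."""

    person_id: str
    source: Source
    start_date: date
    end_date: date
    raw_code: str
    scheme: Scheme
    level1_group: Optional[str] = None  # filled by harmonization

    def __post_init__(self):
        if self.end_date < self.start_date:
            raise ValueError(
                f"record for {self.person_id}: end_date {self.end_date} "
                f"before start_date {self.start_date}"
            )
        if self.source is Source.APDC and self.scheme is not Scheme.ICD10:
            raise ValueError(
                f"record for {self.person_id}: APDC records must be ICD-10 coded, "
                f"got {self.scheme.value}"
            )


class WindowKind(str, Enum):
    NONE = "NONE"
    MONTHS = "MONTHS"
    HOURS = "HOURS"


@dataclass(frozen=True)
class WindowSpec:
    """Temporal eligibility window around the event date.

    MONTHS windows are symmetric (before == after); HOURS windows are
    forward-looking (before == 0).
    """

    kind: WindowKind
    before: int = 0
    after: int = 0

    def __post_init__(self):
        if self.before < 0 or self.after < 0:
            raise ValueError("window widths must be nonnegative")

    @classmethod
    def months(cls, n: int) -> "WindowSpec":
        return cls(WindowKind.MONTHS, before=n, after=n)

    @classmethod
    def hours(cls, n: int) -> "WindowSpec":
        return cls(WindowKind.HOURS, before=0, after=n)

    @classmethod
    def none(cls) -> "WindowSpec":
        return cls(WindowKind.NONE)

    @property
    def label(self) -> str:
        if self.kind is WindowKind.NONE:
            return "none"
        if self.kind is WindowKind.MONTHS:
            return f"{self.after}m"
        return f"{self.after}h"

    @classmethod
    def from_label(cls, label: str) -> "WindowSpec":
        label = str(label).strip().lower()
        if label in ("none", "no", ""):
            return cls.none()
        if label.endswith("m"):
            return cls.months(int(label[:-1]))
        if label.endswith("h"):
            return cls.hours(int(label[:-1]))
        raise ValueError(f"unrecognized window label {label!r}")


def in_window(
    event_date: date,
    record: HospitalRecord,
    window: WindowSpec,
    *,
    semantics: str = "overlap",
) -> bool:
    """Window-membership test (closed endpoints).

    With ``semantics="overlap"`` (default) a MONTHS window admits any record
    whose [start_date, end_date] interval intersects
    [event − before months, event + after months]; with ``semantics="start"``
    only the admission start date is tested.  HOURS windows always test the
    start date, treating dates as midnight timestamps.
    """
    if window.kind is WindowKind.NONE:
        return True
    if window.kind is WindowKind.HOURS:
        lo = datetime.combine(event_date, datetime.min.time())
        hi = lo + timedelta(hours=window.after)
        start = datetime.combine(record.start_date, datetime.min.time())
        return lo <= start <= hi
    lo = event_date - relativedelta(months=window.before)
    hi = event_date + relativedelta(months=window.after)
    if semantics == "start":
        return lo <= record.start_date <= hi
    return record.start_date <= hi and record.end_date >= lo


def harmonize_records(
    records: Sequence[HospitalRecord],
    crosswalk: Crosswalk,
    hierarchy: Hierarchy,
) -> tuple[list[HospitalRecord], int]:
    """Fill ``level1_group`` on each record; return (kept, n_unmappable).

    A record is unmappable when its raw code has no crosswalk row (for ICD-9/
    SNOMED schemes) or its ICD-10 code falls outside the level-1 map.
    """
    kept: list[HospitalRecord] = []
    dropped = 0
    for rec in records:
        icd10 = crosswalk.convert(rec.raw_code, rec.scheme)
        group = hierarchy.roll_up(icd10) if icd10 is not None else None
        if group is None:
            dropped += 1
            continue
        kept.append(replace(rec, level1_group=group))
    if dropped:
        logger.info("excluded %d unmappable hospital record(s)", dropped)
    return kept, dropped


LinkedSets = dict[tuple[str, Role], list[HospitalRecord]]


def link_events(
    events: Sequence[DVEvent],
    records: Sequence[HospitalRecord],
    window: WindowSpec,
    *,
    semantics: str = "overlap",
) -> LinkedSets:
    """Per-event, per-role linked record sets (exact person-ID join + window).

    Every (event_id, role) key is present, possibly with an empty list.
    Records must already be harmonized (``level1_group`` filled).
    """
    by_person: dict[str, list[HospitalRecord]] = {}
    for rec in records:
        if rec.level1_group is None:
            raise ValueError("link_events requires harmonized records")
        by_person.setdefault(rec.person_id, []).append(rec)

    linked: LinkedSets = {}
    for ev in events:
        for role, pid in ((Role.POI, ev.poi_id), (Role.VICTIM, ev.victim_id)):
            linked[(ev.event_id, role)] = [
                r
                for r in by_person.get(pid, ())
                if in_window(ev.event_date, r, window, semantics=semantics)
            ]
    return linked


# ---------------------------------------------------------------------------
# Delimited-text I/O

HOSPITAL_COLUMNS = ["person_id", "source", "start_date", "end_date", "raw_code", "scheme"]
LINKED_COLUMNS = ["event_id", "role", "person_id", "record_index", "level1_group", "start_date"]


def load_hospital_records(path: Union[str, Path]) -> list[HospitalRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != HOSPITAL_COLUMNS:
        raise ValueError(f"hospital header must be {HOSPITAL_COLUMNS}, got {list(df.columns)}")
    return [
        HospitalRecord(
            person_id=r.person_id,
            source=Source(r.source),
            start_date=date.fromisoformat(r.start_date),
            end_date=date.fromisoformat(r.end_date),
            raw_code=r.raw_code,
            scheme=Scheme(r.scheme),
        )
        for r in df.itertuples()
    ]


def write_hospital_records(
    records: Sequence[HospitalRecord], path: Union[str, Path]
) -> None:
    pd.DataFrame(
        [
            {
                "person_id": r.person_id,
                "source": r.source.value,
                "start_date": r.start_date.isoformat(),
                "end_date": r.end_date.isoformat(),
                "raw_code": r.raw_code,
                "scheme": r.scheme.value,
            }
            for r in records
        ],
        columns=HOSPITAL_COLUMNS,
    ).to_csv(path, index=False)


def write_linked(linked: LinkedSets, path: Union[str, Path]) -> None:
    rows = []
    for (event_id, role), recs in sorted(linked.items(), key=lambda kv: (kv[0][0], kv[0][1].value)):
        for i, r in enumerate(recs):
            rows.append(
                {
                    "event_id": event_id,
                    "role": role.value,
                    "person_id": r.person_id,
                    "record_index": i,
                    "level1_group": r.level1_group,
                    "start_date": r.start_date.isoformat(),
                }
            )
    pd.DataFrame(rows, columns=LINKED_COLUMNS).to_csv(path, index=False)
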