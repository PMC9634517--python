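import random
from datetime import date, timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_in_window, shift_months
from dvconcord.extraction import DVEvent
from dvconcord.lexicon import Scheme
from dvconcord.linkage import (
    HospitalRecord,
    Source,
    WindowSpec,
    harmonize_records,
    in_window,
    link_events,
)
from dvconcord.synthetic import CohortConfig, generate_cohort


def rec(start, end, person="P1", code="F32.9", scheme=Scheme.ICD10, group="Mood (affective) disorders"):
    return HospitalRecord(person, Source.EDDC, start, end, code, scheme, level1_group=group)


class TestHospitalRecordInvariants:
    def test_end_before_start_rejected(self):
        with pytest.raises(ValueError, match="before start_date"):
            rec(date(2010, 5, 2), date(2010, 5, 1))

    def test_apdc_must_be_icd10(self):
        with pytest.raises(ValueError, match="APDC"):
            HospitalRecord("P1", Source.APDC, date(2010, 1, 1), date(2010, 1, 2), "311", Scheme.ICD9)


class TestInWindow:
    def test_admission_inside_wide_window(self):
        r = rec(date(2010, 6, 20), date(2010, 6, 21))
        assert in_window(date(2010, 6, 15), r, WindowSpec.months(12))

    def test_closed_upper_endpoint(self):
        ev = date(2010, 6, 15)
        assert in_window(ev, rec(date(2011, 6, 15), date(2011, 6, 15)), WindowSpec.months(12))
        assert not in_window(ev, rec(date(2011, 6, 16), date(2011, 6, 16)), WindowSpec.months(12))

    def test_month_end_clamping(self):
        # event Jan 31, 1-month window: lower bound Dec 31
        ev = date(2010, 1, 31)
        assert in_window(ev, rec(date(2009, 12, 31), date(2009, 12, 31)), WindowSpec.months(1))
        assert not in_window(ev, rec(date(2009, 12, 29), date(2009, 12, 30)), WindowSpec.months(1))

    def test_overlap_vs_start_semantics(self):
        # admission starts before the window but spans into it
        ev = date(2010, 6, 15)
        r = rec(date(2010, 5, 10), date(2010, 5, 20))
        assert in_window(ev, r, WindowSpec.months(1), semantics="overlap")
        assert not in_window(ev, r, WindowSpec.months(1), semantics="start")

    def test_none_window_admits_everything(self):
        r = rec(date(1999, 1, 1), date(1999, 1, 1))
        assert in_window(date(2010, 6, 15), r, WindowSpec.none())

    def test_48h_window_is_forward_looking_start_only(self):
        ev = date(2010, 6, 15)
        w = WindowSpec.hours(48)
        assert in_window(ev, rec(date(2010, 6, 15), date(2010, 6, 16)), w)
        assert in_window(ev, rec(date(2010, 6, 17), date(2010, 6, 18)), w)
        assert not in_window(ev, rec(date(2010, 6, 18), date(2010, 6, 19)), w)
        # pre-event admission overlapping the event date does not count
        assert not in_window(ev, rec(date(2010, 6, 14), date(2010, 6, 20)), w)

    @settings(max_examples=300, derandomize=True)
    @given(
        event=st.dates(min_value=date(2006, 1, 1), max_value=date(2015, 12, 31)),
        offset=st.integers(min_value=-800, max_value=800),
        duration=st.integers(min_value=0, max_value=10),
        months=st.sampled_from([1, 3, 6, 12]),
    )
    def test_agrees_with_day_enumeration_oracle(self, event, offset, duration, months):
        start = event + timedelta(days=offset)
        r = rec(start, start + timedelta(days=duration))
        assert in_window(event, r, WindowSpec.months(months)) == brute_force_in_window(
            event, start, r.end_date, months
        )


class TestWindowSpec:
    def test_labels_roundtrip(self):
        for label in ("1m", "3m", "6m", "12m", "48h", "none"):
            assert WindowSpec.from_label(label).label == label

    def test_symmetric_months(self):
        w = WindowSpec.months(6)
        assert w.before == w.after == 6

    def test_negative_width_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec.months(-1)


class TestLinkEvents:
    def make_fixture(self):
        ev = DVEvent("E1", date(2010, 6, 15), "P1", "V1", "narrative.")
        records = [
            rec(date(2010, 6, 20), date(2010, 6, 21), person="P1"),
            rec(date(2011, 1, 10), date(2011, 1, 12), person="V1"),
            rec(date(2010, 6, 16), date(2010, 6, 16), person="STRANGER"),
        ]
        return ev, records

    def test_unrelated_person_links_to_nothing(self):
        ev, records = self.make_fixture()
        linked = link_events([ev], records, WindowSpec.none())
        all_people = {r.person_id for recs in linked.values() for r in recs}
        assert "STRANGER" not in all_people

    def test_roles_get_their_own_records(self):
        from dvconcord.extraction import Role

        ev, records = self.make_fixture()
        linked = link_events([ev], records, WindowSpec.none())
        assert [r.person_id for r in linked[("E1", Role.POI)]] == ["P1"]
        assert [r.person_id for r in linked[("E1", Role.VICTIM)]] == ["V1"]

    def test_unharmonized_records_rejected(self):
        ev, _ = self.make_fixture()
        bad = HospitalRecord("P1", Source.EDDC, date(2010, 1, 1), date(2010, 1, 2), "311", Scheme.ICD9)
        with pytest.raises(ValueError, match="harmonized"):
            link_events([ev], [bad], WindowSpec.none())

    def test_window_monotonicity_on_cohort(self, lexicon, crosswalk, hierarchy):
        cohort = generate_cohort(CohortConfig(n_events=150, seed=17), lexicon)
        harmonized, _ = harmonize_records(cohort.records, crosswalk, hierarchy)
        sizes = []
        for label in ("1m", "3m", "6m", "12m", "none"):
            linked = link_events(cohort.events, harmonized, WindowSpec.from_label(label))
            sizes.append(sum(len(v) for v in linked.values()))
        assert sizes == sorted(sizes), "widening the window must never shrink linked sets"

    def test_none_window_equals_brute_force_join(self, lexicon, crosswalk, hierarchy):
        cohort = generate_cohort(CohortConfig(n_events=100, seed=23), lexicon)
        harmonized, _ = harmonize_records(cohort.records, crosswalk, hierarchy)
        linked = link_events(cohort.events, harmonized, WindowSpec.none())
        from dvconcord.extraction import Role

        for ev in cohort.events:
            for role, pid in ((Role.POI, ev.poi_id), (Role.VICTIM, ev.victim_id)):
                expected = [r for r in harmonized if r.person_id == pid]
                assert linked[(ev.event_id, role)] == expected


class TestHarmonize:
    def test_unmappable_records_excluded_and_counted(self, crosswalk, hierarchy):
        good = HospitalRecord("P1", Source.EDDC, date(2010, 1, 1), date(2010, 1, 2), "311", Scheme.ICD9)
        bad = HospitalRecord("P2", Source.EDDC, date(2010, 1, 1), date(2010, 1, 2), "999.99", Scheme.ICD9)
        kept, dropped = harmonize_records([good, bad], crosswalk, hierarchy)
        assert dropped == 1
        assert [r.person_id for r in kept] == ["P1"]
        assert kept[0].level1_group == "Mood (affective) disorders"

    def test_generator_truth_recovered(self, lexicon, crosswalk, hierarchy):
        cohort = generate_cohort(CohortConfig(n_events=200, seed=29), lexicon)
        kept, dropped = harmonize_records(cohort.records, crosswalk, hierarchy)
        assert dropped == 0
        assert [r.level1_group for r in kept] == cohort.record_groups
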