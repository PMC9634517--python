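import random

import pytest
from scipy import stats

from dvconcord.concordance import Cell
from dvconcord.extraction import Role, extract_corpus, write_events
from dvconcord.linkage import WindowSpec
from dvconcord.synthetic import (
    CohortConfig,
    generate_cohort,
    expected_tables,
    load_gold,
    write_gold,
)


class TestConfigValidation:
    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="concordant_fraction"):
            CohortConfig(concordant_fraction=1.5)
        with pytest.raises(ValueError, match="mention_prevalence"):
            CohortConfig(mention_prevalence={"POI": -0.1, "VICTIM": 0.1})

    def test_nonpositive_event_count_rejected(self):
        with pytest.raises(ValueError, match="n_events"):
            CohortConfig(n_events=0)

    def test_group_weights_normalized(self):
        cfg = CohortConfig(
            group_weights={
                "POI": {"mood": 2.0, "anxiety": 2.0},
                "VICTIM": {"mood": 1.0},
            }
        )
        assert sum(cfg.group_weights["POI"].values()) == pytest.approx(1.0)
        assert cfg.group_weights["POI"]["mood"] == pytest.approx(0.5)


class TestGenerateCohort:
    def test_same_seed_gives_byte_identical_outputs(self, lexicon, tmp_path):
        cfg = CohortConfig(n_events=50, seed=99)
        a, b = generate_cohort(cfg, lexicon), generate_cohort(cfg, lexicon)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_events(a.events, pa)
        write_events(b.events, pb)
        assert pa.read_bytes() == pb.read_bytes()
        assert a.records == b.records and a.gold == b.gold

    def test_different_seeds_differ(self, lexicon):
        a = generate_cohort(CohortConfig(n_events=50, seed=1), lexicon)
        b = generate_cohort(CohortConfig(n_events=50, seed=2), lexicon)
        assert a.events != b.events

    def test_dates_inside_configured_range(self, lexicon):
        cfg = CohortConfig(n_events=150, seed=3)
        cohort = generate_cohort(cfg, lexicon)
        d0, d1 = cfg.date_range
        for ev in cohort.events:
            assert d0 <= ev.event_date <= d1
        for rec in cohort.records:
            assert d0 <= rec.start_date <= rec.end_date <= d1

    def test_person_ids_unique_and_reused_consistently(self, lexicon):
        cohort = generate_cohort(CohortConfig(n_events=100, seed=5), lexicon)
        people = set()
        for ev in cohort.events:
            assert ev.poi_id != ev.victim_id
            people.update((ev.poi_id, ev.victim_id))
        assert len(people) == 2 * len(cohort.events)
        for rec in cohort.records:
            assert rec.person_id in people

    def test_mention_count_within_binomial_bounds(self, lexicon):
        # one role at prevalence 0.15: the count is Binomial(1000, 0.15)
        cfg = CohortConfig(
            n_events=1000,
            seed=7,
            mention_prevalence={"POI": 0.15, "VICTIM": 0.0},
        )
        cohort = generate_cohort(cfg, lexicon)
        n_mention_events = len({g.event_id for g in cohort.gold})
        lo = stats.binom.ppf(0.005, 1000, 0.15)
        hi = stats.binom.ppf(0.995, 1000, 0.15)
        assert lo <= n_mention_events <= hi

    def test_gold_phrases_appear_in_narratives(self, lexicon):
        cohort = generate_cohort(CohortConfig(n_events=80, seed=11), lexicon)
        narratives = {ev.event_id: ev.narrative for ev in cohort.events}
        for g in cohort.gold:
            assert g.planted_phrase in narratives[g.event_id]

    def test_zero_concordant_fraction_forces_zero_agreement(self, lexicon):
        cfg = CohortConfig(n_events=300, seed=13, concordant_fraction=0.0)
        cohort = generate_cohort(cfg, lexicon)
        assert all(not g.expected_concordant_at for g in cohort.gold)
        for label in ("1m", "12m", "none"):
            t = expected_tables(cfg, cohort, WindowSpec.from_label(label))
            assert t.per_role_agreement == {Role.POI: 0, Role.VICTIM: 0}


class TestExpectedTables:
    def test_conservation(self, lexicon):
        cfg = CohortConfig(n_events=120, seed=17)
        cohort = generate_cohort(cfg, lexicon)
        t = expected_tables(cfg, cohort, WindowSpec.months(12))
        assert sum(t.two_by_two.values()) == cfg.n_events

    def test_none_window_dominates_every_windowed_both_count(self, lexicon):
        cfg = CohortConfig(n_events=200, seed=19)
        cohort = generate_cohort(cfg, lexicon)
        none_both = expected_tables(cfg, cohort, WindowSpec.none()).two_by_two[Cell.BOTH]
        for label in ("1m", "3m", "6m", "12m"):
            t = expected_tables(cfg, cohort, WindowSpec.from_label(label))
            assert t.two_by_two[Cell.BOTH] <= none_both

    def test_cross_role_events_exceed_same_role_agreement(self, lexicon):
        # with cross-role records on, event-level BOTH strictly exceeds the
        # number of events with same-role agreement
        cfg = CohortConfig(n_events=600, seed=23, cross_role_fraction=0.5)
        cohort = generate_cohort(cfg, lexicon)
        t = expected_tables(cfg, cohort, WindowSpec.none())
        same_role = t.per_role_agreement[Role.POI] + t.per_role_agreement[Role.VICTIM]
        assert t.two_by_two[Cell.BOTH] > same_role

    def test_gold_windows_predict_agreement(self, lexicon):
        # each gold label's expected_concordant_at matches the windows at
        # which expected_tables sees same-role agreement for that group
        cfg = CohortConfig(n_events=150, seed=29, hospital_only_rate={"POI": 0.0, "VICTIM": 0.0},
                           cross_role_fraction=0.0)
        cohort = generate_cohort(cfg, lexicon)
        for label in ("1m", "12m", "none"):
            t = expected_tables(cfg, cohort, WindowSpec.from_label(label))
            expected_agree = {
                r: sum(1 for g in cohort.gold if g.role is r and label in g.expected_concordant_at)
                for r in Role
            }
            assert t.per_role_agreement == expected_agree


class TestGoldIO:
    def test_roundtrip(self, lexicon, tmp_path):
        cohort = generate_cohort(CohortConfig(n_events=40, seed=31), lexicon)
        p = tmp_path / "gold.csv"
        write_gold(cohort.gold, p)
        assert load_gold(p) == cohort.gold


class TestEndToEndRecovery:
    def test_clean_pipeline_reproduces_expected_tables(
        self, lexicon, crosswalk, hierarchy
    ):
        from dvconcord.concordance import classify_corpus, tabulate
        from dvconcord.linkage import harmonize_records, link_events

        cfg = CohortConfig(n_events=250, seed=37, distractor_rate=0.0)
        cohort = generate_cohort(cfg, lexicon)
        mentions, _ = extract_corpus(cohort.events, lexicon)
        harmonized, dropped = harmonize_records(cohort.records, crosswalk, hierarchy)
        assert dropped == 0
        for label in ("1m", "6m", "none"):
            w = WindowSpec.from_label(label)
            got = tabulate(
                classify_corpus(
                    cohort.events, mentions, link_events(cohort.events, harmonized, w)
                )
            )
            want = expected_tables(cfg, cohort, w)
            assert got.two_by_two == want.two_by_two
            assert got.per_role_agreement == want.per_role_agreement
            assert got.per_group_concordance.equals(want.per_group_concordance)
            assert got.mention_only_profile.equals(want.mention_only_profile)
            assert got.hospital_only_profile.equals(want.hospital_only_profile)
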