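"""Independent brute-force re-implementations used as test oracles.

These deliberately avoid the library's own counting code: every
(event, role, group) triple is enumerated directly from the raw group sets.
"""

from decimal import ROUND_HALF_UP, Decimal

from dvconcord.extraction import Role
from dvconcord.lexicon import LEVEL1_GROUPS


def brute_force_tabulate(pairs):
    """Recount all summary tables from EventPair group sets, the slow way."""
    result = {
        "two_by_two": {"BOTH": 0, "MENTION_ONLY": 0, "HOSPITAL_ONLY": 0, "NEITHER": 0},
        "per_role_both": {"POI": 0, "VICTIM": 0},
        "per_role_agreement": {"POI": 0, "VICTIM": 0},
        "per_group": {},   # (group, role) -> [total_with_mention, n_concordant]
        "mention_only": {},  # (group, role) -> count
        "hospital_only": {},
        "mention_only_role_n": {"POI": 0, "VICTIM": 0},
        "hospital_only_role_n": {"POI": 0, "VICTIM": 0},
    }
    for g in LEVEL1_GROUPS:
        for r in ("POI", "VICTIM"):
            result["per_group"][(g, r)] = [0, 0]
            result["mention_only"][(g, r)] = 0
            result["hospital_only"][(g, r)] = 0

    for pair in pairs:
        sets = {}
        for role in Role:
            ec = pair.for_role(role)
            sets[role.value] = (set(ec.mention_groups), set(ec.hospital_groups))
        m_any = bool(sets["POI"][0] | sets["VICTIM"][0])
        h_any = bool(sets["POI"][1] | sets["VICTIM"][1])
        if m_any and h_any:
            cell = "BOTH"
        elif m_any:
            cell = "MENTION_ONLY"
        elif h_any:
            cell = "HOSPITAL_ONLY"
        else:
            cell = "NEITHER"
        result["two_by_two"][cell] += 1

        for r in ("POI", "VICTIM"):
            ment, hosp = sets[r]
            if ment and hosp:
                result["per_role_both"][r] += 1
            if ment & hosp:
                result["per_role_agreement"][r] += 1
            for g in LEVEL1_GROUPS:
                if g in ment:
                    result["per_group"][(g, r)][0] += 1
                    if g in hosp:
                        result["per_group"][(g, r)][1] += 1
            if cell == "MENTION_ONLY":
                if ment:
                    result["mention_only_role_n"][r] += 1
                for g in ment:
                    result["mention_only"][(g, r)] += 1
            if cell == "HOSPITAL_ONLY":
                if hosp:
                    result["hospital_only_role_n"][r] += 1
                for g in hosp:
                    result["hospital_only"][(g, r)] += 1
    return result


def brute_force_rate(num, den):
    if den == 0:
        return 0.0
    return float(
        (Decimal(100) * Decimal(num) / Decimal(den)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def assert_tables_match_oracle(tables, oracle):
    """Field-by-field comparison of a SummaryTables against the oracle dict."""
    assert {c.value: n for c, n in tables.two_by_two.items()} == oracle["two_by_two"]
    assert {r.value: n for r, n in tables.per_role_both.items()} == oracle["per_role_both"]
    assert {r.value: n for r, n in tables.per_role_agreement.items()} == oracle[
        "per_role_agreement"
    ]
    for row in tables.per_group_concordance.itertuples():
        total, agree = oracle["per_group"][(row.level1_group, row.role)]
        assert row.total_with_mention == total
        assert row.n_concordant == agree
        assert row.concordance_rate_pct == brute_force_rate(agree, total)
    for row in tables.mention_only_profile.itertuples():
        n = oracle["mention_only"][(row.level1_group, row.role)]
        assert row.n_events == n
        assert row.pct_of_role == brute_force_rate(n, oracle["mention_only_role_n"][row.role])
    for row in tables.hospital_only_profile.itertuples():
        n = oracle["hospital_only"][(row.level1_group, row.role)]
        assert row.n_events == n
        assert row.pct_of_role == brute_force_rate(n, oracle["hospital_only_role_n"][row.role])
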