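"""Administrative frailty rules: LTC overlap, terminal coding, EFS domains."""

import pandas as pd
import pytest

from frailscan.admin_rules import (
    AdminRuleConfig,
    apply_admin_definition,
    default_admin_config,
    rule_efs_indices,
    rule_ltc,
    rule_terminal,
)
from frailscan.bundle import empty_bundle


def ltc_df(rows):
    return pd.DataFrame([{
        "person_id": r.get("pid", "P1"),
        "start_date": pd.Timestamp(r["start"]),
        "end_date": pd.Timestamp(r["end"]) if r.get("end") else pd.NaT,
        "setting": r.get("setting", "long_term_care"),
    } for r in rows])


def claims_df(rows):
    return pd.DataFrame([{
        "person_id": r.get("pid", "P1"),
        "service_date": pd.Timestamp(r["date"]),
        "icd9_code": r.get("icd9", ""),
        "free_text": "",
        "provider_type": "gp",
        "fee": 0.0,
    } for r in rows])


def hosp_df(rows):
    return pd.DataFrame([{
        "person_id": r.get("pid", "P1"),
        "admit_date": pd.Timestamp(r["date"]),
        "discharge_date": pd.Timestamp(r["date"]),
        "icd10_codes": r["codes"],
        "cost": 0.0,
    } for r in rows])


def rx_df(rows):
    return pd.DataFrame([{
        "person_id": r.get("pid", "P1"),
        "dispense_date": pd.Timestamp(r["date"]),
        "atc_code": r["atc"],
        "source": "admin",
        "cost": 0.0,
    } for r in rows])


EMPTY_CLAIMS = pd.DataFrame(
    columns=["person_id", "service_date", "icd9_code", "free_text",
             "provider_type", "fee"])


class TestRuleLtc:
    def test_episode_entirely_before_year(self):
        assert not rule_ltc(ltc_df([{"start": "2013-01-01", "end": "2013-12-31"}]), 2014)

    def test_open_ended_episode_overlaps(self):
        assert rule_ltc(ltc_df([{"start": "2012-05-01"}]), 2014)

    def test_one_day_overlap_counts(self):
        assert rule_ltc(ltc_df([{"start": "2013-06-01", "end": "2014-01-01"}]), 2014)

    def test_brute_force_day_overlap_oracle(self):
        import random
        from datetime import date, timedelta
        rng = random.Random(7)
        year = {date(2014, 1, 1) + timedelta(days=i) for i in range(365)}
        for _ in range(40):
            s = date(2012, 1, 1) + timedelta(days=rng.randint(0, 1400))
            e = None if rng.random() < 0.3 else s + timedelta(days=rng.randint(0, 900))
            df = ltc_df([{"start": str(s), "end": str(e) if e else None}])
            days = {s + timedelta(days=i)
                    for i in range((e - s).days + 1)} if e else \
                   {s + timedelta(days=i) for i in range(1500)}
            assert rule_ltc(df, 2014) == bool(days & year)


class TestRuleTerminal:
    def test_palliative_hospital_code(self):
        cfg = default_admin_config()
        hosp = hosp_df([{"date": "2014-03-01", "codes": ["Z51.5"]}])
        assert rule_terminal(EMPTY_CLAIMS, hosp, 2014, cfg)

    def test_no_events(self):
        cfg = default_admin_config()
        assert not rule_terminal(EMPTY_CLAIMS, hosp_df([]).reindex(
            columns=["person_id", "admit_date", "discharge_date", "icd10_codes",
                     "cost"]), 2014, cfg)

    def test_code_outside_year(self):
        cfg = default_admin_config()
        hosp = hosp_df([{"date": "2013-03-01", "codes": ["Z51.5"]}])
        assert not rule_terminal(EMPTY_CLAIMS, hosp, 2014, cfg)

    def test_billing_code_v667(self):
        cfg = default_admin_config()
        claims = claims_df([{"date": "2014-06-01", "icd9": "V66.7"}])
        assert rule_terminal(claims, hosp_df([{"date": "2013-01-01",
                                               "codes": ["J18.9"]}]), 2014, cfg)

    def test_empty_code_set_warns_and_never_fires(self):
        cfg = AdminRuleConfig(terminal_icd9=(), terminal_icd10=(),
                              efs_domains=default_admin_config().efs_domains)
        with pytest.warns(UserWarning, match="empty"):
            assert not rule_terminal(
                claims_df([{"date": "2014-06-01", "icd9": "V66.7"}]),
                hosp_df([{"date": "2014-01-01", "codes": ["Z51.5"]}]), 2014, cfg)


class TestRuleEfs:
    def test_repeated_events_one_domain_count_once(self):
        cfg = default_admin_config()
        claims = claims_df([{"date": "2014-01-05", "icd9": "V15.88"},
                            {"date": "2014-07-01", "icd9": "781.2"}])
        ok, count, domains = rule_efs_indices(claims, rx_df([]).reindex(
            columns=["person_id", "dispense_date", "atc_code", "source", "cost"]),
            2014, cfg)
        assert count == 1 and domains == ["falls_mobility"] and not ok

    def test_cognition_plus_polypharmacy(self):
        cfg = default_admin_config()
        claims = claims_df([{"date": "2014-02-01", "icd9": "290.0"}])
        rx = rx_df([{"date": f"2014-0{m}-01", "atc": atc} for m, atc in
                    enumerate(["A02BC01", "B01AC06", "C07AB02", "C09AA05",
                               "C10AA01", "N02BE01"], start=1)])
        ok, count, domains = rule_efs_indices(claims, rx, 2014, cfg)
        assert ok and count == 2 and set(domains) == {"cognition", "polypharmacy"}

    def test_five_distinct_meds_not_polypharmacy(self):
        cfg = default_admin_config()
        rx = rx_df([{"date": "2014-03-01", "atc": a}
                    for a in ["A02BC01", "B01AC06", "C07AB02", "C09AA05", "C10AA01"]
                    ] * 3)
        ok, count, domains = rule_efs_indices(EMPTY_CLAIMS, rx, 2014, cfg)
        assert count == 0

    def test_all_coded_domains_fire(self):
        cfg = default_admin_config()
        codes = ["290.0", "300.0", "788.3", "V15.88", "783.2", "797", "V60.4"]
        claims = claims_df([{"date": "2014-05-01", "icd9": c} for c in codes])
        _, count, domains = rule_efs_indices(claims, rx_df([]).reindex(
            columns=["person_id", "dispense_date", "atc_code", "source", "cost"]),
            2014, cfg)
        assert count == 7  # every coded domain; polypharmacy needs prescriptions

    def test_duplication_invariance(self):
        cfg = default_admin_config()
        claims = claims_df([{"date": "2014-02-01", "icd9": "290.0"},
                            {"date": "2014-04-01", "icd9": "783.2"}])
        doubled = pd.concat([claims, claims], ignore_index=True)
        empty_rx = rx_df([]).reindex(columns=["person_id", "dispense_date",
                                              "atc_code", "source", "cost"])
        assert rule_efs_indices(claims, empty_rx, 2014, cfg)[1] == \
            rule_efs_indices(doubled, empty_rx, 2014, cfg)[1]


class TestApplyAdminDefinition:
    def test_matches_or_of_single_rules(self, sim_small, cohort, admin_calls):
        """Bulk evaluation equals per-person brute force over the three rules."""
        _, admin, _ = sim_small
        cfg = default_admin_config()
        by_person = {t: dict(list(df.groupby("person_id")))
                     for t, df in (("claims", admin.claims),
                                   ("hospitals", admin.hospitals),
                                   ("ltc", admin.ltc),
                                   ("rx", admin.prescriptions))}
        empty = {t: getattr(empty_bundle("admin"), n)
                 for t, n in (("claims", "claims"), ("hospitals", "hospitals"),
                              ("ltc", "ltc"), ("rx", "prescriptions"))}
        for rec in admin_calls.itertuples(index=False):
            pid = rec.person_id
            claims = by_person["claims"].get(pid, empty["claims"])
            hosp = by_person["hospitals"].get(pid, empty["hospitals"])
            ltc = by_person["ltc"].get(pid, empty["ltc"])
            rx = by_person["rx"].get(pid, empty["rx"])
            expected = (rule_ltc(ltc, 2014)
                        or rule_terminal(claims, hosp, 2014, cfg)
                        or rule_efs_indices(claims, rx, 2014, cfg)[0])
            assert rec.frail == expected, pid

    def test_evidence_names_fired_rules(self, admin_calls):
        frail = admin_calls[admin_calls["frail"]]
        assert all(len(ev) >= 1 for ev in frail["evidence"])
        ltc_only = admin_calls[admin_calls["rule_ltc"]
                               & ~admin_calls["rule_terminal"]
                               & ~admin_calls["rule_efs"]]
        if len(ltc_only):
            assert ltc_only["evidence"].iloc[0][0][0] == "rule_ltc"

    def test_or_monotone_under_added_events(self, admin_calls):
        """frail is the OR of the rule booleans — adding events can only add."""
        assert (admin_calls["frail"] == (admin_calls["rule_ltc"]
                                         | admin_calls["rule_terminal"]
                                         | admin_calls["rule_efs"])).all()
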