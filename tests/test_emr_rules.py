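"""EMR case-definition engine: atoms, windows, expression equivalence."""

import itertools
from datetime import date

import pandas as pd
import pytest
from hypothesis import given, strategies as st

from frailscan.bundle import empty_bundle
from frailscan.emr_rules import (
    Atom,
    CaseDefinition,
    apply_emr_definition,
    default_definition,
    evaluate_atom,
    evaluate_expression,
    lookback_window,
)

from conftest import persons_row

WINDOW = lookback_window(2014, 6)


def claims_df(rows):
    return pd.DataFrame([{
        "person_id": r.get("pid", "P1"),
        "service_date": pd.Timestamp(r.get("date", "2014-01-01")),
        "icd9_code": r.get("icd9", ""),
        "free_text": r.get("text", ""),
        "provider_type": "gp",
        "fee": 0.0,
    } for r in rows])


def rx_df(rows):
    return pd.DataFrame([{
        "person_id": r.get("pid", "P1"),
        "dispense_date": pd.Timestamp(r.get("date", "2014-01-01")),
        "atc_code": r["atc"],
        "source": "emr",
        "cost": 0.0,
    } for r in rows])


class TestAtoms:
    def test_dementia_code_inside_window(self):
        fired, ev = evaluate_atom(Atom("icd9_prefix", ("290",)),
                                  {"claims": claims_df([{"icd9": "290.0",
                                                         "date": "2011-05-02"}])},
                                  lookback_window(2014, 6))
        assert fired
        assert ev[0] == (date(2011, 5, 2), "290.0")

    def test_no_events_no_evidence(self):
        fired, ev = evaluate_atom(Atom("icd9_prefix", ("290",)), {}, WINDOW)
        assert not fired and ev == []

    def test_window_excludes_old_events(self):
        fired, _ = evaluate_atom(Atom("icd9_prefix", ("290",)),
                                 {"claims": claims_df([{"icd9": "290.0",
                                                        "date": "2008-12-31"}])},
                                 lookback_window(2014, 6))
        assert not fired

    def test_prefix_matching_dot_insensitive(self):
        fired, _ = evaluate_atom(Atom("icd9_prefix", ("290.4",)),
                                 {"claims": claims_df([{"icd9": "290.41"}])}, WINDOW)
        assert fired

    def test_atc_prefix(self):
        assert evaluate_atom(Atom("atc_prefix", ("A11",)),
                             {"prescriptions": rx_df([{"atc": "A11GA01"}])}, WINDOW)[0]
        assert not evaluate_atom(Atom("atc_prefix", ("A11",)),
                                 {"prescriptions": rx_df([{"atc": "A10BA02"}])},
                                 WINDOW)[0]

    @pytest.mark.parametrize("text,expected", [
        ("bowel OBSTRUCTION f/u", True),
        ("obstruction", True),
        ("obstructive sleep apnea", False),   # whole-token: no substring firing
        ("pseudoobstruction", False),
        ("small-bowel obstruction; resolved", True),
        ("", False),
    ])
    def test_keyword_whole_token(self, text, expected):
        fired, _ = evaluate_atom(Atom("text_keyword", ("obstruction",)),
                                 {"claims": claims_df([{"text": text}])}, WINDOW)
        assert fired == expected

    def test_unknown_atom_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            Atom("regex", ("x",))


class TestDefaultDefinition:
    def test_structure(self):
        d = default_definition()
        assert set(d.atoms) == {"dementia", "vitamins", "furosemide", "obstruction"}
        assert d.lookback_years == 6

    def test_vitamins_alone_insufficient(self):
        d = default_definition()
        values = {"dementia": False, "vitamins": True, "furosemide": False,
                  "obstruction": False}
        assert not evaluate_expression(d.expression, values)

    def test_dementia_alone_sufficient(self):
        d = default_definition()
        values = {"dementia": True, "vitamins": False, "furosemide": False,
                  "obstruction": False}
        assert evaluate_expression(d.expression, values)

    def test_vitamins_and_furosemide_sufficient(self):
        d = default_definition()
        values = {"dementia": False, "vitamins": True, "furosemide": True,
                  "obstruction": False}
        assert evaluate_expression(d.expression, values)

    def test_default_truth_table_oracle(self):
        """Engine output equals the hand expression over all 16 assignments."""
        d = default_definition()
        for bits in itertools.product([False, True], repeat=4):
            vals = dict(zip(["dementia", "vitamins", "furosemide", "obstruction"],
                            bits))
            expected = vals["dementia"] or (vals["vitamins"]
                                            and vals["furosemide"]) \
                or vals["obstruction"]
            assert evaluate_expression(d.expression, vals) == expected


# random expression trees over k named atoms
def expr_strategy(names):
    leaf = st.sampled_from(names)
    return st.recursive(
        leaf,
        lambda children: st.one_of(
            st.lists(children, min_size=1, max_size=3).map(lambda xs: ["and", *xs]),
            st.lists(children, min_size=1, max_size=3).map(lambda xs: ["or", *xs]),
            children.map(lambda x: ["not", x]),
        ),
        max_leaves=12)


def brute_eval(expr, values):
    if isinstance(expr, str):
        return values[expr]
    op, *args = expr
    results = [brute_eval(a, values) for a in args]
    if op == "and":
        return all(results)
    if op == "or":
        return any(results)
    return not results[0]


@given(expr=expr_strategy([f"a{i}" for i in range(6)]))
def test_expression_engine_equals_brute_force(expr):
    """All 2^k assignments agree with an independent recursive evaluator."""
    names = [f"a{i}" for i in range(6)]
    for bits in itertools.product([False, True], repeat=6):
        values = dict(zip(names, bits))
        assert evaluate_expression(expr, values) == brute_eval(expr, values)


def test_expression_validation():
    atoms = {"a": Atom("icd9_prefix", ("1",))}
    with pytest.raises(ValueError, match="undeclared"):
        CaseDefinition(atoms=atoms, expression=["or", "a", "b"])
    with pytest.raises(ValueError, match="operator"):
        CaseDefinition(atoms=atoms, expression=["xor", "a"])


class TestApplyDefinition:
    @pytest.fixture()
    def tiny_setup(self):
        b = empty_bundle("emr")
        b.persons = pd.DataFrame([
            persons_row("P1", "1"), persons_row("P2", "2"), persons_row("P3", "3"),
        ])
        b.claims = claims_df([
            {"pid": "P1", "icd9": "290.0", "date": "2012-03-01"},
            {"pid": "P3", "text": "obstruction noted", "date": "2014-02-01"},
        ])
        b.prescriptions = rx_df([
            {"pid": "P2", "atc": "A11GA01", "date": "2013-01-01"},
        ])
        cohort = pd.DataFrame({
            "emr_person_id": ["P1", "P2", "P3"],
            "admin_person_id": ["A1", "A2", "A3"],
            "scrambled_id": ["S1", "S2", "S3"],
            "age_on_jan1": [80, 80, 80],
            "coverage_fraction": [1.0, 1.0, 1.0],
            "included": [True, True, True],
            "exclusion_reason": ["none"] * 3,
        })
        return b, cohort

    def test_calls_and_evidence(self, tiny_setup):
        b, cohort = tiny_setup
        calls = apply_emr_definition(default_definition(), b, cohort, 2014)
        by_id = calls.set_index("person_id")
        assert bool(by_id.loc["P1", "frail"])          # dementia claim
        assert not bool(by_id.loc["P2", "frail"])      # vitamins alone
        assert bool(by_id.loc["P3", "frail"])          # obstruction keyword
        assert by_id.loc["P1", "evidence"][0][0] == "dementia"
        assert by_id.loc["P2", "evidence"]             # vitamins fired, not frail
        assert all(e[1] is None or e[1] >= date(2009, 1, 1)
                   for ev in calls["evidence"] for e in ev)

    def test_frail_implies_evidence(self, sim_small, cohort, emr_calls):
        frail = emr_calls[emr_calls["frail"]]
        assert all(len(ev) > 0 for ev in frail["evidence"])

    def test_monotonicity_adding_events(self, tiny_setup):
        """Adding a dementia claim never flips frail → not frail."""
        b, cohort = tiny_setup
        before = apply_emr_definition(default_definition(), b, cohort, 2014)
        extra = claims_df([{"pid": "P2", "icd9": "290.0", "date": "2013-05-01"}])
        b.claims = pd.concat([b.claims, extra], ignore_index=True)
        after = apply_emr_definition(default_definition(), b, cohort, 2014)
        assert (before["frail"] <= after["frail"]).all()
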