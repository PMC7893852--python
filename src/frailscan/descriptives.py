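"""Mutually exclusive frailty groups and descriptive/utilization tables.

Cohort members are partitioned into four groups by the two case definitions
— frail in the EMR only, frail in the administrative data only, frail in
both, or neither — and summarized the way the published tables are laid
out: index-year characteristics (age bands, sex, dichotomized neighborhood
income, rurality, recent blood pressure and BMI, chronic-condition bands
per source) and next-year utilization (GP contacts, costs by category,
hospitalizations per 100, hospital days, polypharmacy, deaths).

Percentages and means are reported to one decimal using round-half-away-
from-zero, matching conventional table formatting.  Utilization denominators
exclude persons who died during the index year.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from ._codes import POSTAL_RE
from .bundle import SourceBundle

__all__ = [
    "GROUPS",
    "SummaryTable",
    "assign_groups",
    "rural_flag",
    "mean_recent_bp",
    "polypharmacy_flag",
    "build_person_table",
    "summarize",
    "group_compare",
    "round1",
    "percent",
]

GROUPS = ("emr_only", "admin_only", "both", "neither")

AGE_BANDS = ("65-74", "75-84", "85+")

POLYPHARMACY_THRESHOLD = 5  # "more than 5 prescribed medications"

_CATEGORICAL_BLOCKS = {
    "age_band": AGE_BANDS,
    "sex": ("female", "male"),
    "income": ("high", "low"),
    "location": ("rural", "urban"),
    "conditions_emr": ("0-1", "2", "3+"),
    "conditions_admin": ("0-1", "2", "3+"),
}

_CONTINUOUS_CHARACTERISTICS = ("systolic_bp", "diastolic_bp", "bmi")

_UTILIZATION_CONTINUOUS = (
    "gp_contacts", "gp_cost", "specialist_cost", "physician_cost",
    "hospital_cost", "rx_cost", "hospitalizations_per_100", "hospital_days",
)
_UTILIZATION_BINARY = ("polypharmacy", "died_next_year")


def round1(x: float) -> float:
    """Round to 1 decimal, halves away from zero (table convention)."""
    if pd.isna(x):
        return float("nan")
    d = Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP) \
        if x >= 0 else -Decimal(repr(float(-x))).quantize(Decimal("0.1"),
                                                          rounding=ROUND_HALF_UP)
    return float(d)


def percent(count: int, denom: int) -> float:
    """Table percentage: 100·count/denom rounded to one decimal."""
    if denom == 0:
        return float("nan")
    return round1(100.0 * count / denom)


def rural_flag(postal_code: str) -> str:
    """Rural iff the second character of the forward sortation area is '0'."""
    if not isinstance(postal_code, str) or not POSTAL_RE.match(postal_code.upper()):
        raise ValueError(f"malformed postal code {postal_code!r}")
    return "rural" if postal_code[1] == "0" else "urban"


def assign_groups(emr_calls: pd.DataFrame, admin_calls: pd.DataFrame,
                  cohort: pd.DataFrame) -> pd.DataFrame:
    """Partition included cohort members into the four exclusive groups."""
    included = cohort[cohort["included"]]
    ids = set(included["scrambled_id"])
    for name, calls in (("emr", emr_calls), ("admin", admin_calls)):
        got = set(calls["scrambled_id"])
        if got != ids:
            missing = sorted(ids ^ got)[:5]
            raise ValueError(f"{name} call list does not cover the cohort exactly "
                             f"(symmetric difference starts {missing})")
    emr_frail = emr_calls.set_index("scrambled_id")["frail"]
    admin_frail = admin_calls.set_index("scrambled_id")["frail"]
    rows = []
    for sid in included["scrambled_id"]:
        e, a = bool(emr_frail[sid]), bool(admin_frail[sid])
        group = "both" if e and a else "emr_only" if e else "admin_only" if a else "neither"
        rows.append({"scrambled_id": sid, "group": group})
    return pd.DataFrame(rows)


def mean_recent_bp(observations: pd.DataFrame, person_id: str, kind: str,
                   window: tuple[date, date] | None = None):
    """Mean of the up-to-three most recent readings of one kind, or None.

    Date ties resolve by stable input order within the last three slots.
    """
    obs = observations[(observations["person_id"] == person_id)
                       & (observations["kind"] == kind)]
    if window is not None:
        obs = obs[(obs["obs_date"] >= pd.Timestamp(window[0]))
                  & (obs["obs_date"] <= pd.Timestamp(window[1]))]
    if obs.empty:
        return None
    obs = obs.sort_values("obs_date", kind="mergesort")
    recent = obs["value"].to_numpy()[-3:]
    return float(np.mean(recent)), len(recent)


def polypharmacy_flag(prescriptions: pd.DataFrame, person_id: str, year: int) -> bool:
    """More than five distinct full ATC codes dispensed in the year."""
    rx = prescriptions[(prescriptions["person_id"] == person_id)
                       & (prescriptions["dispense_date"] >= pd.Timestamp(date(year, 1, 1)))
                       & (prescriptions["dispense_date"] <= pd.Timestamp(date(year, 12, 31)))]
    return rx["atc_code"].nunique() > POLYPHARMACY_THRESHOLD


def _year_slice(df: pd.DataFrame, col: str, year: int) -> pd.DataFrame:
    return df[(df[col] >= pd.Timestamp(date(year, 1, 1)))
              & (df[col] <= pd.Timestamp(date(year, 12, 31)))]


def build_person_table(groups: pd.DataFrame, emr_bundle: SourceBundle,
                       admin_bundle: SourceBundle, cohort: pd.DataFrame,
                       emr_condition_flags: pd.DataFrame,
                       admin_condition_flags: pd.DataFrame,
                       index_year: int) -> pd.DataFrame:
    """One row per included person with every summarized variable.

    Characteristics come from index-year data (EMR vitals use the
    two-year window ending with the index year); utilization variables
    come from index_year+1 administrative data and are missing for persons
    who died during the index year.
    """
    included = cohort[cohort["included"]].set_index("scrambled_id")
    g = groups.set_index("scrambled_id")["group"]
    persons = emr_bundle.persons.set_index("person_id")
    iy = index_year

    # vectorized recent-BP/BMI means over the characteristics window
    obs = _year_slice(emr_bundle.observations, "obs_date", iy)
    obs = pd.concat([_year_slice(emr_bundle.observations, "obs_date", iy - 1), obs])
    obs = obs.sort_values("obs_date", kind="mergesort")
    recent_mean = {}
    for kind in ("systolic_bp", "diastolic_bp", "bmi"):
        sub = obs[obs["kind"] == kind]
        recent_mean[kind] = sub.groupby("person_id")["value"].agg(
            lambda v: float(np.mean(v.to_numpy()[-3:])))

    # next-year utilization from administrative data
    uy = iy + 1
    claims = _year_slice(admin_bundle.claims, "service_date", uy)
    gp = claims[claims["provider_type"] == "gp"]
    spec = claims[claims["provider_type"] == "specialist"]
    gp_n = gp.groupby("person_id").size()
    gp_cost = gp.groupby("person_id")["fee"].sum()
    spec_cost = spec.groupby("person_id")["fee"].sum()
    hosp = _year_slice(admin_bundle.hospitals, "admit_date", uy)
    hosp_n = hosp.groupby("person_id").size()
    hosp_cost = hosp.groupby("person_id")["cost"].sum()
    hosp_days = ((hosp["discharge_date"] - hosp["admit_date"]).dt.days + 1) \
        .groupby(hosp["person_id"]).sum()
    rx = _year_slice(admin_bundle.prescriptions, "dispense_date", uy)
    rx_cost = rx.groupby("person_id")["cost"].sum()
    rx_distinct = rx.groupby("person_id")["atc_code"].nunique()

    rows = []
    for sid, rec in included.iterrows():
        p = persons.loc[rec["emr_person_id"]]
        death = p["death_date"]
        died_index = pd.notna(death) and death.year == iy
        died_next = pd.notna(death) and death.year == iy + 1
        age = rec["age_on_jan1"]
        band = "65-74" if age < 75 else "75-84" if age < 85 else "85+"
        aid = rec["admin_person_id"]
        row = {
            "scrambled_id": sid,
            "group": g[sid],
            "age_band": band,
            "sex": p["sex"],
            "income": "high" if p["income_quintile"] >= 3 else "low",
            "location": rural_flag(p["postal_code"]),
            "systolic_bp": recent_mean["systolic_bp"].get(rec["emr_person_id"], np.nan),
            "diastolic_bp": recent_mean["diastolic_bp"].get(rec["emr_person_id"], np.nan),
            "bmi": recent_mean["bmi"].get(rec["emr_person_id"], np.nan),
            "conditions_emr": _band(emr_condition_flags, rec["emr_person_id"]),
            "conditions_admin": _band(admin_condition_flags, aid),
            "died_index_year": died_index,
        }
        if died_index:
            for c in _UTILIZATION_CONTINUOUS:
                row[c] = np.nan
            row["polypharmacy"] = np.nan
            row["died_next_year"] = np.nan
        else:
            row.update({
                "gp_contacts": float(gp_n.get(aid, 0)),
                "gp_cost": float(gp_cost.get(aid, 0.0)),
                "specialist_cost": float(spec_cost.get(aid, 0.0)),
                "physician_cost": float(gp_cost.get(aid, 0.0) + spec_cost.get(aid, 0.0)),
                "hospital_cost": float(hosp_cost.get(aid, 0.0)),
                "rx_cost": float(rx_cost.get(aid, 0.0)),
                "hospitalizations_per_100": 100.0 * float(hosp_n.get(aid, 0)),
                "hospital_days": float(hosp_days.get(aid, 0)),
                "polypharmacy": bool(rx_distinct.get(aid, 0) > POLYPHARMACY_THRESHOLD),
                "died_next_year": died_next,
            })
        rows.append(row)
    return pd.DataFrame(rows)


def _band(flags: pd.DataFrame, pid: str) -> str:
    from .comorbidity import condition_band
    if pid in flags.index:
        return condition_band(int(flags.loc[pid].sum()))
    return condition_band(0)


@dataclass
class SummaryTable:
    """Formatted group summaries plus the per-person data behind them."""

    group_sizes: pd.Series
    categorical: pd.DataFrame   # group, block, level, n, pct
    continuous: pd.DataFrame    # group, variable, mean, sd, n
    utilization: pd.DataFrame   # group, variable, mean/sd or n/pct
    person_data: pd.DataFrame


def summarize(groups: pd.DataFrame, emr_bundle: SourceBundle,
              admin_bundle: SourceBundle, cohort: pd.DataFrame,
              emr_condition_flags: pd.DataFrame, admin_condition_flags: pd.DataFrame,
              index_year: int) -> SummaryTable:
    """Build the three-table summary for the four exclusive groups."""
    pt = build_person_table(groups, emr_bundle, admin_bundle, cohort,
                            emr_condition_flags, admin_condition_flags, index_year)
    sizes = pt.groupby("group").size().reindex(GROUPS, fill_value=0)

    cat_rows, cont_rows, util_rows = [], [], []
    for group in GROUPS:
        sub = pt[pt["group"] == group]
        n = len(sub)
        for block, levels in _CATEGORICAL_BLOCKS.items():
            for level in levels:
                k = int((sub[block] == level).sum())
                cat_rows.append({"group": group, "block": block, "level": level,
                                 "n": k, "pct": percent(k, n)})
        for var in _CONTINUOUS_CHARACTERISTICS:
            vals = sub[var].dropna()
            cont_rows.append({
                "group": group, "variable": var,
                "mean": round1(vals.mean()) if len(vals) else float("nan"),
                "sd": round1(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                "n": len(vals),
            })
        alive = sub[~sub["died_index_year"]]
        m = len(alive)
        for var in _UTILIZATION_CONTINUOUS:
            vals = alive[var].dropna()
            util_rows.append({
                "group": group, "variable": var, "kind": "mean_sd",
                "mean": round1(vals.mean()) if len(vals) else float("nan"),
                "sd": round1(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                "n": len(vals), "pct": float("nan"),
            })
        for var in _UTILIZATION_BINARY:
            k = int(alive[var].eq(True).sum())
            util_rows.append({"group": group, "variable": var, "kind": "n_pct",
                              "mean": float("nan"), "sd": float("nan"),
                              "n": k, "pct": percent(k, m)})
    return SummaryTable(
        group_sizes=sizes,
        categorical=pd.DataFrame(cat_rows),
        continuous=pd.DataFrame(cont_rows),
        utilization=pd.DataFrame(util_rows),
        person_data=pt,
    )


def _significance(p: float) -> str:
    if p < 1e-4:
        return "p<0.0001"
    if p < 0.01:
        return "p<0.01"
    if p < 0.05:
        return "p<0.05"
    return ""


def chi_square_test(table: np.ndarray) -> tuple[float, float, bool]:
    """Pearson chi-square without continuity correction.

    Returns (statistic, p, small_sample_warning); degenerate tables (a zero
    margin) give statistic 0, p 1.
    """
    table = np.asarray(table, dtype=float)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 0.0, 1.0, True
    res = stats.chi2_contingency(table, correction=False)
    warn = bool((res.expected_freq < 1).any())
    return float(res.statistic), float(res.pvalue), warn


def welch_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Welch two-sample t-test; zero-variance degenerate input gives p 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2 or (np.var(x) == 0 and np.var(y) == 0):
        return 0.0, 1.0, True
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue), False


def group_compare(summary: SummaryTable, group_a: str = "emr_only",
                  group_b: str = "admin_only") -> pd.DataFrame:
    """Chi-square (categorical) and Welch t-test (continuous) between groups."""
    pt = summary.person_data
    a = pt[pt["group"] == group_a]
    b = pt[pt["group"] == group_b]
    rows = []
    for block, levels in _CATEGORICAL_BLOCKS.items():
        table = np.array([[(a[block] == lv).sum(), (b[block] == lv).sum()]
                          for lv in levels])
        stat, p, warn = chi_square_test(table)
        rows.append({"variable": block, "test": "chi_square", "statistic": stat,
                     "p_value": p, "significance": _significance(p),
                     "small_sample_warning": warn})
    cont_vars = _CONTINUOUS_CHARACTERISTICS + _UTILIZATION_CONTINUOUS
    for var in cont_vars:
        stat, p, warn = welch_t_test(a[var].to_numpy(), b[var].to_numpy())
        rows.append({"variable": var, "test": "welch_t", "statistic": stat,
                     "p_value": p, "significance": _significance(p),
                     "small_sample_warning": warn})
    for var in _UTILIZATION_BINARY:
        aa, bb = a[var].dropna(), b[var].dropna()
        table = np.array([[int(aa.sum()), int(bb.sum())],
                          [int((~aa.astype(bool)).sum()), int((~bb.astype(bool)).sum())]])
        stat, p, warn = chi_square_test(table)
        rows.append({"variable": var, "test": "chi_square", "statistic": stat,
                     "p_value": p, "significance": _significance(p),
                     "small_sample_warning": warn})
    return pd.DataFrame(rows)
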