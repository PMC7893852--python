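"""Rolling-window chronic-condition classification.

A person is classified with a condition when, within the study window,
either (a) at least one hospital discharge diagnosis matches the condition's
ICD-10-CA prefixes, or (b) two physician billing claims matching its ICD-9
prefixes fall within a rolling window of ``window_days`` (730 by default;
365 for depression).  Two same-day claims count as a qualifying pair.

Depression is additionally *persistence-checked*: when the first
qualification predates the index year, classification requires index-year
treatment evidence — an antidepressant dispensation, a depression billing
claim or a depression hospitalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from ._codes import strip_dots
from .bundle import SourceBundle, _empty_table

__all__ = [
    "ConditionDef",
    "default_conditions",
    "classify_condition",
    "classify_depression",
    "classify_bundle",
    "count_conditions",
    "condition_band",
]


@dataclass(frozen=True)
class ConditionDef:
    name: str
    icd9_prefixes: tuple[str, ...]
    icd10_prefixes: tuple[str, ...]
    window_days: int = 730
    treatment_atc_prefixes: tuple[str, ...] = ()

    def __post_init__(self):
        if self.window_days <= 0:
            raise ValueError("window_days must be positive")
        if not self.icd9_prefixes or not self.icd10_prefixes:
            raise ValueError("code prefix sets must be non-empty")


def default_conditions() -> dict[str, ConditionDef]:
    text = resources.files("frailscan.data").joinpath("conditions.yaml").read_text()
    raw = yaml.safe_load(text)
    out = {}
    for name, spec in raw.items():
        out[name] = ConditionDef(
            name=name,
            icd9_prefixes=tuple(spec["icd9_prefixes"]),
            icd10_prefixes=tuple(spec["icd10_prefixes"]),
            window_days=int(spec.get("window_days", 730)),
            treatment_atc_prefixes=tuple(spec.get("treatment_atc_prefixes", ())),
        )
    return out


def _within(series: pd.Series, window: tuple[date, date]) -> pd.Series:
    return (series >= pd.Timestamp(window[0])) & (series <= pd.Timestamp(window[1]))


def _matching_claim_dates(cond: ConditionDef, claims: pd.DataFrame,
                          window: tuple[date, date]) -> pd.Series:
    if claims.empty:
        return claims["service_date"]
    bare = claims["icd9_code"].astype(str).str.replace(".", "", regex=False)
    pref = tuple(strip_dots(p) for p in cond.icd9_prefixes)
    hit = _within(claims["service_date"], window) & (claims["icd9_code"] != "") \
        & bare.str.startswith(pref)
    return claims.loc[hit, "service_date"]


def _matching_hospital_dates(cond: ConditionDef, hospitals: pd.DataFrame,
                             window: tuple[date, date]) -> pd.Series:
    if hospitals.empty:
        return hospitals["admit_date"]
    pref = tuple(strip_dots(p) for p in cond.icd10_prefixes)
    in_win = _within(hospitals["admit_date"], window)
    mask = in_win & pd.Series(
        [any(strip_dots(c).startswith(pref) for c in codes)
         for codes in hospitals["icd10_codes"]], index=hospitals.index)
    return hospitals.loc[mask, "admit_date"]


def _pair_first_date(dates: np.ndarray, window_days: int):
    """Earliest date at which two claims ≤ window_days apart have occurred.

    ``dates`` must be sorted.  Because dates are sorted, some pair within the
    window exists iff some *adjacent* pair is within it, but the first
    qualifying date is the earliest d[j] with d[j] − d[j−1] ≤ window.
    """
    if len(dates) < 2:
        return None
    gaps = np.diff(dates).astype("timedelta64[D]").astype(int)
    ok = np.flatnonzero(gaps <= window_days)
    if len(ok) == 0:
        return None
    return dates[ok[0] + 1]


def classify_condition(cond: ConditionDef, person_events: dict,
                       study_window: tuple[date, date]) -> tuple[bool, date | None]:
    """Classify one person; returns (flag, first qualifying date).

    ``person_events`` maps "claims" / "hospitals" to that person's rows.
    """
    claims = person_events.get("claims")
    hospitals = person_events.get("hospitals")
    claims = claims if claims is not None else _empty_table("claims")
    hospitals = hospitals if hospitals is not None else _empty_table("hospitals")

    hosp_dates = _matching_hospital_dates(cond, hospitals, study_window)
    first_hosp = hosp_dates.min() if len(hosp_dates) else None

    claim_dates = np.sort(_matching_claim_dates(cond, claims, study_window)
                          .to_numpy().astype("datetime64[D]"))
    first_pair = _pair_first_date(claim_dates, cond.window_days)

    candidates = [d for d in (first_hosp, first_pair) if d is not None]
    if not candidates:
        return False, None
    first = min(pd.Timestamp(d) for d in candidates)
    return True, first.date()


def classify_depression(cond: ConditionDef, person_events: dict,
                        index_year: int,
                        study_window: tuple[date, date] | None = None) -> bool:
    """Depression with the one-year window and index-year persistence rule."""
    if study_window is None:
        study_window = (date(index_year - 5, 1, 1), date(index_year, 12, 31))
    flag, first = classify_condition(cond, person_events, study_window)
    if not flag:
        return False
    if first >= date(index_year, 1, 1):
        return True
    # qualified before the index year: require treatment evidence in it
    year = (date(index_year, 1, 1), date(index_year, 12, 31))
    claims = person_events.get("claims")
    hospitals = person_events.get("hospitals")
    rx = person_events.get("prescriptions")
    claims = claims if claims is not None else _empty_table("claims")
    hospitals = hospitals if hospitals is not None else _empty_table("hospitals")
    rx = rx if rx is not None else _empty_table("prescriptions")
    if len(_matching_claim_dates(cond, claims, year)):
        return True
    if len(_matching_hospital_dates(cond, hospitals, year)):
        return True
    if len(rx) and cond.treatment_atc_prefixes:
        pref = tuple(strip_dots(p) for p in cond.treatment_atc_prefixes)
        hit = _within(rx["dispense_date"], year) \
            & rx["atc_code"].astype(str).str.startswith(pref)
        if hit.any():
            return True
    return False


def classify_bundle(bundle: SourceBundle, person_ids, index_year: int,
                    conditions: dict[str, ConditionDef] | None = None,
                    study_window: tuple[date, date] | None = None) -> pd.DataFrame:
    """Condition flags for many persons from one source's events.

    Returns a boolean DataFrame indexed by person id with one column per
    condition.  The study window defaults to the six calendar years ending
    with the index year.
    """
    if conditions is None:
        conditions = default_conditions()
    if study_window is None:
        study_window = (date(index_year - 5, 1, 1), date(index_year, 12, 31))
    person_ids = list(person_ids)
    flags = pd.DataFrame(False, index=pd.Index(person_ids, name="person_id"),
                         columns=list(conditions))

    claims, hospitals, rx = bundle.claims, bundle.hospitals, bundle.prescriptions
    for name, cond in conditions.items():
        hosp_dates = _matching_hospital_dates(cond, hospitals, study_window)
        hosp_first = hosp_dates.groupby(hospitals.loc[hosp_dates.index, "person_id"]).min()

        cdates = _matching_claim_dates(cond, claims, study_window)
        cframe = pd.DataFrame({
            "person_id": claims.loc[cdates.index, "person_id"],
            "d": cdates,
        }).sort_values(["person_id", "d"], kind="mergesort")
        gap_ok = (cframe["person_id"] == cframe["person_id"].shift()) & \
            ((cframe["d"] - cframe["d"].shift()).dt.days <= cond.window_days)
        pair_first = cframe.loc[gap_ok].groupby("person_id")["d"].min()

        first = pd.concat([hosp_first, pair_first]).groupby(level=0).min()
        first = first[first.index.isin(flags.index)]

        if name == "depression":
            qualified = first.copy()
            persists = qualified >= pd.Timestamp(date(index_year, 1, 1))
            needs_check = qualified.index[~persists]
            if len(needs_check):
                year = (date(index_year, 1, 1), date(index_year, 12, 31))
                treated: set = set()
                treated |= set(claims.loc[_matching_claim_dates(cond, claims, year).index,
                                          "person_id"])
                yr_hosp = _matching_hospital_dates(cond, hospitals, year)
                treated |= set(hospitals.loc[yr_hosp.index, "person_id"])
                if len(rx) and cond.treatment_atc_prefixes:
                    pref = tuple(strip_dots(p) for p in cond.treatment_atc_prefixes)
                    hit = _within(rx["dispense_date"], year) \
                        & rx["atc_code"].astype(str).str.startswith(pref)
                    treated |= set(rx.loc[hit, "person_id"])
                keep = [pid for pid in qualified.index
                        if persists.get(pid) or pid in treated]
            else:
                keep = list(qualified.index)
            flags.loc[flags.index.isin(keep), name] = True
        else:
            flags.loc[first.index, name] = True
    return flags


def count_conditions(flags: pd.DataFrame) -> pd.DataFrame:
    """Per-person condition count and the 0-1 / 2 / 3+ reporting band."""
    counts = flags.sum(axis=1).astype(int)
    return pd.DataFrame({"count": counts, "band": counts.map(condition_band)})


def condition_band(count: int) -> str:
    if count <= 1:
        return "0-1"
    if count == 2:
        return "2"
    return "3+"
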