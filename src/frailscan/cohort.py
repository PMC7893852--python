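"""Cohort inclusion rules for the index year.

A person enters the study cohort when all four rules hold, checked in this
order (the first failing rule becomes the recorded exclusion reason):

1. linked across the two sources (exact PHN match),
2. aged 65+ in completed years on Jan 1 of the index year,
3. at least one primary-care (GP) encounter in the EMR in the two calendar
   years ending with the index year,
4. registered for provincial health coverage for at least 75% of the days
   they were alive in the index year.
"""

from __future__ import annotations

from datetime import date

import pandas as pd

from .bundle import SourceBundle, merge_episodes
from .linkage import Crosswalk

__all__ = ["coverage_fraction", "age_on_jan1", "build_cohort", "EXCLUSION_REASONS"]

EXCLUSION_REASONS = ("none", "not_linked", "under_65", "no_recent_visit", "low_coverage")

COVERAGE_THRESHOLD = 0.75


def coverage_fraction(coverage_episodes, death_date, index_year: int) -> tuple[float, bool]:
    """Fraction of days alive in the index year covered by registry episodes.

    Returns ``(fraction, dead_before_year)``.  Episodes are closed day
    intervals; the denominator is the number of days the person was alive
    within the calendar year.  A person dead before Jan 1 has no alive days
    and is reported as fraction 0.0 with the flag set.
    """
    year_start = date(index_year, 1, 1)
    year_end = date(index_year, 12, 31)
    death = None if pd.isna(death_date) else pd.Timestamp(death_date).date()
    if death is not None and death < year_start:
        return 0.0, True
    alive_end = year_end if death is None else min(death, year_end)
    alive_days = (alive_end - year_start).days + 1
    covered = 0
    for s, e in merge_episodes(coverage_episodes):
        lo, hi = max(s, year_start), min(e, alive_end)
        if lo <= hi:
            covered += (hi - lo).days + 1
    return covered / alive_days, False


def age_on_jan1(birth_date, index_year: int) -> int:
    """Age in completed years on Jan 1 of the index year."""
    b = pd.Timestamp(birth_date).date()
    ref = date(index_year, 1, 1)
    return ref.year - b.year - ((ref.month, ref.day) < (b.month, b.day))


def build_cohort(emr_bundle: SourceBundle, admin_bundle: SourceBundle,
                 crosswalk: Crosswalk, index_year: int) -> pd.DataFrame:
    """Apply the four inclusion rules to every EMR person.

    Returns one row per EMR person: ``emr_person_id``, ``admin_person_id``
    (empty when unlinked), ``scrambled_id``, ``age_on_jan1``, ``included``,
    ``exclusion_reason``.
    """
    persons = emr_bundle.persons
    xw = crosswalk.table
    missing = set(xw["emr_person_id"]) - set(persons["person_id"])
    if missing:
        raise ValueError(f"crosswalk references persons absent from EMR bundle: "
                         f"{sorted(missing)[:5]}")
    missing_admin = set(xw["admin_person_id"]) - set(admin_bundle.persons["person_id"])
    if missing_admin:
        raise ValueError(f"crosswalk references persons absent from admin bundle: "
                         f"{sorted(missing_admin)[:5]}")

    link_map = xw.set_index("emr_person_id")

    claims = emr_bundle.claims
    window_lo = pd.Timestamp(date(index_year - 1, 1, 1))
    window_hi = pd.Timestamp(date(index_year, 12, 31))
    gp = claims[(claims["provider_type"] == "gp")
                & (claims["service_date"] >= window_lo)
                & (claims["service_date"] <= window_hi)]
    has_visit = set(gp["person_id"])

    rows = []
    for rec in persons.itertuples(index=False):
        pid = rec.person_id
        linked = pid in link_map.index
        age = age_on_jan1(rec.birth_date, index_year)
        frac, dead_before = coverage_fraction(rec.coverage_episodes, rec.death_date,
                                              index_year)
        if not linked:
            reason = "not_linked"
        elif age < 65:
            reason = "under_65"
        elif pid not in has_visit:
            reason = "no_recent_visit"
        elif frac < COVERAGE_THRESHOLD:
            reason = "low_coverage"
        else:
            reason = "none"
        rows.append({
            "emr_person_id": pid,
            "admin_person_id": link_map["admin_person_id"].get(pid, "") if linked else "",
            "scrambled_id": link_map["scrambled_id"].get(pid, "") if linked else "",
            "age_on_jan1": age,
            "coverage_fraction": frac,
            "included": reason == "none",
            "exclusion_reason": reason,
        })
    return pd.DataFrame(rows)
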