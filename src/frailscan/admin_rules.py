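"""Administrative frailty identification: three rules over index-year data.

A person is administratively frail when at least one rule fires:

1. **LTC residence** — any long-term-care or assisted-living episode
   overlapping the index year by at least one day;
2. **terminal illness** — palliative/terminal coding (billing or hospital
   diagnosis) dated within the index year;
3. **Edmonton-Frail-Scale indices** — qualifying events in at least
   ``efs_min_indices`` (default 2) *distinct* claims-detectable domains of
   the modified Edmonton Frail Scale during the index year.  Repeated events
   within one domain count once; the polypharmacy domain fires on more than
   a threshold number of distinct medications dispensed in the year.

Code sets ship in an editable YAML; the published per-province criterion
lists live in unavailable supplemental material, so the defaults here are
documented stand-ins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date
from importlib import resources

import pandas as pd
import yaml

from ._codes import strip_dots
from .bundle import SourceBundle

__all__ = [
    "AdminRuleConfig",
    "default_admin_config",
    "rule_ltc",
    "rule_terminal",
    "rule_efs_indices",
    "apply_admin_definition",
]


@dataclass
class AdminRuleConfig:
    terminal_icd9: tuple[str, ...] = ("V66.7",)
    terminal_icd10: tuple[str, ...] = ("Z51.5",)
    efs_domains: dict[str, dict] = field(default_factory=dict)
    efs_min_indices: int = 2

    def __post_init__(self):
        if self.efs_min_indices < 1:
            raise ValueError("efs_min_indices must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "AdminRuleConfig":
        term = d.get("terminal_illness", {})
        return cls(
            terminal_icd9=tuple(term.get("icd9", ())),
            terminal_icd10=tuple(term.get("icd10", ())),
            efs_domains=dict(d.get("efs_domains", {})),
            efs_min_indices=int(d.get("efs_min_indices", 2)),
        )

    @classmethod
    def from_yaml(cls, path) -> "AdminRuleConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_admin_config() -> AdminRuleConfig:
    text = resources.files("frailscan.data").joinpath("admin_rules.yaml").read_text()
    return AdminRuleConfig.from_dict(yaml.safe_load(text))


def _year_bounds(index_year: int) -> tuple[pd.Timestamp, pd.Timestamp]:
    return pd.Timestamp(date(index_year, 1, 1)), pd.Timestamp(date(index_year, 12, 31))


# ---------------------------------------------------------------------------
# single-person rule forms (operate on one person's event frames)


def rule_ltc(ltc_episodes: pd.DataFrame, index_year: int) -> bool:
    """True iff any LTC/assisted-living episode overlaps the index year."""
    if ltc_episodes.empty:
        return False
    lo, hi = _year_bounds(index_year)
    starts = ltc_episodes["start_date"]
    ends = ltc_episodes["end_date"]
    open_or_late = ends.isna() | (ends >= lo)
    return bool(((starts <= hi) & open_or_late).any())


def rule_terminal(claims: pd.DataFrame, hospitals: pd.DataFrame, index_year: int,
                  config: AdminRuleConfig) -> bool:
    """True iff any palliative/terminal code appears in the index year."""
    if not config.terminal_icd9 and not config.terminal_icd10:
        warnings.warn("terminal-illness code set is empty; rule 2 can never fire")
        return False
    lo, hi = _year_bounds(index_year)
    if len(claims) and config.terminal_icd9:
        bare = claims["icd9_code"].astype(str).str.replace(".", "", regex=False)
        pref = tuple(strip_dots(c) for c in config.terminal_icd9)
        hit = ((claims["service_date"] >= lo) & (claims["service_date"] <= hi)
               & bare.str.startswith(pref))
        if hit.any():
            return True
    if len(hospitals) and config.terminal_icd10:
        pref = tuple(strip_dots(c) for c in config.terminal_icd10)
        in_year = (hospitals["admit_date"] >= lo) & (hospitals["admit_date"] <= hi)
        for codes in hospitals.loc[in_year, "icd10_codes"]:
            if any(strip_dots(c).startswith(pref) for c in codes):
                return True
    return False


def rule_efs_indices(claims: pd.DataFrame, prescriptions: pd.DataFrame, index_year: int,
                     config: AdminRuleConfig) -> tuple[bool, int, list[str]]:
    """Count distinct Edmonton-Frail-Scale domains with index-year evidence."""
    lo, hi = _year_bounds(index_year)
    fired = []
    for domain, spec in config.efs_domains.items():
        if "distinct_atc_threshold" in spec:
            if len(prescriptions):
                in_year = ((prescriptions["dispense_date"] >= lo)
                           & (prescriptions["dispense_date"] <= hi))
                n_meds = prescriptions.loc[in_year, "atc_code"].nunique()
                if n_meds > spec["distinct_atc_threshold"]:
                    fired.append(domain)
            continue
        prefixes = tuple(strip_dots(p) for p in spec.get("icd9_prefixes", ()))
        if not prefixes or claims.empty:
            continue
        bare = claims["icd9_code"].astype(str).str.replace(".", "", regex=False)
        hit = ((claims["service_date"] >= lo) & (claims["service_date"] <= hi)
               & (claims["icd9_code"] != "") & bare.str.startswith(prefixes))
        if hit.any():
            fired.append(domain)
    return len(fired) >= config.efs_min_indices, len(fired), fired


# ---------------------------------------------------------------------------
# cohort-level application


def apply_admin_definition(admin_bundle: SourceBundle, cohort: pd.DataFrame,
                           index_year: int,
                           config: AdminRuleConfig | None = None) -> pd.DataFrame:
    """Evaluate all three rules for every included cohort member.

    Returns one row per included person: ``person_id`` (admin id),
    ``scrambled_id``, ``source`` ("admin"), ``frail``, ``evidence`` — the
    rules that fired, with EFS domains listed — and the per-rule booleans.
    """
    if config is None:
        config = default_admin_config()
    included = cohort[cohort["included"]]
    lo, hi = _year_bounds(index_year)

    ltc = admin_bundle.ltc
    ltc_hits = set()
    if len(ltc):
        open_or_late = ltc["end_date"].isna() | (ltc["end_date"] >= lo)
        ltc_hits = set(ltc.loc[(ltc["start_date"] <= hi) & open_or_late, "person_id"])

    claims = admin_bundle.claims
    in_year = (claims["service_date"] >= lo) & (claims["service_date"] <= hi)
    year_claims = claims[in_year]
    bare = year_claims["icd9_code"].astype(str).str.replace(".", "", regex=False)

    terminal_hits: set = set()
    if config.terminal_icd9:
        pref = tuple(strip_dots(c) for c in config.terminal_icd9)
        terminal_hits |= set(year_claims.loc[bare.str.startswith(pref), "person_id"])
    hospitals = admin_bundle.hospitals
    if len(hospitals) and config.terminal_icd10:
        pref = tuple(strip_dots(c) for c in config.terminal_icd10)
        hy = hospitals[(hospitals["admit_date"] >= lo) & (hospitals["admit_date"] <= hi)]
        mask = [any(strip_dots(c).startswith(pref) for c in codes)
                for codes in hy["icd10_codes"]]
        terminal_hits |= set(hy.loc[mask, "person_id"])
    if not config.terminal_icd9 and not config.terminal_icd10:
        warnings.warn("terminal-illness code set is empty; rule 2 can never fire")

    domain_hits: dict[str, set] = {}
    rx = admin_bundle.prescriptions
    rx_year = rx[(rx["dispense_date"] >= lo) & (rx["dispense_date"] <= hi)]
    for domain, spec in config.efs_domains.items():
        if "distinct_atc_threshold" in spec:
            counts = rx_year.groupby("person_id")["atc_code"].nunique()
            domain_hits[domain] = set(counts.index[counts > spec["distinct_atc_threshold"]])
        else:
            pref = tuple(strip_dots(p) for p in spec.get("icd9_prefixes", ()))
            hit = (year_claims["icd9_code"] != "") & bare.str.startswith(pref)
            domain_hits[domain] = set(year_claims.loc[hit, "person_id"])

    rows = []
    for rec in included.itertuples(index=False):
        pid = rec.admin_person_id
        is_ltc = pid in ltc_hits
        is_terminal = pid in terminal_hits
        domains = sorted(d for d, hits in domain_hits.items() if pid in hits)
        efs_count = len(domains)
        is_efs = efs_count >= config.efs_min_indices
        frail = is_ltc or is_terminal or is_efs
        evidence = []
        if is_ltc:
            evidence.append(("rule_ltc", None, "LTC/assisted-living episode overlaps year"))
        if is_terminal:
            evidence.append(("rule_terminal", None, "terminal-illness coding in year"))
        if is_efs:
            evidence.append(("rule_efs", None, ",".join(domains)))
        rows.append({"person_id": pid, "scrambled_id": rec.scrambled_id,
                     "source": "admin", "frail": frail, "evidence": evidence,
                     "rule_ltc": is_ltc, "rule_terminal": is_terminal,
                     "rule_efs": is_efs, "efs_count": efs_count})
    return pd.DataFrame(rows, columns=["person_id", "scrambled_id", "source", "frail",
                                       "evidence", "rule_ltc", "rule_terminal",
                                       "rule_efs", "efs_count"])
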