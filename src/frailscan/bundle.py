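"""Domain tables for the two linked data sources and their flat-file I/O.

A :class:`SourceBundle` holds one source's tables — patient registry rows,
physician billing claims, hospital discharge abstracts, drug dispensations,
long-term-care / assisted-living episodes and clinical observations — as
pandas DataFrames with day-granular datetime columns.  The on-disk form is a
directory of six UTF-8, LF-terminated CSV files with ISO-8601 dates; writing
is canonical (fixed column order, deterministic sort) so that a read/write
round trip is byte-identical.

Two sources exist: ``emr`` (primary-care electronic medical record) and
``admin`` (administrative claims/hospital/pharmacy data).  Both share the
same schema; the EMR side typically has empty hospital and LTC tables
because primary-care records do not capture those contacts.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from ._codes import ATC_RE, ICD9_RE, ICD10_RE, POSTAL_RE

__all__ = [
    "SourceBundle",
    "BundleValidationError",
    "MissingTableError",
    "read_bundle",
    "write_bundle",
    "empty_bundle",
    "bundles_equal",
]

SEXES = ("female", "male")
PROVIDER_TYPES = ("gp", "specialist")
SOURCES = ("emr", "admin")
LTC_SETTINGS = ("long_term_care", "assisted_living")
OBS_KINDS = ("systolic_bp", "diastolic_bp", "bmi")

# value plausibility bounds per observation kind (inclusive)
OBS_BOUNDS = {"systolic_bp": (50.0, 300.0), "diastolic_bp": (20.0, 200.0), "bmi": (8.0, 100.0)}

TABLE_COLUMNS = {
    "persons": [
        "person_id", "phn", "birth_date", "sex", "death_date",
        "income_quintile", "postal_code", "coverage_episodes",
    ],
    "claims": ["person_id", "service_date", "icd9_code", "free_text", "provider_type", "fee"],
    "hospitals": ["person_id", "admit_date", "discharge_date", "icd10_codes", "cost"],
    "prescriptions": ["person_id", "dispense_date", "atc_code", "source", "cost"],
    "ltc": ["person_id", "start_date", "end_date", "setting"],
    "observations": ["person_id", "obs_date", "kind", "value"],
}

_DATE_COLUMNS = {
    "persons": ["birth_date", "death_date"],
    "claims": ["service_date"],
    "hospitals": ["admit_date", "discharge_date"],
    "prescriptions": ["dispense_date"],
    "ltc": ["start_date", "end_date"],
    "observations": ["obs_date"],
}

_SORT_KEYS = {
    "persons": ["person_id"],
    "claims": ["person_id", "service_date", "icd9_code", "free_text"],
    "hospitals": ["person_id", "admit_date", "discharge_date"],
    "prescriptions": ["person_id", "dispense_date", "atc_code"],
    "ltc": ["person_id", "start_date", "setting"],
    "observations": ["person_id", "obs_date", "kind"],
}


class BundleValidationError(ValueError):
    """A row violates a schema invariant; names the table, row and field."""

    def __init__(self, table: str, row: object, column: str, message: str):
        self.table, self.row, self.column = table, row, column
        super().__init__(f"{table}[row {row}].{column}: {message}")


class MissingTableError(FileNotFoundError):
    def __init__(self, table: str, path: object):
        self.table = table
        super().__init__(f"expected table file missing: {table} ({path})")


@dataclass
class SourceBundle:
    """All tables for one data source, validated and canonically ordered."""

    source: str
    persons: pd.DataFrame
    claims: pd.DataFrame
    hospitals: pd.DataFrame
    prescriptions: pd.DataFrame
    ltc: pd.DataFrame
    observations: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_COLUMNS}

    def person_ids(self) -> pd.Index:
        return pd.Index(self.persons["person_id"])

    def normalized(self) -> "SourceBundle":
        """Canonical sort of every table plus coverage-episode merging."""
        out = {}
        for name, df in self.tables().items():
            df = df.copy()
            for c in _DATE_COLUMNS[name]:
                df[c] = pd.to_datetime(df[c]).astype("datetime64[ns]")
            df = df.sort_values(_SORT_KEYS[name], kind="mergesort").reset_index(drop=True)
            out[name] = df
        persons = out["persons"].copy()
        if len(persons):
            persons["coverage_episodes"] = [
                merge_episodes(eps) for eps in persons["coverage_episodes"]
            ]
        out["persons"] = persons
        return SourceBundle(source=self.source, **out)


def empty_bundle(source: str = "emr") -> SourceBundle:
    return SourceBundle(source=source, **{
        name: _empty_table(name) for name in TABLE_COLUMNS
    })


def _empty_table(name: str) -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype="object") for c in TABLE_COLUMNS[name]})
    for c in _DATE_COLUMNS[name]:
        df[c] = pd.Series(dtype="datetime64[ns]")
    for c in ("fee", "cost", "value"):
        if c in df.columns:
            df[c] = pd.Series(dtype="float64")
    if "income_quintile" in df.columns:
        df["income_quintile"] = pd.Series(dtype="int64")
    return df


# ---------------------------------------------------------------------------
# coverage-episode helpers


def merge_episodes(episodes) -> list[tuple[date, date]]:
    """Sort closed day-intervals and merge overlapping or abutting ones."""
    eps = sorted((pd.Timestamp(s).date(), pd.Timestamp(e).date()) for s, e in episodes)
    merged: list[tuple[date, date]] = []
    for s, e in eps:
        if merged and s <= merged[-1][1] + timedelta(days=1):
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _episodes_to_str(episodes) -> str:
    return ";".join(f"{s.isoformat()}/{e.isoformat()}" for s, e in episodes)


def _episodes_from_str(text: str) -> list[tuple[date, date]]:
    if not text:
        return []
    out = []
    for part in text.split(";"):
        s, e = part.split("/")
        out.append((date.fromisoformat(s), date.fromisoformat(e)))
    return out


# ---------------------------------------------------------------------------
# validation


def validate_bundle(bundle: SourceBundle) -> None:
    """Raise :class:`BundleValidationError` on the first violated invariant."""
    if bundle.source not in SOURCES:
        raise BundleValidationError("bundle", "-", "source", f"unknown source {bundle.source!r}")
    _validate_persons(bundle.persons)
    known = set(bundle.persons["person_id"])
    for name, df in bundle.tables().items():
        missing = [c for c in TABLE_COLUMNS[name] if c not in df.columns]
        if missing:
            raise BundleValidationError(name, "-", missing[0], "column missing")
        if name == "persons":
            continue
        bad = ~df["person_id"].isin(known)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise BundleValidationError(name, row, "person_id",
                                        f"unknown person {df['person_id'].iloc[row]!r}")
    _validate_claims(bundle.claims)
    _validate_hospitals(bundle.hospitals)
    _validate_prescriptions(bundle.prescriptions)
    _validate_ltc(bundle.ltc)
    _validate_observations(bundle.observations)


def _validate_persons(df: pd.DataFrame) -> None:
    dup = df["person_id"].duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise BundleValidationError("persons", row, "person_id", "duplicate person_id")
    for row, rec in enumerate(df.itertuples(index=False)):
        if rec.sex not in SEXES:
            raise BundleValidationError("persons", row, "sex", f"not in {SEXES}")
        if not (1 <= int(rec.income_quintile) <= 5):
            raise BundleValidationError("persons", row, "income_quintile", "must be 1..5")
        if not POSTAL_RE.match(str(rec.postal_code)):
            raise BundleValidationError("persons", row, "postal_code",
                                        f"malformed postal code {rec.postal_code!r}")
        if pd.notna(rec.death_date) and not rec.birth_date < rec.death_date:
            raise BundleValidationError("persons", row, "death_date",
                                        "death_date must follow birth_date")
        for s, e in rec.coverage_episodes:
            if s > e:
                raise BundleValidationError("persons", row, "coverage_episodes",
                                            f"episode start {s} after end {e}")


def _validate_claims(df: pd.DataFrame) -> None:
    for row, rec in enumerate(df.itertuples(index=False)):
        code = rec.icd9_code
        if code and not ICD9_RE.match(code):
            raise BundleValidationError("claims", row, "icd9_code", f"invalid ICD-9 {code!r}")
        if rec.provider_type not in PROVIDER_TYPES:
            raise BundleValidationError("claims", row, "provider_type", f"not in {PROVIDER_TYPES}")
        if rec.fee < 0:
            raise BundleValidationError("claims", row, "fee", "negative fee")


def _validate_hospitals(df: pd.DataFrame) -> None:
    for row, rec in enumerate(df.itertuples(index=False)):
        if rec.admit_date > rec.discharge_date:
            raise BundleValidationError("hospitals", row, "discharge_date",
                                        "discharge before admission")
        codes = rec.icd10_codes
        if not codes:
            raise BundleValidationError("hospitals", row, "icd10_codes",
                                        "at least one diagnosis required")
        for code in codes:
            if not ICD10_RE.match(code):
                raise BundleValidationError("hospitals", row, "icd10_codes",
                                            f"invalid ICD-10-CA {code!r}")
        if rec.cost < 0:
            raise BundleValidationError("hospitals", row, "cost", "negative cost")


def _validate_prescriptions(df: pd.DataFrame) -> None:
    for row, rec in enumerate(df.itertuples(index=False)):
        if not ATC_RE.match(rec.atc_code):
            raise BundleValidationError("prescriptions", row, "atc_code",
                                        f"invalid ATC {rec.atc_code!r}")
        if rec.source not in SOURCES:
            raise BundleValidationError("prescriptions", row, "source", f"not in {SOURCES}")
        if rec.cost < 0:
            raise BundleValidationError("prescriptions", row, "cost", "negative cost")


def _validate_ltc(df: pd.DataFrame) -> None:
    for row, rec in enumerate(df.itertuples(index=False)):
        if rec.setting not in LTC_SETTINGS:
            raise BundleValidationError("ltc", row, "setting", f"not in {LTC_SETTINGS}")
        if pd.notna(rec.end_date) and rec.start_date > rec.end_date:
            raise BundleValidationError("ltc", row, "end_date", "episode end before start")


def _validate_observations(df: pd.DataFrame) -> None:
    for row, rec in enumerate(df.itertuples(index=False)):
        if rec.kind not in OBS_KINDS:
            raise BundleValidationError("observations", row, "kind", f"not in {OBS_KINDS}")
        lo, hi = OBS_BOUNDS[rec.kind]
        if not (lo <= rec.value <= hi):
            raise BundleValidationError("observations", row, "value",
                                        f"{rec.kind} value {rec.value} outside [{lo}, {hi}]")


# ---------------------------------------------------------------------------
# I/O


def read_bundle(directory: str | os.PathLike, source: str | None = None) -> SourceBundle:
    """Read and validate a bundle from a directory of CSV files.

    ``source`` defaults to the directory's basename when that is ``emr`` or
    ``admin``; otherwise it must be given explicitly.
    """
    directory = Path(directory)
    if source is None:
        if directory.name in SOURCES:
            source = directory.name
        else:
            raise ValueError(
                f"cannot infer source from directory name {directory.name!r}; pass source=")
    tables = {}
    for name in TABLE_COLUMNS:
        path = directory / f"{name}.csv"
        if not path.exists():
            raise MissingTableError(name, path)
        tables[name] = _read_table(name, path)
    bundle = SourceBundle(source=source, **tables).normalized()
    validate_bundle(bundle)
    return bundle


def _read_table(name: str, path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TABLE_COLUMNS[name] if c not in df.columns]
    if missing:
        raise BundleValidationError(name, "-", missing[0], "column missing from header")
    df = df[TABLE_COLUMNS[name]]
    if df.empty:
        return _empty_table(name)
    for c in _DATE_COLUMNS[name]:
        blank = df[c] == ""
        df[c] = pd.to_datetime(df[c].where(~blank), format="%Y-%m-%d")
    for c in ("fee", "cost", "value"):
        if c in df.columns:
            df[c] = df[c].astype(float)
    if name == "persons":
        df["income_quintile"] = df["income_quintile"].astype(int)
        df["coverage_episodes"] = [_episodes_from_str(t) for t in df["coverage_episodes"]]
    if name == "hospitals":
        df["icd10_codes"] = [t.split(";") if t else [] for t in df["icd10_codes"]]
    return df


def write_bundle(bundle: SourceBundle, directory: str | os.PathLike) -> list[Path]:
    """Write one CSV per table: canonical order, ISO dates, UTF-8, LF endings."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bundle = bundle.normalized()
    written = []
    for name, df in bundle.tables().items():
        df = df.copy()
        for c in _DATE_COLUMNS[name]:
            dates = pd.to_datetime(df[c])
            df[c] = dates.dt.strftime("%Y-%m-%d").fillna("")
        if name == "persons":
            df["coverage_episodes"] = [_episodes_to_str(eps) for eps in df["coverage_episodes"]]
        if name == "hospitals":
            df["icd10_codes"] = [";".join(codes) for codes in df["icd10_codes"]]
        path = directory / f"{name}.csv"
        buf = io.StringIO()
        df.to_csv(buf, index=False, lineterminator="\n")
        path.write_bytes(buf.getvalue().encode("utf-8"))
        written.append(path)
    return written


def bundles_equal(a: SourceBundle, b: SourceBundle) -> bool:
    """Semantic equality after canonical normalization of both bundles."""
    if a.source != b.source:
        return False
    a, b = a.normalized(), b.normalized()
    for name in TABLE_COLUMNS:
        ta, tb = getattr(a, name), getattr(b, name)
        if len(ta) != len(tb):
            return False
        try:
            pd.testing.assert_frame_equal(ta, tb, check_dtype=False)
        except AssertionError:
            return False
    return True
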