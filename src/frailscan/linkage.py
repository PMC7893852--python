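"""Deterministic person-level linkage and ID scrambling between sources.

Mirrors the trusted-third-party workflow used by provincial data stewards:
records are linked by exact match on the personal health number (PHN), a
project-specific scrambled identifier is derived from the PHN with a keyed
one-way hash, and released bundles carry only the scrambled id.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import pandas as pd

from .bundle import SourceBundle

__all__ = ["Crosswalk", "DuplicatePhnError", "scramble_ids", "link_deterministic"]


class DuplicatePhnError(ValueError):
    """Deterministic linkage is undefined when a PHN repeats within a source."""

    def __init__(self, source: str, phn: str):
        self.source, self.phn = source, phn
        super().__init__(f"duplicate PHN {phn!r} in {source} source")


@dataclass
class Crosswalk:
    """Exact-match links between the two sources plus the unlinked remainder.

    ``table`` has one row per linked person: emr_person_id, admin_person_id,
    scrambled_id.  ``linkage_rate`` uses the EMR person count as denominator
    by default (the study cohort is drawn from EMR patients); pass
    ``denominator="admin"`` to :func:`link_deterministic` for the other
    convention.
    """

    table: pd.DataFrame
    linkage_rate: float
    unlinked_emr: list[str]
    unlinked_admin: list[str]

    def __post_init__(self):
        for col in ("emr_person_id", "admin_person_id", "scrambled_id"):
            if self.table[col].duplicated().any():
                raise ValueError(f"crosswalk column {col} not unique")


def scrambled_id(phn: str, salt: str) -> str:
    digest = hashlib.sha256(f"{salt}|{phn}".encode("utf-8")).hexdigest()
    return "S" + digest[:16]


def scramble_ids(bundle: SourceBundle, salt: str) -> tuple[SourceBundle, pd.DataFrame]:
    """Replace person ids by keyed hashes of the PHN and drop the PHN column.

    Returns the scrambled bundle and a keymap DataFrame (person_id, phn,
    scrambled_id) that a data steward would retain; the released bundle
    itself carries no PHN.
    """
    persons = bundle.persons
    keymap = pd.DataFrame({
        "person_id": persons["person_id"],
        "phn": persons["phn"],
        "scrambled_id": [scrambled_id(p, salt) for p in persons["phn"]],
    })
    mapping = dict(zip(keymap["person_id"], keymap["scrambled_id"]))
    tables = {}
    for name, df in bundle.tables().items():
        df = df.copy()
        df["person_id"] = df["person_id"].map(mapping)
        if name == "persons":
            df = df.drop(columns=["phn"])
        tables[name] = df
    return SourceBundle(source=bundle.source, **tables), keymap


def link_deterministic(emr_bundle: SourceBundle, admin_bundle: SourceBundle,
                       salt: str = "frailscan", denominator: str = "emr") -> Crosswalk:
    """Link the two sources by exact PHN match; no fuzzy fallback.

    The link set is exactly the PHN intersection.  Raises
    :class:`DuplicatePhnError` if any PHN repeats within one source.
    """
    frames = {}
    for src, bundle in (("emr", emr_bundle), ("admin", admin_bundle)):
        persons = bundle.persons
        dup = persons["phn"].duplicated()
        if dup.any():
            raise DuplicatePhnError(src, persons["phn"][dup].iloc[0])
        frames[src] = persons[["person_id", "phn"]].rename(
            columns={"person_id": f"{src}_person_id"})
    merged = frames["emr"].merge(frames["admin"], on="phn", how="inner")
    merged["scrambled_id"] = [scrambled_id(p, salt) for p in merged["phn"]]
    table = merged[["emr_person_id", "admin_person_id", "scrambled_id"]].sort_values(
        "scrambled_id", kind="mergesort").reset_index(drop=True)

    linked_phn = set(merged["phn"])
    unlinked_emr = sorted(frames["emr"].loc[~frames["emr"]["phn"].isin(linked_phn),
                                            "emr_person_id"])
    unlinked_admin = sorted(frames["admin"].loc[~frames["admin"]["phn"].isin(linked_phn),
                                                "admin_person_id"])
    denom = len(frames[denominator])
    rate = len(table) / denom if denom else 0.0
    return Crosswalk(table=table, linkage_rate=rate,
                     unlinked_emr=unlinked_emr, unlinked_admin=unlinked_admin)
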