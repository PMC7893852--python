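"""Clinical code handling: validation regexes and dot-insensitive prefix matching."""

from __future__ import annotations

import re

# Physician billing diagnoses (ICD-9, incl. E/V codes), optional 1-2 digit decimal.
ICD9_RE = re.compile(r"^[EV0-9][0-9]{2}(\.[0-9]{1,2})?$")

# ATC codes, any hierarchy level from anatomical group (1 char) to substance (7 chars).
ATC_RE = re.compile(r"^[A-V]([0-9]{2}([A-Z]([A-Z]([0-9]{2})?)?)?)?$")

# ICD-10-CA: letter + two digits, optional subdivision (with or without dot).
ICD10_RE = re.compile(r"^[A-Z][0-9]{2}(\.?[0-9A-Z]{1,2})?$")

POSTAL_RE = re.compile(r"^[A-Z][0-9][A-Z][0-9][A-Z][0-9]$")


def strip_dots(code: str) -> str:
    return code.replace(".", "")


def code_matches_prefix(code: str, prefixes) -> bool:
    """True if ``code`` starts with any prefix, ignoring dots on both sides.

    Matching is case-sensitive: diagnosis and ATC codes are upper-case by
    convention and validated as such on ingest.
    """
    bare = strip_dots(code)
    return any(bare.startswith(strip_dots(p)) for p in prefixes)
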