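"""Shared fixtures: a small simulated linked population and its pipeline stages."""

from __future__ import annotations

from datetime import date

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from frailscan.admin_rules import apply_admin_definition
from frailscan.cohort import build_cohort
from frailscan.emr_rules import apply_emr_definition, default_definition
from frailscan.linkage import link_deterministic
from frailscan.simulate import SimConfig, generate

settings.register_profile(
    "ci", derandomize=True, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")

INDEX_YEAR = 2014


@pytest.fixture(scope="session")
def sim_small():
    """A 1,500-person linked population used across downstream tests."""
    return generate(SimConfig(n_persons=1500, seed=42))


@pytest.fixture(scope="session")
def crosswalk(sim_small):
    emr, admin, _ = sim_small
    return link_deterministic(emr, admin)


@pytest.fixture(scope="session")
def cohort(sim_small, crosswalk):
    emr, admin, _ = sim_small
    return build_cohort(emr, admin, crosswalk, INDEX_YEAR)


@pytest.fixture(scope="session")
def emr_calls(sim_small, cohort):
    emr, _, _ = sim_small
    return apply_emr_definition(default_definition(), emr, cohort, INDEX_YEAR)


@pytest.fixture(scope="session")
def admin_calls(sim_small, cohort):
    _, admin, _ = sim_small
    return apply_admin_definition(admin, cohort, INDEX_YEAR)


def persons_row(person_id="P1", phn="111111111", birth="1940-06-15", sex="female",
                death=None, quintile=3, postal="V6T2B5",
                coverage=((date(2009, 1, 1), date(2016, 12, 31)),)):
    return {
        "person_id": person_id, "phn": phn,
        "birth_date": pd.Timestamp(birth), "sex": sex,
        "death_date": pd.Timestamp(death) if death else pd.NaT,
        "income_quintile": quintile, "postal_code": postal,
        "coverage_episodes": list(coverage),
    }
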