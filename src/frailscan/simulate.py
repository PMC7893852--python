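"""Synthetic linked EMR + administrative cohorts from a latent frailty model.

Every person carries a latent 9-level frailty score (1 = very fit, 9 =
terminally ill; scores of 5+ define the frail state), drawn from an ordered
logistic model with age and sex effects whose intercept is calibrated so the
population frail fraction hits a configured target.  The latent class then
drives everything observable:

* code emission — dementia diagnoses, furosemide and vitamin prescriptions,
  "obstruction" free text, long-term-care entry, palliative coding, each
  Edmonton-Frail-Scale domain family and eight chronic conditions all fire
  with class-conditional probabilities;
* primary-care contact volume (negative binomial, frail mean roughly twice
  the non-frail mean, emulating the reported 20 vs 10 contacts per year);
* hospital use, costs (gamma amounts) and distinct-medication counts;
* death in the year after the index year (logistic, increasing in the
  latent score).

Two bundles are emitted from the one underlying population: the EMR side
sees primary-care claims, medications and vital-sign observations; the
administrative side sees billing, hospital abstracts, pharmacy and LTC
episodes.  A configurable fraction of persons is present in only one source
so deterministic linkage has realistic holes (defaults emulate the 97%/96%
provincial linkage rates).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .bundle import SourceBundle, empty_bundle

__all__ = [
    "SimConfig",
    "PlantedRule",
    "CalibrationError",
    "generate",
    "plant_rule",
    "DEFAULT_EMISSIONS",
    "CONDITIONS",
    "CONDITION_CODES",
    "EFS_DOMAIN_CODES",
]


CONDITIONS = (
    "hypertension", "diabetes", "copd", "osteoarthritis",
    "dementia", "depression", "epilepsy", "parkinsonism",
)

# diagnosis code families used when a condition emits billing / hospital codes
CONDITION_CODES: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    # name: (ICD-9 prefixes, ICD-10-CA prefixes)
    "hypertension": (("401", "402", "403", "404", "405"), ("I10", "I11", "I12", "I13", "I15")),
    "diabetes": (("250",), ("E10", "E11", "E13", "E14")),
    "copd": (("491", "492", "496"), ("J41", "J43", "J44")),
    "osteoarthritis": (("715",), ("M15", "M16", "M17", "M18", "M19")),
    "dementia": (("290",), ("F00", "F01", "F02", "F03", "G30")),
    "depression": (("296", "311"), ("F32", "F33")),
    "epilepsy": (("345",), ("G40",)),
    "parkinsonism": (("332",), ("G20", "G21")),
}

# claims-detectable Edmonton-Frail-Scale domains and their billing code families
EFS_DOMAIN_CODES: dict[str, tuple[str, ...]] = {
    "cognition": ("290.0", "294.8", "331.0"),
    "mood": ("296.2", "300.0", "311"),
    "incontinence": ("788.3", "625.6"),
    "falls_mobility": ("V15.88", "781.2"),
    "nutrition": ("783.2", "263.9"),
    "functional_dependence": ("797",),
    "social_support": ("V60.4",),
}

# atom -> (P(emit | frail), P(emit | non-frail)); the emission vocabulary
DEFAULT_EMISSIONS: dict[str, tuple[float, float]] = {
    "dementia_dx": (0.30, 0.03),
    "furosemide_rx": (0.45, 0.10),
    "vitamins_rx": (0.50, 0.25),
    "obstruction_text": (0.10, 0.01),
    "ltc_entry": (0.35, 0.005),
    "terminal_illness_dx": (0.12, 0.003),
    "efs_cognition": (0.35, 0.04),
    "efs_mood": (0.30, 0.08),
    "efs_incontinence": (0.25, 0.04),
    "efs_falls_mobility": (0.40, 0.05),
    "efs_nutrition": (0.20, 0.03),
    "efs_functional_dependence": (0.30, 0.02),
    "efs_social_support": (0.15, 0.03),
    "cond_hypertension": (0.80, 0.55),
    "cond_diabetes": (0.40, 0.22),
    "cond_copd": (0.35, 0.12),
    "cond_osteoarthritis": (0.45, 0.25),
    "cond_dementia": (0.45, 0.05),
    "cond_depression": (0.30, 0.10),
    "cond_epilepsy": (0.06, 0.01),
    "cond_parkinsonism": (0.10, 0.01),
}

# innocuous ICD-9 codes for routine primary-care contacts (disjoint from every
# condition and EFS family so contact volume cannot confound classification)
_ROUTINE_ICD9 = ("780.79", "786.5", "V70.0", "729.5", "465.9")
_ROUTINE_ICD10 = ("J18.9", "N39.0", "S72.0", "K92.2")

# generic medication pool for distinct-drug counts (excludes the furosemide,
# vitamin and antidepressant codes that downstream rules key on)
_MED_POOL = (
    "A02BC01", "A10BA02", "B01AC06", "C07AB02", "C08CA01", "C09AA05",
    "C10AA01", "M01AE01", "N02BE01", "N05CF01", "R03AC02", "S01ED51",
    "H03AA01", "M04AA01", "A12AA04", "N02AA05", "C01DA14", "R06AE07",
    "J01CA04", "G04CA02",
)
_ANTIDEPRESSANT = "N06AB03"

_ORDINAL_CUTS = np.array([-3.0, -2.0, -1.0, 0.0, 1.1, 2.2, 3.4, 4.8])
_FRAIL_CUT_INDEX = 3  # latent > cuts[3]  <=>  score >= 5  <=>  frail


class CalibrationError(RuntimeError):
    """The requested frail fraction is unreachable for the drawn covariates."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated linked population."""

    n_persons: int = 5000
    index_year: int = 2014
    seed: int = 0
    frail_fraction_target: float = 0.15
    unlinked_fraction: float = 0.03
    mean_gp_contacts_frail: float = 20.0
    mean_gp_contacts_nonfrail: float = 10.0
    gp_dispersion: float = 1.5
    # P(death in index_year+1) = expit(intercept + slope * latent_score);
    # defaults put next-year mortality near 1% for the fit and 10-25% across
    # the frail range, echoing the reported death rates of frail groups
    mortality_logit_params: tuple[float, float] = (-7.5, 0.9)
    emission_probabilities: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EMISSIONS))
    age_effect_per_decade: float = 0.6
    female_effect: float = 0.3
    low_coverage_fraction: float = 0.04
    mean_distinct_meds_frail: float = 7.0
    mean_distinct_meds_nonfrail: float = 3.5
    specialist_contacts_frail: float = 4.0
    specialist_contacts_nonfrail: float = 2.0
    hosp_rate_frail: float = 0.5
    hosp_rate_nonfrail: float = 0.15
    mean_los_frail: float = 12.0
    mean_los_nonfrail: float = 6.0

    def __post_init__(self):
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        if not 0.0 < self.frail_fraction_target < 1.0:
            raise ValueError("frail_fraction_target must lie in (0, 1)")
        if not 0.0 <= self.unlinked_fraction < 1.0:
            raise ValueError("unlinked_fraction must lie in [0, 1)")
        if min(self.mean_gp_contacts_frail, self.mean_gp_contacts_nonfrail) <= 0:
            raise ValueError("contact means must be positive")
        for atom, (pf, pn) in self.emission_probabilities.items():
            if not (0.0 <= pf <= 1.0 and 0.0 <= pn <= 1.0):
                raise ValueError(f"emission probabilities for {atom!r} outside [0, 1]")


@dataclass(frozen=True)
class PlantedRule:
    """A conjunction over emission atoms to be recoverable by a learner.

    The config returned by :func:`plant_rule` makes truly frail persons
    satisfy the whole conjunction with probability ``p_frail`` and non-frail
    persons with probability ``p_nonfrail`` (each atom fires independently at
    the k-th root of the joint probability).
    """

    atoms: tuple[str, ...]
    p_frail: float = 0.9
    p_nonfrail: float = 0.05


# atoms whose emitted events fall in the same code family as another atom's;
# planting an atom silences its colliders so the stated probabilities hold
_COLLIDING_EMISSIONS = {"dementia_dx": ("cond_dementia",)}


def plant_rule(config: SimConfig, rule: PlantedRule) -> SimConfig:
    if not rule.atoms:
        return config
    unknown = [a for a in rule.atoms if a not in config.emission_probabilities]
    if unknown:
        raise ValueError(f"atoms not in emission vocabulary: {unknown}")
    k = len(rule.atoms)
    probs = dict(config.emission_probabilities)
    for atom in rule.atoms:
        probs[atom] = (rule.p_frail ** (1.0 / k), rule.p_nonfrail ** (1.0 / k))
        for collider in _COLLIDING_EMISSIONS.get(atom, ()):
            probs[collider] = (0.0, 0.0)
    return replace(config, emission_probabilities=probs)


# ---------------------------------------------------------------------------
# latent model


def _calibrate_offset(eta: np.ndarray, target: float) -> float:
    """Solve for the ordinal intercept putting the mean frail probability at target."""
    cut = _ORDINAL_CUTS[_FRAIL_CUT_INDEX]

    def gap(delta: float) -> float:
        return float(np.mean(expit(eta + delta - cut))) - target

    lo, hi = -40.0, 40.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise CalibrationError(
            f"frail fraction target {target} unreachable for these covariates")
    return float(brentq(gap, lo, hi, xtol=1e-10))


def _draw_latent(rng, age, female, cfg: SimConfig) -> np.ndarray:
    eta = (cfg.age_effect_per_decade * (age - 65.0) / 10.0
           + cfg.female_effect * female)
    delta = _calibrate_offset(eta, cfg.frail_fraction_target)
    noise = rng.logistic(0.0, 1.0, size=len(age))
    latent = eta + delta + noise
    return 1 + (latent[:, None] > _ORDINAL_CUTS[None, :]).sum(axis=1)


# ---------------------------------------------------------------------------
# small vector helpers


def _rand_dates(rng, n: int, start: str, end: str) -> np.ndarray:
    """n random datetime64[D] values uniform on [start, end] inclusive."""
    s, e = np.datetime64(start), np.datetime64(end)
    span = (e - s).astype(int) + 1
    return s + rng.integers(0, span, size=n).astype("timedelta64[D]")

def _gamma_costs(rng, n: int, mean: float, shape: float = 3.0) -> np.ndarray:
    return np.round(rng.gamma(shape, mean / shape, size=n), 2)


class _EventSink:
    """Accumulates event rows, then concatenates once per table."""

    def __init__(self):
        self.claims: list[pd.DataFrame] = []
        self.hospitals: list[pd.DataFrame] = []
        self.prescriptions: list[pd.DataFrame] = []
        self.ltc: list[pd.DataFrame] = []
        self.observations: list[pd.DataFrame] = []

    def add_claims(self, person_idx, dates, icd9, free_text="", provider="gp", fees=None):
        n = len(person_idx)
        if n == 0:
            return
        self.claims.append(pd.DataFrame({
            "person_idx": np.asarray(person_idx),
            "service_date": pd.to_datetime(dates),
            "icd9_code": icd9 if not np.isscalar(icd9) else np.repeat(icd9, n),
            "free_text": free_text if not np.isscalar(free_text) else np.repeat(free_text, n),
            "provider_type": np.repeat(provider, n),
            "fee": fees if fees is not None else np.zeros(n),
        }))

    def add_hospitals(self, person_idx, admit, discharge, codes, costs):
        if len(person_idx) == 0:
            return
        self.hospitals.append(pd.DataFrame({
            "person_idx": np.asarray(person_idx),
            "admit_date": pd.to_datetime(admit),
            "discharge_date": pd.to_datetime(discharge),
            "icd10_codes": list(codes),
            "cost": costs,
        }))

    def add_prescriptions(self, person_idx, dates, atc, costs):
        if len(person_idx) == 0:
            return
        self.prescriptions.append(pd.DataFrame({
            "person_idx": np.asarray(person_idx),
            "dispense_date": pd.to_datetime(dates),
            "atc_code": atc,
            "cost": costs,
        }))

    def add_ltc(self, person_idx, starts, ends, settings):
        if len(person_idx) == 0:
            return
        self.ltc.append(pd.DataFrame({
            "person_idx": np.asarray(person_idx),
            "start_date": pd.to_datetime(starts),
            "end_date": pd.to_datetime(ends),
            "setting": settings,
        }))

    def add_observations(self, person_idx, dates, kind, values):
        if len(person_idx) == 0:
            return
        self.observations.append(pd.DataFrame({
            "person_idx": np.asarray(person_idx),
            "obs_date": pd.to_datetime(dates),
            "kind": np.repeat(kind, len(person_idx)),
            "value": np.round(values, 1),
        }))


# ---------------------------------------------------------------------------
# generation


def generate(config: SimConfig) -> tuple[SourceBundle, SourceBundle, pd.DataFrame]:
    """Simulate one population and split it into EMR and admin bundles.

    Returns ``(emr_bundle, admin_bundle, truth)`` where ``truth`` has one row
    per simulated person with the latent frailty score, the true condition
    flags and next-year death, keyed by PHN with the per-source person ids.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_emr = cfg.n_persons
    n_extra = int(round(cfg.n_persons * cfg.unlinked_fraction))
    n = n_emr + n_extra
    iy = cfg.index_year

    # --- demographics ------------------------------------------------------
    age = 65.0 + np.minimum(rng.exponential(8.0, n), 40.0)
    female = rng.random(n) < 0.55
    jan1 = np.datetime64(f"{iy}-01-01")
    birth = (jan1 - (age * 365.25).astype(int).astype("timedelta64[D]")
             - rng.integers(0, 365, n).astype("timedelta64[D]"))
    income = rng.integers(1, 6, size=n)
    rural = rng.random(n) < 0.35
    postal = _postal_codes(rng, rural)
    phn = np.array([f"{900000000 + i}" for i in rng.permutation(n)])

    latent = _draw_latent(rng, age, female, cfg)
    frail = latent >= 5

    # --- mortality and coverage -------------------------------------------
    b0, b1 = cfg.mortality_logit_params
    p_next = expit(b0 + b1 * latent)
    died_index_year = rng.random(n) < 0.6 * p_next
    died_next = (~died_index_year) & (rng.random(n) < p_next)
    death_date = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
    death_date[died_index_year] = _rand_dates(
        rng, int(died_index_year.sum()), f"{iy}-03-01", f"{iy}-12-31")
    death_date[died_next] = _rand_dates(
        rng, int(died_next.sum()), f"{iy + 1}-01-01", f"{iy + 1}-12-31")

    low_cov = rng.random(n) < cfg.low_coverage_fraction
    cov_start = np.full(n, np.datetime64(f"{iy - 5}-01-01"), dtype="datetime64[D]")
    cov_start[low_cov] = _rand_dates(rng, int(low_cov.sum()), f"{iy}-05-01", f"{iy}-10-01")
    cov_end = np.where(np.isnat(death_date), np.datetime64(f"{iy + 1}-12-31"), death_date)
    cov_start = np.minimum(cov_start, cov_end)

    # --- atom emissions ----------------------------------------------------
    fires = {}
    for atom, (pf, pn) in cfg.emission_probabilities.items():
        p = np.where(frail, pf, pn)
        fires[atom] = rng.random(n) < p

    emr, admin = _EventSink(), _EventSink()
    lookback_start = f"{iy - 5}-01-01"
    year_end = f"{iy}-12-31"

    # routine GP contacts for index_year-1 .. index_year+1 (cohort window + next-year use)
    mean_contacts = np.where(frail, cfg.mean_gp_contacts_frail, cfg.mean_gp_contacts_nonfrail)
    k = cfg.gp_dispersion
    for year in (iy - 1, iy, iy + 1):
        alive = _alive_mask(death_date, year)
        counts = rng.negative_binomial(k, k / (k + mean_contacts), size=n) * alive
        idx = np.repeat(np.arange(n), counts)
        m = len(idx)
        dates = np.minimum(_rand_dates(rng, m, f"{year}-01-01", f"{year}-12-31"), cov_end[idx])
        codes = rng.choice(_ROUTINE_ICD9, size=m)
        fees = _gamma_costs(rng, m, 50.0)
        for sink in (emr, admin):
            sink.add_claims(idx, dates, codes, fees=fees)

    # specialist claims (admin only, next-year utilization)
    spec_mean = np.where(frail, cfg.specialist_contacts_frail, cfg.specialist_contacts_nonfrail)
    alive_next = _alive_mask(death_date, iy + 1)
    counts = rng.poisson(spec_mean) * alive_next
    idx = np.repeat(np.arange(n), counts)
    spec_dates = np.minimum(
        _rand_dates(rng, len(idx), f"{iy + 1}-01-01", f"{iy + 1}-12-31"), cov_end[idx])
    admin.add_claims(idx, spec_dates,
                     rng.choice(_ROUTINE_ICD9, size=len(idx)), provider="specialist",
                     fees=_gamma_costs(rng, len(idx), 150.0))

    # EMR frailty-marker atoms (6-year lookback window)
    _emit_marker_claims(emr, rng, fires["dementia_dx"], ("290.0", "290.4"),
                        lookback_start, year_end, cov_end)
    idx = np.flatnonzero(fires["obstruction_text"])
    emr.add_claims(idx,
                   np.minimum(_rand_dates(rng, len(idx), lookback_start, year_end),
                              cov_end[idx]), "",
                   free_text=np.repeat("bowel obstruction follow-up", len(idx)))
    idx = np.flatnonzero((~fires["obstruction_text"]) & (rng.random(n) < 0.02))
    emr.add_claims(idx,
                   np.minimum(_rand_dates(rng, len(idx), lookback_start, year_end),
                              cov_end[idx]), "",
                   free_text=np.repeat("obstructive sleep apnea", len(idx)))
    for atom, code in (("furosemide_rx", "C03CA01"), ("vitamins_rx", "A11GA01")):
        idx = np.flatnonzero(fires[atom])
        dates = np.minimum(_rand_dates(rng, len(idx), lookback_start, year_end), cov_end[idx])
        costs = _gamma_costs(rng, len(idx), 25.0)
        emr.add_prescriptions(idx, dates, np.repeat(code, len(idx)), costs)
        admin.add_prescriptions(idx, dates, np.repeat(code, len(idx)), costs)

    # administrative frailty rules (index-year window)
    idx = np.flatnonzero(fires["ltc_entry"])
    starts = _rand_dates(rng, len(idx), f"{iy - 1}-01-01", f"{iy}-12-01")
    starts = np.minimum(starts, cov_end[idx])  # no admissions after death
    settings = rng.choice(("long_term_care", "assisted_living"), size=len(idx), p=(0.8, 0.2))
    admin.add_ltc(idx, starts, np.full(len(idx), np.datetime64("NaT", "D")), settings)

    idx = np.flatnonzero(fires["terminal_illness_dx"])
    tdates = _rand_dates(rng, len(idx), f"{iy}-01-01", year_end)
    tdates = np.minimum(tdates, cov_end[idx])
    admin.add_hospitals(idx, tdates, tdates, [["Z51.5"]] * len(idx),
                        _gamma_costs(rng, len(idx), 2000.0))

    for domain, codes in EFS_DOMAIN_CODES.items():
        _emit_marker_claims(admin, rng, fires[f"efs_{domain}"], codes,
                            f"{iy}-01-01", year_end, cov_end)

    # chronic conditions: billing pairs + hospital diagnoses in both sources
    truth_cond = {}
    for cond in CONDITIONS:
        has = fires[f"cond_{cond}"]
        truth_cond[cond] = has
        _emit_condition(emr, admin, rng, has, cond, cfg, cov_end)

    # antidepressant treatment evidence for depression persistence
    idx = np.flatnonzero(truth_cond["depression"] & (rng.random(n) < 0.7))
    dates = np.minimum(_rand_dates(rng, len(idx), f"{iy}-01-01", year_end), cov_end[idx])
    costs = _gamma_costs(rng, len(idx), 30.0)
    for sink in (emr, admin):
        sink.add_prescriptions(idx, dates, np.repeat(_ANTIDEPRESSANT, len(idx)), costs)

    # hospital stays (admin; next-year utilization + some index-window stays)
    hosp_rate = np.where(frail, cfg.hosp_rate_frail, cfg.hosp_rate_nonfrail)
    mean_los = np.where(frail, cfg.mean_los_frail, cfg.mean_los_nonfrail)
    for year, scale in ((iy, 0.7), (iy + 1, 1.0)):
        alive = _alive_mask(death_date, year)
        counts = rng.poisson(scale * hosp_rate) * alive
        idx = np.repeat(np.arange(n), counts)
        m = len(idx)
        admit = np.minimum(_rand_dates(rng, m, f"{year}-01-01", f"{year}-12-01"), cov_end[idx])
        los = 1 + rng.gamma(1.2, (mean_los[idx] - 1) / 1.2)
        discharge = np.minimum(admit + los.astype(int).astype("timedelta64[D]"), cov_end[idx])
        codes = [[c] for c in rng.choice(_ROUTINE_ICD10, size=m)]
        admin.add_hospitals(idx, admit, discharge, codes,
                            _gamma_costs(rng, m, 1100.0) * np.maximum(los, 1.0))

    # medications: distinct-drug counts per year drive polypharmacy
    med_mean = np.where(frail, cfg.mean_distinct_meds_frail, cfg.mean_distinct_meds_nonfrail)
    pool = np.asarray(_MED_POOL)
    for year in (iy, iy + 1):
        alive = _alive_mask(death_date, year)
        counts = np.minimum(rng.poisson(med_mean), len(pool)) * alive
        order = rng.random((n, len(pool))).argsort(axis=1)
        take = np.arange(len(pool))[None, :] < counts[:, None]
        meds = pool[order[take]]  # first counts[i] of each row, row-major
        idx = np.repeat(np.arange(n), counts)
        dates = np.minimum(
            _rand_dates(rng, len(idx), f"{year}-01-01", f"{year}-12-31"), cov_end[idx])
        costs = _gamma_costs(rng, len(idx), 60.0)
        for sink in (emr, admin):
            sink.add_prescriptions(idx, dates, meds, costs)

    # vital-sign observations (EMR only, characteristics window)
    has_obs = rng.random(n) < 0.9
    for kind, mean_frail, mean_fit, sd in (("systolic_bp", 124.0, 131.0, 17.0),
                                           ("diastolic_bp", 71.0, 74.0, 9.0)):
        counts = rng.poisson(2.2, n) * has_obs
        idx = np.repeat(np.arange(n), counts)
        mu = np.where(frail[idx], mean_frail, mean_fit)
        vals = np.clip(rng.normal(mu, sd), *((50, 300) if kind == "systolic_bp" else (20, 200)))
        obs_dates = np.minimum(
            _rand_dates(rng, len(idx), f"{iy - 1}-01-01", year_end), cov_end[idx])
        emr.add_observations(idx, obs_dates, kind, vals)
    counts = rng.poisson(1.2, n) * has_obs
    idx = np.repeat(np.arange(n), counts)
    obs_dates = np.minimum(_rand_dates(rng, len(idx), f"{iy - 1}-01-01", year_end), cov_end[idx])
    emr.add_observations(idx, obs_dates, "bmi",
                         np.clip(rng.normal(26.5, 4.5, len(idx)), 12, 60))

    # --- assemble bundles --------------------------------------------------
    linked = np.ones(n, dtype=bool)
    linked[:n_emr] = rng.random(n_emr) >= cfg.unlinked_fraction
    in_emr = np.arange(n) < n_emr
    in_admin = ~in_emr | linked
    emr_ids = np.array([f"E{i:07d}" for i in range(n)])
    admin_ids = np.array([f"A{i:07d}" for i in range(n)])

    persons = pd.DataFrame({
        "phn": phn,
        "birth_date": pd.to_datetime(birth),
        "sex": np.where(female, "female", "male"),
        "death_date": pd.to_datetime(death_date),
        "income_quintile": income,
        "postal_code": postal,
        "coverage_episodes": [
            [(pd.Timestamp(s).date(), pd.Timestamp(e).date())]
            for s, e in zip(cov_start, cov_end)
        ],
    })

    emr_bundle = _build_bundle("emr", persons, emr, in_emr, emr_ids)
    admin_bundle = _build_bundle("admin", persons, admin, in_admin, admin_ids)

    truth = pd.DataFrame({
        "person_id": np.where(in_emr, emr_ids, admin_ids),
        "phn": phn,
        "emr_person_id": np.where(in_emr, emr_ids, ""),
        "admin_person_id": np.where(in_admin, admin_ids, ""),
        "latent_cfs": latent,
        "truly_frail": frail,
        "died_index_year": died_index_year,
        "died_next_year": died_next,
        **{f"cond_{c}": truth_cond[c] for c in CONDITIONS},
    })
    return emr_bundle, admin_bundle, truth


def _alive_mask(death_date: np.ndarray, year: int) -> np.ndarray:
    return np.isnat(death_date) | (death_date >= np.datetime64(f"{year}-01-01"))


def _postal_codes(rng, rural: np.ndarray) -> np.ndarray:
    letters = np.array(list("ABCEGHJKLMNPRSTVXY"))
    n = len(rural)
    cols = [rng.choice(letters, n), None, rng.choice(letters, n),
            rng.integers(0, 10, n).astype(str), rng.choice(letters, n),
            rng.integers(0, 10, n).astype(str)]
    second = rng.integers(1, 10, n).astype(str)
    second[rural] = "0"
    cols[1] = second
    return np.array(["".join(parts) for parts in zip(*cols)])


def _emit_marker_claims(sink: _EventSink, rng, mask: np.ndarray, codes, start, end,
                        cov_end: np.ndarray):
    idx = np.flatnonzero(mask)
    reps = rng.integers(1, 3, size=len(idx))
    idx = np.repeat(idx, reps)
    dates = np.minimum(_rand_dates(rng, len(idx), start, end), cov_end[idx])
    sink.add_claims(idx, dates, rng.choice(np.asarray(codes), size=len(idx)))


def _emit_condition(emr: _EventSink, admin: _EventSink, rng, has: np.ndarray,
                    cond: str, cfg: SimConfig, cov_end: np.ndarray) -> None:
    """Billing-claim pairs inside the rolling window and hospital diagnoses."""
    icd9, icd10 = CONDITION_CODES[cond]
    iy = cfg.index_year
    window = 365 if cond == "depression" else 730
    n = len(has)
    for sink, p_detect in ((emr, 0.8), (admin, 0.8)):
        detected = has & (rng.random(n) < p_detect)
        idx = np.flatnonzero(detected)
        if cond == "depression":
            # anchor the pair year late enough that treated cases persist
            first = _rand_dates(rng, len(idx), f"{iy - 4}-01-01", f"{iy}-06-01")
        else:
            first = _rand_dates(rng, len(idx), f"{iy - 5}-01-01", f"{iy}-06-01")
        first = np.minimum(first, cov_end[idx])
        gap = rng.integers(20, int(window * 0.9), size=len(idx)).astype("timedelta64[D]")
        second = np.minimum(first + gap, cov_end[idx])
        codes1 = rng.choice(np.asarray(icd9), size=len(idx))
        codes2 = rng.choice(np.asarray(icd9), size=len(idx))
        sink.add_claims(idx, first, codes1)
        sink.add_claims(idx, second, codes2)
        # stray single claims on non-cases (below the two-claim threshold)
        stray = np.flatnonzero(~has & (rng.random(n) < 0.04))
        stray_dates = np.minimum(
            _rand_dates(rng, len(stray), f"{iy - 5}-01-01", f"{iy}-12-31"), cov_end[stray])
        sink.add_claims(stray, stray_dates, rng.choice(np.asarray(icd9), size=len(stray)))
    # hospital diagnosis (admin source only)
    idx = np.flatnonzero(has & (rng.random(n) < 0.25))
    dates = np.minimum(_rand_dates(rng, len(idx), f"{iy - 5}-01-01", f"{iy}-12-31"),
                       cov_end[idx] - np.timedelta64(3, "D"))
    admin.add_hospitals(idx, dates, dates + np.timedelta64(3, "D"),
                        [[c] for c in rng.choice(np.asarray(icd10), size=len(idx))],
                        _gamma_costs(rng, len(idx), 4000.0))


def _build_bundle(source: str, persons: pd.DataFrame, sink: _EventSink,
                  member: np.ndarray, ids: np.ndarray) -> SourceBundle:
    bundle = empty_bundle(source)
    ptab = persons[member].copy()
    ptab.insert(0, "person_id", ids[member])
    bundle.persons = ptab.reset_index(drop=True)

    def finalize(frames: list[pd.DataFrame]) -> pd.DataFrame | None:
        if not frames:
            return None
        df = pd.concat(frames, ignore_index=True)
        df = df[member[df["person_idx"].to_numpy()]].copy()
        df.insert(0, "person_id", ids[df.pop("person_idx").to_numpy()])
        return df.reset_index(drop=True)

    claims = finalize(sink.claims)
    if claims is not None:
        bundle.claims = claims
    hospitals = finalize(sink.hospitals)
    if hospitals is not None:
        bundle.hospitals = hospitals
    rx = finalize(sink.prescriptions)
    if rx is not None:
        rx["source"] = source
        rx = rx[["person_id", "dispense_date", "atc_code", "source", "cost"]]
        bundle.prescriptions = rx
    ltc = finalize(sink.ltc)
    if ltc is not None:
        bundle.ltc = ltc
    obs = finalize(sink.observations)
    if obs is not None:
        bundle.observations = obs
    return bundle.normalized()
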