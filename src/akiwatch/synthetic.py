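"""Seeded multi-site OMOP-CDM-style EHR simulator.

Generates the five event tables (person, measurement, drug_exposure,
condition_occurrence, procedure_occurrence) for a synthetic hospital site with
a planted case/control structure:

* every exposed patient is eligible by construction (two or more pre-index
  serum-creatinine tests at or below the ULN, plus a visit record at least 30
  days before index), minus a configurable ``spoiler_frac`` of patients who
  deliberately break one rule so the cohort exclusions are exercised;
* planted AKI cases cross 2 x ULN on an onset day drawn from a per-drug
  lognormal within the 60-day follow-up;
* case status is confounded with age, sex and baseline SCr on the log-odds
  scale, and case trajectories drift (falling lymphocytes, albumin and
  hemoglobin; rising urine pH and prothrombin time) over the 28 days before
  onset;
* laboratory values arrive on irregular days (per-variable Poisson-like gaps)
  so downstream forward-filling is exercised.

Simulation day 0 is anchored at 2015-01-01 so calendar arithmetic is
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .config import ConfigurationError, SiteSimConfig

EPOCH = pd.Timestamp("2015-01-01")

#: Lab catalog: baseline mean, between/within-patient sd, mean sampling gap (d).
LAB_CATALOG: dict[str, tuple[float, float, float]] = {
    "serum_creatinine": (0.85, 0.08, 4.0),   # mg/dL; special handling below
    "lymphocytes": (30.0, 6.0, 4.0),         # % of WBC
    "calcium": (9.2, 0.45, 5.0),             # mg/dL
    "albumin": (4.0, 0.35, 5.0),             # g/dL
    "hemoglobin": (13.0, 1.6, 3.0),          # g/dL
    "cholesterol": (180.0, 32.0, 7.0),       # mg/dL
    "urine_ph": (6.0, 0.55, 6.0),            # pH units
    "prothrombin_time": (12.5, 1.1, 6.0),    # seconds
    "glucose": (124.0, 42.0, 3.0),           # mg/dL
    "potassium": (4.1, 0.45, 4.0),           # mmol/L
    "sodium": (138.6, 3.6, 4.0),             # mmol/L
    "bun": (15.9, 6.5, 4.0),                 # mg/dL
    "platelets": (250.0, 65.0, 4.0),         # 10^3/uL
    "wbc": (7.5, 2.4, 3.0),                  # 10^3/uL
    "ast": (28.0, 11.0, 5.0),                # U/L
}

LAB_UNITS: dict[str, str] = {
    "serum_creatinine": "mg/dL", "lymphocytes": "%", "calcium": "mg/dL",
    "albumin": "g/dL", "hemoglobin": "g/dL", "cholesterol": "mg/dL",
    "urine_ph": "pH", "prothrombin_time": "s", "glucose": "mg/dL",
    "potassium": "mmol/L", "sodium": "mmol/L", "bun": "mg/dL",
    "platelets": "10^3/uL", "wbc": "10^3/uL", "ast": "U/L",
}

CO_MEDICATIONS = (
    "furosemide", "omeprazole", "metformin", "amlodipine",
    "aspirin", "ceftriaxone", "prednisolone", "heparin",
)

PROCEDURES = ("contrast_imaging", "major_surgery", "mechanical_ventilation")

TABLE_NAMES = (
    "person", "measurement", "drug_exposure",
    "condition_occurrence", "procedure_occurrence",
)

TABLE_COLUMNS: dict[str, list[str]] = {
    "person": ["person_id", "gender", "year_of_birth"],
    "measurement": ["person_id", "variable_label", "date", "value", "unit"],
    "drug_exposure": ["person_id", "drug_label", "start_date"],
    "condition_occurrence": ["person_id", "condition_label", "date"],
    "procedure_occurrence": ["person_id", "procedure_label", "date"],
}


@dataclass
class CdmBundle:
    """One site's OMOP-subset event tables.

    ``truth`` carries the generator's planted ground truth (case status, onset
    day, spoiler flag) for calibration checks; it is not part of the CDM
    surface and is not serialized by :func:`write_bundle`.
    """

    person: pd.DataFrame
    measurement: pd.DataFrame
    drug_exposure: pd.DataFrame
    condition_occurrence: pd.DataFrame
    procedure_occurrence: pd.DataFrame
    site_id: str
    truth: Optional[pd.DataFrame] = field(default=None, repr=False, compare=False)

    def table(self, name: str) -> pd.DataFrame:
        if name not in TABLE_NAMES:
            raise KeyError(name)
        return getattr(self, name)


def _day_to_date(days) -> pd.Series:
    return EPOCH + pd.to_timedelta(np.asarray(days, dtype=int), unit="D")


def _solve_intercept(lin: np.ndarray, target: float) -> float:
    """Intercept b0 such that mean(sigmoid(b0 + lin)) == target."""
    if target <= 0.0:
        return -np.inf
    if target >= 1.0:
        return np.inf

    def f(b0: float) -> float:
        return float(np.mean(expit(b0 + lin))) - target

    return brentq(f, -30.0, 30.0, xtol=1e-10)


def _poisson_gap_days(rng: np.random.Generator, start: int, stop: int,
                      mean_gap: float) -> np.ndarray:
    """Irregular event days in [start, stop] with ~geometric gaps."""
    days = []
    d = start + int(rng.integers(0, max(1, int(mean_gap))))
    while d <= stop:
        days.append(d)
        d += 1 + int(rng.poisson(max(mean_gap - 1.0, 0.1)))
    return np.asarray(days, dtype=int)


def simulate_confounded_covariates(n: int, rng: np.random.Generator,
                                   age_mean: float = 60.5, age_sd: float = 15.5,
                                   male_frac: float = 0.57,
                                   uln: float = 1.2,
                                   confound_strength: float = 0.6,
                                   aki_frac: float = 0.12) -> pd.DataFrame:
    """Draw patient covariates and a confounded case label.

    Case status is Bernoulli with log-odds linear in standardized age, sex
    and baseline SCr (slopes 1.0 / 0.8 / 0.6 times ``confound_strength``);
    the intercept is solved numerically so the marginal case rate equals
    ``aki_frac`` despite the confounding.
    """
    ages = np.clip(rng.normal(age_mean, age_sd, n), 18, 95)
    male = rng.random(n) < male_frac
    base_scr = np.clip(rng.normal(0.85, 0.18, n), 0.40, uln - 0.02)
    z_age = (ages - ages.mean()) / (ages.std() or 1.0)
    z_sex = male.astype(float) - male.mean()
    z_scr = (base_scr - base_scr.mean()) / (base_scr.std() or 1.0)
    lin = confound_strength * (1.0 * z_age + 0.8 * z_sex + 0.6 * z_scr)
    if aki_frac <= 0.0:
        is_case = np.zeros(n, dtype=bool)
    elif aki_frac >= 1.0:
        is_case = np.ones(n, dtype=bool)
    else:
        b0 = _solve_intercept(lin, aki_frac)
        is_case = rng.random(n) < expit(b0 + lin)
    return pd.DataFrame({"age": ages, "male": male,
                         "baseline_scr": base_scr, "is_case": is_case})


def generate_site(config: SiteSimConfig) -> CdmBundle:
    """Simulate one hospital site.

    Deterministic for a fixed seed. Returns a :class:`CdmBundle` whose
    ``truth`` table records person_id, drug, planted case status, onset day
    (days after index) and the spoiler rule broken, if any.
    """
    if not isinstance(config, SiteSimConfig):
        raise ConfigurationError("generate_site expects a SiteSimConfig")
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    drugs = sorted(config.drug_mix)
    probs = np.array([config.drug_mix[d] for d in drugs])

    person_ids = np.arange(1, n + 1)
    cov = simulate_confounded_covariates(
        n, rng, age_mean=config.age_mean, age_sd=config.age_sd,
        male_frac=config.male_frac, uln=config.uln,
        confound_strength=config.confound_strength,
        aki_frac=config.aki_frac)
    ages = cov["age"].to_numpy()
    male = cov["male"].to_numpy()
    base_scr = cov["baseline_scr"].to_numpy()
    is_case = cov["is_case"].to_numpy()
    drug_idx = rng.choice(len(drugs), size=n, p=probs)
    index_day = rng.integers(120, 220, n)

    # AKI onset days: per-drug lognormal, rejection-sampled into (0, 60]
    onset_day = np.full(n, -1, dtype=int)
    followup = 60
    for i in np.flatnonzero(is_case):
        med, lsd = config.onset_lognormal.get(drugs[drug_idx[i]], (17.0, 0.6))
        for _ in range(1000):
            d = int(round(float(rng.lognormal(np.log(med), lsd))))
            if 1 <= d <= followup:
                onset_day[i] = d
                break
        else:  # pragma: no cover - pathological config
            onset_day[i] = min(max(int(med), 1), followup)

    # spoilers: break exactly one eligibility rule each
    spoiler = np.array([""] * n, dtype=object)
    if config.spoiler_frac > 0:
        which = rng.random(n) < config.spoiler_frac
        kinds = rng.choice(
            ["no_prior_visit", "insufficient_preobs_scr", "preobs_scr_above_uln"],
            size=n,
        )
        spoiler[which] = kinds[which]

    meas_pid, meas_var, meas_day, meas_val = [], [], [], []
    cond_pid, cond_label, cond_day = [], [], []
    drug_pid, drug_label, drug_day = [], [], []
    proc_pid, proc_label, proc_day = [], [], []

    def add_meas(pid: int, var: str, day, val) -> None:
        day = np.atleast_1d(day)
        val = np.atleast_1d(val)
        meas_pid.extend([pid] * len(day))
        meas_var.extend([var] * len(day))
        meas_day.extend(day.tolist())
        meas_val.extend(val.tolist())

    comorbs = sorted(config.comorbidity_prev)
    threshold = 2.0 * config.uln  # AKI crossing level under the ULN baseline

    for i in range(n):
        pid = int(person_ids[i])
        idx = int(index_day[i])
        onset = int(onset_day[i])
        spoil = spoiler[i]

        # target-drug exposure (index) plus possible repeats
        drug_pid.append(pid)
        drug_label.append(drugs[drug_idx[i]])
        drug_day.append(idx)
        for _ in range(int(rng.poisson(0.7))):
            drug_pid.append(pid)
            drug_label.append(drugs[drug_idx[i]])
            drug_day.append(idx + int(rng.integers(1, 40)))

        # visit evidence >= 30 days before index (a routine lab), unless the
        # patient is a no_prior_visit spoiler
        earliest = idx - 29 if spoil == "no_prior_visit" else idx - 60
        if spoil != "no_prior_visit":
            visit_day = idx - int(rng.integers(35, 120))
            add_meas(pid, "hemoglobin", visit_day,
                     float(rng.normal(*LAB_CATALOG["hemoglobin"][:2])))

        # pre-index SCr: >= 2 tests in the pre-observation window, all <= ULN
        n_pre = 1 if spoil == "insufficient_preobs_scr" else 2 + int(rng.poisson(1.2))
        pre_pool = np.arange(max(earliest, idx - 59), idx)
        pre_days = np.sort(rng.choice(pre_pool, size=min(n_pre, len(pre_pool)),
                                      replace=False))
        n_pre = len(pre_days)
        pre_vals = np.clip(rng.normal(base_scr[i], 0.08, n_pre), 0.30, config.uln)
        if spoil == "preobs_scr_above_uln":
            pre_vals[-1] = config.uln + float(rng.uniform(0.1, 0.5))
        add_meas(pid, "serum_creatinine", pre_days, np.round(pre_vals, 3))

        # post-index SCr: below threshold for controls and pre-onset cases,
        # crossing planted exactly on the onset day
        post_days = _poisson_gap_days(rng, idx + 2, idx + followup, 4.0)
        post_vals = np.clip(rng.normal(base_scr[i], 0.10, len(post_days)),
                            0.30, threshold - 0.15)
        if onset > 0:
            od = idx + onset
            elevated = post_days >= od
            post_vals[elevated] = np.clip(
                rng.normal(threshold + 0.5, 0.3, int(elevated.sum())),
                threshold, threshold + 2.0)
            if od not in post_days:
                post_days = np.append(post_days, od)
                post_vals = np.append(
                    post_vals, threshold + float(rng.uniform(0.1, 1.0)))
        add_meas(pid, "serum_creatinine", post_days, np.round(post_vals, 3))

        # other labs on irregular grids, with prodromal drift for cases
        for lab, (mu, sd, gap) in LAB_CATALOG.items():
            if lab == "serum_creatinine":
                continue
            days = _poisson_gap_days(rng, earliest, idx + followup, gap)
            if len(days) == 0:
                continue
            vals = rng.normal(mu, sd, len(days))
            slope = config.drift_effects.get(lab, 0.0)
            if onset > 0 and slope != 0.0:
                od = idx + onset
                in_win = (days > od - 28) & (days <= od)
                weeks_in = (days[in_win] - (od - 28)) / 7.0
                vals[in_win] += slope * weeks_in
            vals = np.maximum(vals, 0.1)
            add_meas(pid, lab, days, np.round(vals, 3))

        # comorbidities recorded before index (doubling as visit evidence)
        lo, hi = (1, 29) if spoil == "no_prior_visit" else (30, 300)
        for cond in comorbs:
            if rng.random() < config.comorbidity_prev[cond]:
                cond_pid.append(pid)
                cond_label.append(cond)
                cond_day.append(idx - int(rng.integers(lo, hi)))

        # co-medications and procedures around the index date
        for med in CO_MEDICATIONS:
            if rng.random() < 0.22:
                for _ in range(1 + int(rng.poisson(0.5))):
                    drug_pid.append(pid)
                    drug_label.append(med)
                    drug_day.append(idx + int(rng.integers(-25, 45)))
        for proc in PROCEDURES:
            if rng.random() < 0.08:
                proc_pid.append(pid)
                proc_label.append(proc)
                proc_day.append(idx + int(rng.integers(-25, 45)))

    person = pd.DataFrame({
        "person_id": person_ids,
        "gender": np.where(male, "M", "F"),
        "year_of_birth": (EPOCH.year - np.round(ages)).astype(int),
    })
    measurement = pd.DataFrame({
        "person_id": meas_pid,
        "variable_label": meas_var,
        "date": _day_to_date(meas_day),
        "value": meas_val,
    })
    measurement["unit"] = measurement["variable_label"].map(LAB_UNITS)
    measurement = measurement.sort_values(
        ["person_id", "variable_label", "date"], kind="stable"
    ).reset_index(drop=True)
    drug_exposure = pd.DataFrame({
        "person_id": drug_pid,
        "drug_label": drug_label,
        "start_date": _day_to_date(drug_day),
    }).sort_values(["person_id", "drug_label", "start_date"],
                   kind="stable").reset_index(drop=True)
    condition_occurrence = pd.DataFrame({
        "person_id": cond_pid,
        "condition_label": cond_label,
        "date": _day_to_date(cond_day),
    }).astype({"person_id": int})
    procedure_occurrence = pd.DataFrame({
        "person_id": proc_pid,
        "procedure_label": proc_label,
        "date": _day_to_date(proc_day),
    }).astype({"person_id": int})

    truth = pd.DataFrame({
        "person_id": person_ids,
        "drug": [drugs[j] for j in drug_idx],
        "index_day": index_day,
        "is_case": is_case,
        "onset_day": onset_day,
        "spoiler": spoiler,
        "age": np.round(ages, 2),
        "male": male,
        "baseline_scr": np.round(base_scr, 3),
    })

    return CdmBundle(
        person=person,
        measurement=measurement,
        drug_exposure=drug_exposure,
        condition_occurrence=condition_occurrence,
        procedure_occurrence=procedure_occurrence,
        site_id=config.site_id,
        truth=truth,
    )


def generate_multisite(configs: Sequence[SiteSimConfig]) -> list[CdmBundle]:
    """Simulate several independent sites (a distributed-network stand-in)."""
    if len(configs) == 0:
        raise ConfigurationError("at least one site config is required")
    ids = [c.site_id for c in configs]
    if len(set(ids)) != len(ids):
        raise ConfigurationError(f"duplicate site_id in {ids}")
    return [generate_site(c) for c in configs]


def write_bundle(bundle: CdmBundle, directory) -> dict:
    """Write one CSV per CDM table plus a JSON manifest; returns the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"site_id": bundle.site_id, "files": {}, "row_counts": {}}
    for name in TABLE_NAMES:
        df = bundle.table(name)[TABLE_COLUMNS[name]]
        path = directory / f"{name}.csv"
        out = df.copy()
        for col in out.columns:
            if pd.api.types.is_datetime64_any_dtype(out[col]):
                out[col] = out[col].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)
        manifest["files"][name] = path.name
        manifest["row_counts"][name] = int(len(df))
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_bundle(directory, site_id: Optional[str] = None) -> CdmBundle:
    """Inverse of :func:`write_bundle`."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if site_id is None:
        with open(manifest_path) as fh:
            site_id = json.load(fh)["site_id"]
    date_cols = {"measurement": ["date"], "drug_exposure": ["start_date"],
                 "condition_occurrence": ["date"], "procedure_occurrence": ["date"],
                 "person": []}
    tables = {}
    for name in TABLE_NAMES:
        df = pd.read_csv(directory / f"{name}.csv",
                         parse_dates=date_cols[name] or False)
        tables[name] = df
    return CdmBundle(site_id=site_id, **tables)
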