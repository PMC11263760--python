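"""Case/control cohort construction from CDM event tables.

A patient exposed to a target drug enters follow-up at the index date (first
exposure). AKI is labeled at the first serum creatinine reaching twice the
baseline within 60 days after index; with the fixed-ULN policy the baseline is
the 1.2 mg/dL upper limit of normal, so the crossing level is 2.4 mg/dL.

Eligibility requires a visit record at least 30 days before index and at least
two SCr tests in the 60-day pre-observation window, none above the ULN.
Exclusion reasons are assigned in the fixed order no_prior_visit ->
insufficient_preobs_scr -> preobs_scr_above_uln.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .config import AkiCriteria
from .synthetic import CdmBundle

EXCLUSION_REASONS = (
    "no_prior_visit",
    "insufficient_preobs_scr",
    "preobs_scr_above_uln",
)

COHORT_COLUMNS = [
    "person_id", "site_id", "drug", "index_date", "label",
    "aki_onset_date", "onset_day", "exclusion_reason",
]


def index_date(bundle: CdmBundle, drug: str) -> "pd.Series":
    """Earliest exposure start date per person for ``drug``.

    Returns a Series indexed by person_id; empty when the drug is absent.
    """
    exp = bundle.drug_exposure
    mask = exp["drug_label"] == drug
    if not mask.any():
        return pd.Series(dtype="datetime64[ns]", name="index_date")
    out = exp.loc[mask].groupby("person_id")["start_date"].min()
    out.name = "index_date"
    return out


def detect_aki(scr: pd.Series, index: pd.Timestamp,
               criteria: AkiCriteria) -> Optional[pd.Timestamp]:
    """First AKI-qualifying SCr date within follow-up, or ``None``.

    ``scr`` is a date-indexed, date-sorted series of SCr values (mg/dL).
    The follow-up interval is half-open ``(index, index + followup_days]``:
    a spike on the index date itself is not attributed to the drug.
    """
    idx = scr.index
    if len(idx) > 1 and (np.diff(idx.values.astype("datetime64[ns]")) <
                         np.timedelta64(0)).any():
        raise ValueError("SCr series must be sorted by date")
    if (np.asarray(scr.values, dtype=float) <= 0).any():
        raise ValueError("SCr values must be positive")

    if criteria.baseline_policy == "uln_fixed":
        baseline = criteria.uln
    else:  # observed_mean_capped
        pre = scr[(idx < index) &
                  (idx >= index - pd.Timedelta(days=criteria.preobs_days))]
        baseline = min(float(pre.mean()), criteria.uln) if len(pre) else criteria.uln
    threshold = criteria.ratio * baseline

    end = index + pd.Timedelta(days=criteria.followup_days)
    window = scr[(idx > index) & (idx <= end)]
    hits = window[window >= threshold]
    if len(hits) == 0:
        return None
    return hits.index[0]


def apply_eligibility(bundle: CdmBundle, drug: str,
                      criteria: AkiCriteria) -> pd.DataFrame:
    """Label every person exposed to ``drug`` as case/control or excluded.

    Returns a CohortTable DataFrame with one row per exposed person: labeled
    rows carry ``label`` in {case, control} (cases also aki_onset_date and
    onset_day); excluded rows carry exactly one ``exclusion_reason``.
    """
    idx_map = index_date(bundle, drug)
    meas = bundle.measurement
    scr_all = meas[meas["variable_label"] == "serum_creatinine"]
    scr_by_person = {pid: grp.sort_values("date")
                     for pid, grp in scr_all.groupby("person_id")}

    # any recorded event counts as visit evidence
    event_dates = pd.concat([
        meas[["person_id", "date"]],
        bundle.condition_occurrence[["person_id", "date"]],
        bundle.procedure_occurrence[["person_id", "date"]],
        bundle.drug_exposure.rename(columns={"start_date": "date"})[
            ["person_id", "date"]],
    ], ignore_index=True)
    first_event = event_dates.groupby("person_id")["date"].min()

    rows = []
    for pid, index in idx_map.items():
        row = {
            "person_id": pid, "site_id": bundle.site_id, "drug": drug,
            "index_date": index, "label": None, "aki_onset_date": pd.NaT,
            "onset_day": np.nan, "exclusion_reason": None,
        }
        grp = scr_by_person.get(pid)
        scr = (grp.groupby("date")["value"].mean()
               if grp is not None else pd.Series(dtype=float))

        visit_cut = index - pd.Timedelta(days=criteria.min_prior_visit_days)
        pre_lo = index - pd.Timedelta(days=criteria.preobs_days)
        pre = scr[(scr.index >= pre_lo) & (scr.index < index)] if len(scr) else scr

        if pid not in first_event.index or first_event[pid] > visit_cut:
            row["exclusion_reason"] = "no_prior_visit"
        elif len(pre) < criteria.min_preobs_scr:
            row["exclusion_reason"] = "insufficient_preobs_scr"
        elif (pre > criteria.uln).any():
            row["exclusion_reason"] = "preobs_scr_above_uln"
        else:
            onset = detect_aki(scr, index, criteria) if len(scr) else None
            if onset is not None:
                row["label"] = "case"
                row["aki_onset_date"] = onset
                row["onset_day"] = int((onset - index).days)
            else:
                row["label"] = "control"
        rows.append(row)

    out = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    if len(out) == 0:
        out = pd.DataFrame(columns=COHORT_COLUMNS)
    return out


def _age_at_index(cohort: pd.DataFrame, person: pd.DataFrame) -> pd.Series:
    yob = person.set_index("person_id")["year_of_birth"]
    years = cohort["index_date"].dt.year
    return years.values - yob.reindex(cohort["person_id"]).values


def person_covariates(cohort: pd.DataFrame, bundle: CdmBundle) -> pd.DataFrame:
    """Age, sex and mean pre-index SCr per labeled cohort member."""
    lab = cohort[cohort["label"].notna()].copy()
    lab["age"] = _age_at_index(lab, bundle.person)
    sex = bundle.person.set_index("person_id")["gender"]
    lab["male"] = (sex.reindex(lab["person_id"]).values == "M").astype(int)

    scr = bundle.measurement[
        bundle.measurement["variable_label"] == "serum_creatinine"]
    merged = scr.merge(lab[["person_id", "index_date"]], on="person_id")
    pre = merged[(merged["date"] < merged["index_date"]) &
                 (merged["date"] >= merged["index_date"]
                  - pd.Timedelta(days=60))]
    base = pre.groupby("person_id")["value"].mean()
    lab["baseline_scr"] = base.reindex(lab["person_id"]).values
    return lab


def demographics_table(cohort: pd.DataFrame, bundle: CdmBundle,
                       labs_pre_index: bool = True) -> pd.DataFrame:
    """Per-group, per-site demographic and clinical summary with pooled totals.

    Rows: n; age mean (SD); sex counts (%); comorbidity counts (%);
    pre-medication lab means (SD). Percentages are count / group n x 100
    rounded to 2 decimals.
    """
    lab = person_covariates(cohort, bundle)
    conds = bundle.condition_occurrence
    cond_names = sorted(conds["condition_label"].unique()) if len(conds) else []
    has_cond = {
        c: set(conds.loc[conds["condition_label"] == c, "person_id"])
        for c in cond_names
    }

    meas = bundle.measurement
    lab_names = [v for v in sorted(meas["variable_label"].unique())
                 if v != "serum_creatinine"]

    records = []
    for group in ("case", "control"):
        sub = lab[lab["label"] == group]
        cell: dict = {"group": group, "site_id": bundle.site_id, "n": len(sub)}
        if len(sub):
            cell["age_mean"] = round(float(sub["age"].mean()), 2)
            cell["age_sd"] = round(float(sub["age"].std(ddof=1)), 2) \
                if len(sub) > 1 else 0.0
            n_male = int(sub["male"].sum())
            cell["male_n"] = n_male
            cell["male_pct"] = round(100.0 * n_male / len(sub), 2)
            cell["baseline_scr_mean"] = round(float(sub["baseline_scr"].mean()), 3)
            for c in cond_names:
                k = int(sub["person_id"].isin(has_cond[c]).sum())
                cell[f"{c}_n"] = k
                cell[f"{c}_pct"] = round(100.0 * k / len(sub), 2)
            if labs_pre_index:
                merged = meas.merge(sub[["person_id", "index_date"]],
                                    on="person_id")
                pre = merged[merged["date"] < merged["index_date"]]
                for v in lab_names:
                    vals = pre.loc[pre["variable_label"] == v, "value"]
                    if len(vals):
                        cell[f"{v}_mean"] = round(float(vals.mean()), 2)
                        cell[f"{v}_sd"] = round(float(vals.std(ddof=1)), 2) \
                            if len(vals) > 1 else 0.0
        records.append(cell)
    return pd.DataFrame(records)


def pool_site_summaries(site_rows: pd.DataFrame) -> pd.DataFrame:
    """Pool per-site summary rows into per-group totals.

    ``site_rows`` holds one row per (group, site) with columns ``group``,
    ``site_id``, ``n``, optional ``*_n`` count columns and optional
    ``*_mean`` columns. Pooled counts are sums across sites; pooled
    percentages are pooled count / pooled n x 100 (2 decimals); pooled means
    are n-weighted averages of site means.
    """
    out = []
    for group, sub in site_rows.groupby("group", sort=False):
        n = int(sub["n"].sum())
        row: dict = {"group": group, "site_id": "pooled", "n": n}
        for col in sub.columns:
            if col.endswith("_n"):
                k = int(sub[col].sum())
                row[col] = k
                row[col[:-2] + "_pct"] = round(100.0 * k / n, 2) if n else 0.0
            elif col.endswith("_mean"):
                w = sub["n"].to_numpy(float)
                row[col] = float(np.average(sub[col].to_numpy(float), weights=w)) \
                    if w.sum() else np.nan
        out.append(row)
    return pd.DataFrame(out)


def pooled_demographics(cohorts_and_bundles, **kw) -> pd.DataFrame:
    """Demographics across sites: per-site rows plus pooled totals."""
    per_site = pd.concat(
        [demographics_table(c, b, **kw) for c, b in cohorts_and_bundles],
        ignore_index=True)
    pooled = pool_site_summaries(per_site)
    return pd.concat([per_site, pooled], ignore_index=True)
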