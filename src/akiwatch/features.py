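"""Candidate-predictor selection and time-series window construction.

Event tables are pivoted into per-person daily grids (variables in columns,
days in rows, day 0 = index date). Labs and diagnoses are forward-filled from
the last observation; medications and procedures are zero-filled binary
indicators. Predictors are screened by comparing each variable at cohort
enrollment versus at AKI onset across cases: paired t test for continuous
variables, McNemar for dichotomous ones.

Windows are 28 days long, advanced by a 14-day stride; a window is positive
when the person's AKI onset falls within one prediction cycle (14 days) after
the window's end. Windows never contain post-onset days, and train /
validation / test splits (6:2:2) are made at person level, stratified by case
status.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import WindowSpec
from .synthetic import CdmBundle

CONTINUOUS_KINDS = ("lab",)
BINARY_KINDS = ("condition", "drug", "procedure")


# ---------------------------------------------------------------------------
# paired tests

def paired_t(x, y) -> tuple[float, float]:
    """Two-tailed paired t test.

    t = mean(d) / (sd(d)/sqrt(n)) on d = x - y with the sample sd; p from the
    t distribution with n-1 df. Zero-variance differences yield p = 1 with a
    warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("paired_t needs two equal-length vectors, n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        warnings.warn("zero-variance differences in paired t test; p = 1")
        return 0.0, 1.0
    n = len(d)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def mcnemar(b: int, c: int) -> tuple[float, float]:
    """McNemar chi-square on discordant counts: chi2 = (b-c)^2 / (b+c).

    ``b`` and ``c`` are the two discordant-pair counts. b + c = 0 gives
    chi2 = 0, p = 1.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    if b + c == 0:
        return 0.0, 1.0
    chi2 = (b - c) ** 2 / (b + c)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


# ---------------------------------------------------------------------------
# daily grids

@dataclass
class DailyGrid:
    """Per-person day x variable matrices, day 0 = index date.

    ``start_day`` may be negative: rows then cover pre-index history
    (``start_day .. n_days - 1``), so prediction windows can use the weeks
    leading up to the index date — AKI onset medians for the target drugs are
    only 12-23 days, well inside one window length of the index.
    """

    variables: list  # variable names
    kinds: list      # parallel: lab | condition | drug | procedure
    n_days: int      # exclusive end day (relative to index)
    start_day: int = 0
    data: dict = field(default_factory=dict)  # person_id -> (rows, V) array

    def row(self, day: int) -> int:
        """Row index of calendar day ``day`` (day 0 = index date)."""
        if not self.start_day <= day < self.n_days:
            raise IndexError(f"day {day} outside grid "
                             f"[{self.start_day}, {self.n_days})")
        return day - self.start_day

    @property
    def n_rows(self) -> int:
        return self.n_days - self.start_day

    @property
    def continuous_mask(self) -> np.ndarray:
        return np.array([k in CONTINUOUS_KINDS for k in self.kinds])


def variable_catalog(bundle: CdmBundle,
                     exclude_drugs: Sequence[str] = ()) -> list[tuple[str, str]]:
    """(variable, kind) pairs observed in a bundle, target drugs excluded."""
    out = [(v, "lab") for v in
           sorted(bundle.measurement["variable_label"].unique())]
    out += [(v, "condition") for v in
            sorted(bundle.condition_occurrence["condition_label"].unique())]
    out += [(v, "drug") for v in
            sorted(bundle.drug_exposure["drug_label"].unique())
            if v not in exclude_drugs]
    out += [(v, "procedure") for v in
            sorted(bundle.procedure_occurrence["procedure_label"].unique())]
    return out


def build_grid(bundle: CdmBundle, cohort: pd.DataFrame,
               variables: Sequence[tuple[str, str]],
               n_days: int = 61, start_day: int = 0) -> DailyGrid:
    """Pivot events into fully imputed daily grids for labeled cohort members.

    Labs and conditions are forward-filled; lab days before the first
    observation take the last pre-index value when one exists, otherwise the
    cohort median of that lab (a fallback for patients with no history).
    Drugs and procedures are 1 on event days and 0 elsewhere. Same-day
    duplicate labs are averaged. Variables never observed anywhere are
    dropped with a warning.
    """
    labeled = cohort[cohort["label"].notna()]
    index_by_pid = labeled.set_index("person_id")["index_date"]

    sources = {
        "lab": (bundle.measurement, "variable_label", "date"),
        "condition": (bundle.condition_occurrence, "condition_label", "date"),
        "drug": (bundle.drug_exposure, "drug_label", "start_date"),
        "procedure": (bundle.procedure_occurrence, "procedure_label", "date"),
    }

    # relative-day event frames per kind, restricted to cohort members
    frames = {}
    for kind, (df, label_col, date_col) in sources.items():
        sub = df[df["person_id"].isin(index_by_pid.index)].copy()
        if len(sub) == 0:
            frames[kind] = sub.assign(day=pd.Series(dtype=int))
            continue
        sub["day"] = (
            sub[date_col] - index_by_pid.reindex(sub["person_id"]).values
        ).dt.days
        frames[kind] = sub.rename(columns={label_col: "variable"})

    keep, kinds = [], []
    cohort_median: dict[str, float] = {}
    for var, kind in variables:
        src = frames[kind]
        obs = src[src["variable"] == var] if len(src) else src
        if len(obs) == 0:
            warnings.warn(f"variable {var!r} has no observations; dropped")
            continue
        keep.append(var)
        kinds.append(kind)
        if kind == "lab":
            cohort_median[var] = float(obs["value"].median())

    grid = DailyGrid(variables=keep, kinds=kinds, n_days=n_days,
                     start_day=start_day)
    days = np.arange(start_day, n_days)

    for pid in index_by_pid.index:
        mat = np.zeros((len(days), len(keep)))
        for j, (var, kind) in enumerate(zip(keep, kinds)):
            src = frames[kind]
            ev = src[(src["person_id"] == pid) & (src["variable"] == var)]
            if kind == "lab":
                if len(ev):
                    daily = ev.groupby("day")["value"].mean()
                else:
                    daily = pd.Series(dtype=float)
                in_win = daily[(daily.index >= start_day)
                               & (daily.index < n_days)]
                col = pd.Series(np.nan, index=days)
                col.loc[in_win.index] = in_win.values
                col = col.ffill()
                if col.isna().any():
                    pre = daily[daily.index < start_day]
                    seed_val = float(pre.iloc[-1]) if len(pre) \
                        else cohort_median[var]
                    col = col.fillna(seed_val)
                mat[:, j] = col.values
            elif kind == "condition":
                # diagnosed on/before a day -> 1 from that day onward
                first = int(ev["day"].min()) if len(ev) else None
                if first is not None and first < n_days:
                    mat[max(first, start_day) - start_day:, j] = 1.0
            else:  # drug / procedure: zero fill
                ev_days = ev["day"].to_numpy(int) if len(ev) else []
                for d in ev_days:
                    if start_day <= d < n_days:
                        mat[d - start_day, j] = 1.0
        grid.data[pid] = mat
    return grid


# ---------------------------------------------------------------------------
# predictor selection

def select_predictors(cohort: pd.DataFrame, grid: DailyGrid,
                      alpha: float = 0.05, min_pairs: int = 10,
                      fdr: bool = False) -> pd.DataFrame:
    """Screen variables by their change between enrollment and AKI onset.

    For each case, pairs the variable's value at day 0 (index) with its value
    at the onset day; continuous variables go through the paired t test and
    binary ones through McNemar. A variable is selected when p < alpha
    (optionally after Benjamini-Hochberg adjustment).
    """
    cases = cohort[(cohort["label"] == "case")
                   & cohort["onset_day"].notna()]
    rows = []
    for j, (var, kind) in enumerate(zip(grid.variables, grid.kinds)):
        at_index, at_onset = [], []
        for _, r in cases.iterrows():
            pid, onset = r["person_id"], int(r["onset_day"])
            mat = grid.data.get(pid)
            if mat is None or onset >= grid.n_days:
                continue
            at_index.append(mat[grid.row(0), j])
            at_onset.append(mat[grid.row(onset), j])
        if len(at_index) < min_pairs:
            warnings.warn(f"variable {var!r}: only {len(at_index)} complete "
                          f"pairs; skipped")
            rows.append({"variable": var, "kind": kind, "statistic": np.nan,
                         "p_value": np.nan, "selected": False})
            continue
        x = np.asarray(at_onset, float)
        y = np.asarray(at_index, float)
        if kind in CONTINUOUS_KINDS:
            stat, p = paired_t(x, y)
        else:
            b = int(np.sum((y == 1) & (x == 0)))
            c = int(np.sum((y == 0) & (x == 1)))
            stat, p = mcnemar(b, c)
        rows.append({"variable": var, "kind": kind, "statistic": stat,
                     "p_value": p, "selected": bool(p < alpha)})
    out = pd.DataFrame(rows)
    if fdr and out["p_value"].notna().any():
        mask = out["p_value"].notna()
        out.loc[mask, "selected"] = _bh_reject(
            out.loc[mask, "p_value"].to_numpy(), alpha)
    return out


def _bh_reject(p: np.ndarray, alpha: float) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    k = np.max(np.nonzero(passed)[0]) + 1 if passed.any() else 0
    out = np.zeros(m, bool)
    out[order[:k]] = True
    return out


# ---------------------------------------------------------------------------
# windows

@dataclass
class WindowTensor:
    """Windows x timesteps x variables with labels and provenance."""

    data: np.ndarray          # (n, T, V)
    labels: np.ndarray        # (n,) in {0, 1}
    meta: pd.DataFrame        # person_id, start_day, site_id, drug, is_case
    variables: list
    kinds: list

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx) -> "WindowTensor":
        idx = np.asarray(idx)
        return WindowTensor(self.data[idx], self.labels[idx],
                            self.meta.iloc[idx].reset_index(drop=True),
                            self.variables, self.kinds)


def window_count(length: int, T: int = 28, stride: int = 14) -> int:
    """Number of windows fitting in ``length`` usable days."""
    if length < T:
        return 0
    return (length - T) // stride + 1


def make_windows(grid: DailyGrid, cohort_row: pd.Series,
                 spec: WindowSpec = WindowSpec()) -> list[dict]:
    """Windows for one cohort member.

    Windows start at the grid's first day (day 0 when there is no pre-index
    lookback) and advance by the stride. For cases, only windows ending at or
    before the onset day are emitted; a window is labeled 1 iff onset falls
    in ``(end, end + horizon]``. Controls contribute all windows within
    follow-up, labeled 0.
    """
    pid = cohort_row["person_id"]
    mat = grid.data.get(pid)
    if mat is None:
        return []
    is_case = cohort_row["label"] == "case"
    onset = int(cohort_row["onset_day"]) if is_case else None
    usable = onset if is_case else grid.n_days
    out = []
    for s in range(grid.start_day, usable - spec.length + 1, spec.stride):
        end = s + spec.length
        label = int(is_case and (end < onset <= end + spec.horizon))
        out.append({
            "person_id": pid, "start_day": s,
            "site_id": cohort_row.get("site_id"),
            "drug": cohort_row.get("drug"),
            "is_case": bool(is_case),
            "label": label,
            "data": mat[s - grid.start_day:end - grid.start_day, :],
        })
    return out


def build_window_tensor(grid: DailyGrid, cohort: pd.DataFrame,
                        spec: WindowSpec = WindowSpec()) -> WindowTensor:
    """All windows for a labeled cohort, stacked into one tensor."""
    records = []
    for _, row in cohort[cohort["label"].notna()].iterrows():
        records.extend(make_windows(grid, row, spec))
    if not records:
        return WindowTensor(
            np.zeros((0, spec.length, len(grid.variables))),
            np.zeros(0, int),
            pd.DataFrame(columns=["person_id", "start_day", "site_id",
                                  "drug", "is_case"]),
            grid.variables, grid.kinds)
    data = np.stack([r.pop("data") for r in records])
    meta = pd.DataFrame(records)
    labels = meta.pop("label").to_numpy(int)
    return WindowTensor(data, labels, meta, grid.variables, grid.kinds)


def split_622(windows: WindowTensor, seed: int
              ) -> tuple[WindowTensor, WindowTensor, WindowTensor]:
    """Person-level 6:2:2 train/validation/test split, stratified by case.

    All windows of one person land in the same split. Within each case
    stratum persons are shuffled with the given seed and allocated
    60/20/20 by rounded counts.
    """
    meta = windows.meta
    persons = meta.drop_duplicates("person_id")[["person_id", "is_case"]]
    if len(persons) < 5:
        raise ValueError("split_622 requires at least 5 distinct persons")
    rng = np.random.default_rng(seed)

    strata = [g for _, g in persons.groupby("is_case")]
    if len(strata) < 2:
        warnings.warn("only one class present; unstratified split")
    assign: dict = {}
    for g in strata:
        ids = g["person_id"].to_numpy()
        rng.shuffle(ids)
        m = len(ids)
        n_val = int(round(0.2 * m))
        n_test = int(round(0.2 * m))
        for pid in ids[: m - n_val - n_test]:
            assign[pid] = "train"
        for pid in ids[m - n_val - n_test: m - n_test]:
            assign[pid] = "val"
        for pid in ids[m - n_test:]:
            assign[pid] = "test"

    split_of = meta["person_id"].map(assign)
    out = []
    for name in ("train", "val", "test"):
        out.append(windows.subset(np.flatnonzero(split_of == name)))
    return tuple(out)


class WindowScaler:
    """Standardize continuous channels of a window tensor.

    Fit on the training split; binary channels pass through untouched.
    """

    def fit(self, windows: WindowTensor) -> "WindowScaler":
        mask = np.array([k in CONTINUOUS_KINDS for k in windows.kinds])
        X = windows.data
        self.mask_ = mask
        self.mean_ = np.zeros(X.shape[2])
        self.sd_ = np.ones(X.shape[2])
        if len(windows) and mask.any():
            vals = X[:, :, mask].reshape(-1, mask.sum())
            self.mean_[mask] = vals.mean(axis=0)
            sd = vals.std(axis=0)
            sd[sd == 0] = 1.0
            self.sd_[mask] = sd
        return self

    def transform(self, windows: WindowTensor) -> WindowTensor:
        X = (windows.data - self.mean_) / self.sd_
        return WindowTensor(X, windows.labels, windows.meta,
                            windows.variables, windows.kinds)

    def fit_transform(self, windows: WindowTensor) -> WindowTensor:
        return self.fit(windows).transform(windows)
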