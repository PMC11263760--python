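"""Attention aggregation and cohort-level statistics.

The trained model's temporal attention (``alpha``, per variable over time)
and variable attention (``beta``) are pooled across windows into a temporal
feature-importance surface: per variable and day,

    S[v, t] = sum_s beta_s[v] * alpha_s[v, t] / sum_s beta_s[v],

then averaged into weekly bins (weeks -4..-1 before the window end). The
module also provides the accompanying statistics: repeated-measures ANOVA for
temporal differences, AKI onset-time medians/IQRs with pairwise tests between
drugs and sites, and chi-square / Welch t group comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AttentionSummary:
    """Aggregated variable x week attention surface.

    The rows of ``daily``/``weekly`` describe *when* a variable matters
    (each row's daily values sum to ~1 over the window); ``overall`` is the
    mean variable attention (beta) and says *how much* a variable matters.
    """

    daily: pd.DataFrame    # variables x T days
    weekly: pd.DataFrame   # variables x weeks (-4..-1)
    overall: pd.Series     # per-variable mean beta (variable importance)


def aggregate_attention(alphas: np.ndarray, betas: np.ndarray,
                        variables, weighted: bool = True) -> AttentionSummary:
    """Pool per-window attention into the temporal importance surface.

    Parameters
    ----------
    alphas : (n_samples, V, T)
    betas : (n_samples, V)
    weighted : bool
        If True (default), each sample's temporal attention is weighted by its
        variable attention and normalized by the summed variable attention;
        if False, a plain per-variable mean of alpha is used.
    """
    alphas = np.asarray(alphas, float)
    betas = np.asarray(betas, float)
    if alphas.ndim != 3 or betas.ndim != 2 or alphas.shape[:2] != betas.shape:
        raise ValueError("alphas must be (n, V, T) and betas (n, V)")
    n, V, T = alphas.shape
    if weighted:
        denom = betas.sum(axis=0)                      # (V,)
        ok = denom > 0
        if not ok.all():
            warnings.warn("all-zero variable attention for some variables; "
                          "their rows are dropped")
        S = np.full((V, T), np.nan)
        num = np.einsum("nv,nvt->vt", betas, alphas)
        S[ok] = num[ok] / denom[ok, None]
    else:
        S = alphas.mean(axis=0)
        ok = np.ones(V, bool)

    variables = list(variables)
    daily = pd.DataFrame(S[ok], index=[v for v, k in zip(variables, ok) if k],
                         columns=np.arange(T))
    n_weeks = T // 7
    week_cols = [f"week_{-(n_weeks - w)}" for w in range(n_weeks)]
    weekly = pd.DataFrame(
        {week_cols[w]: daily.iloc[:, w * 7:(w + 1) * 7].mean(axis=1)
         for w in range(n_weeks)})
    overall = pd.Series(betas.mean(axis=0)[ok], index=daily.index,
                        name="overall")
    return AttentionSummary(daily=daily, weekly=weekly, overall=overall)


def repeated_anova(values: np.ndarray) -> tuple[float, float]:
    """One-way within-subject (repeated-measures) ANOVA.

    ``values`` is a complete subjects x timepoints matrix. Returns
    (F, p) with F = MS_time / MS_error on (k-1, (n-1)(k-1)) df. A zero
    error mean square (perfectly parallel profiles) is reported as
    (inf, 0); zero time effect gives (0, 1).
    """
    Y = np.asarray(values, float)
    if Y.ndim != 2 or Y.shape[0] < 2 or Y.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 timepoints")
    if not np.isfinite(Y).all():
        raise ValueError("matrix must be complete (no missing values)")
    n, k = Y.shape
    grand = Y.mean()
    ss_time = n * ((Y.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((Y.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((Y - grand) ** 2).sum()
    ss_err = ss_total - ss_time - ss_subj
    df_time = k - 1
    df_err = (n - 1) * (k - 1)
    ms_time = ss_time / df_time
    ms_err = ss_err / df_err
    if ms_err <= 1e-300:
        if ms_time <= 1e-300:
            return 0.0, 1.0
        return float("inf"), 0.0
    F = ms_time / ms_err
    p = float(stats.f.sf(F, df_time, df_err))
    return float(F), p


def onset_stats(cohort: pd.DataFrame, min_cell: int = 20) -> dict:
    """AKI onset-day summary per (drug, site) plus pairwise comparisons.

    Cells with fewer than ``min_cell`` cases are dropped from the per-cell
    table (mirroring the exclusion of under-sized site/drug models). Medians
    and IQRs use linear-interpolation quantiles; pairwise drug and site
    comparisons are independent two-sided t tests on onset days.
    """
    cases = cohort[(cohort["label"] == "case") & cohort["onset_day"].notna()]
    if len(cases) == 0:
        return {"cells": pd.DataFrame(), "overall": {},
                "drug_pairs": pd.DataFrame(), "site_pairs": pd.DataFrame()}

    def summarize(days: np.ndarray) -> dict:
        return {"n": int(len(days)),
                "median": float(np.median(days)),
                "q1": float(np.quantile(days, 0.25)),
                "q3": float(np.quantile(days, 0.75))}

    cells = []
    for (drug, site), grp in cases.groupby(["drug", "site_id"]):
        if len(grp) < min_cell:
            continue
        cells.append({"drug": drug, "site_id": site,
                      **summarize(grp["onset_day"].to_numpy(float))})
    overall = summarize(cases["onset_day"].to_numpy(float))

    def pairwise(by: str) -> pd.DataFrame:
        rows = []
        groups = {k: g["onset_day"].to_numpy(float)
                  for k, g in cases.groupby(by)}
        for a, b in combinations(sorted(groups), 2):
            if len(groups[a]) < 2 or len(groups[b]) < 2:
                continue
            t, p = stats.ttest_ind(groups[a], groups[b])
            rows.append({by + "_a": a, by + "_b": b,
                         "t": float(t), "p": float(p)})
        return pd.DataFrame(rows)

    return {"cells": pd.DataFrame(cells), "overall": overall,
            "drug_pairs": pairwise("drug"), "site_pairs": pairwise("site_id")}


def per_drug_onset(cohort: pd.DataFrame) -> pd.DataFrame:
    """Pooled onset median and IQR per drug across sites."""
    cases = cohort[(cohort["label"] == "case") & cohort["onset_day"].notna()]
    rows = []
    for drug, grp in cases.groupby("drug"):
        d = grp["onset_day"].to_numpy(float)
        rows.append({"drug": drug, "n": len(d),
                     "median": float(np.median(d)),
                     "q1": float(np.quantile(d, 0.25)),
                     "q3": float(np.quantile(d, 0.75))})
    return pd.DataFrame(rows)


def group_tests(values: pd.DataFrame, group_col: str = "label") -> pd.DataFrame:
    """Case/control comparisons per characteristic.

    Binary columns (only 0/1 values) get an uncorrected Pearson chi-square on
    the 2x2 table; continuous columns get a Welch two-sample t test. A warning
    column flags 2x2 tables with an expected cell below 1.
    """
    g = values[group_col]
    groups = sorted(g.dropna().unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    a_mask = g == groups[0]
    rows = []
    for col in values.columns:
        if col == group_col:
            continue
        x = pd.to_numeric(values[col], errors="coerce")
        xa, xb = x[a_mask].dropna(), x[~a_mask].dropna()
        if set(x.dropna().unique()) <= {0, 1}:
            table = np.array([
                [int((xa == 1).sum()), int((xa == 0).sum())],
                [int((xb == 1).sum()), int((xb == 0).sum())]])
            chi2, p, warning = _pearson_chi2(table)
            rows.append({"characteristic": col, "test": "chi2",
                         "statistic": chi2, "p": p, "warning": warning})
        else:
            t, p = stats.ttest_ind(xa, xb, equal_var=False)
            rows.append({"characteristic": col, "test": "welch_t",
                         "statistic": float(t), "p": float(p),
                         "warning": ""})
    return pd.DataFrame(rows)


def _pearson_chi2(table: np.ndarray) -> tuple[float, float, str]:
    """Uncorrected Pearson chi-square on a 2x2 table."""
    obs = np.asarray(table, float)
    total = obs.sum()
    expected = np.outer(obs.sum(1), obs.sum(0)) / total
    warning = "expected cell < 1" if (expected < 1).any() else ""
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.nansum((obs - expected) ** 2 / expected)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p, warning


def export_heatmap(summary: AttentionSummary, path, render: bool = True) -> None:
    """Write the weekly attention surface as CSV (rows sorted by overall
    score, descending) and optionally render it as a heat-map image."""
    if len(summary.weekly) == 0:
        raise ValueError("empty attention summary")
    order = summary.overall.sort_values(ascending=False).index
    table = summary.weekly.loc[order]
    table.to_csv(path)
    if render:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(6, 0.4 * len(table) + 1.5), constrained_layout=True)
        im = ax.imshow(table.to_numpy(), aspect="auto", cmap="viridis")
        ax.set_xticks(range(table.shape[1]), table.columns)
        ax.set_yticks(range(table.shape[0]), table.index)
        ax.set_xlabel("week before window end")
        fig.colorbar(im, ax=ax, label="aggregated attention")
        fig.savefig(str(path) + ".png", dpi=120)
        plt.close(fig)
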