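"""Propensity-score matching of controls to cases.

Covariates (age, sex, baseline serum creatinine) are standardized, a logistic
regression produces a propensity score for case status, and controls are
greedily matched 1:k (default 1:3) to cases by nearest propensity without
replacement. Balance is reported as raw mean differences and absolute
standardized mean differences (SMD) before and after matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator


@dataclass
class PropensityModel:
    """Fitted logistic propensity model on standardized covariates."""

    coefficients: np.ndarray
    intercept: float
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    columns: list

    def score(self, covariates: pd.DataFrame) -> np.ndarray:
        X = covariates[self.columns].to_numpy(float)
        Z = (X - self.scaler_mean) / self.scaler_sd
        return expit(Z @ self.coefficients + self.intercept)


def standardize(covariates: pd.DataFrame):
    """Column-wise standard scaling (population sd). Returns (table, scaler).

    The scaler is a (mean, sd) pair of arrays for reuse on new data.
    """
    X = covariates.to_numpy(float)
    if X.shape[0] < 2:
        raise ValueError("standardize requires n >= 2")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population sd
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [covariates.columns[j] for j in zero]
        raise ValueError(f"zero-variance column(s): {names}")
    Z = (X - mean) / sd
    out = pd.DataFrame(Z, index=covariates.index, columns=covariates.columns)
    return out, (mean, sd)


def fit_logistic(Z: np.ndarray, y: np.ndarray, tol: float = 1e-8,
                 max_iter: int = 200, ridge: float = 0.0):
    """Newton–Raphson logistic regression maximizing the Bernoulli likelihood.

    Iterates until the gradient norm drops below ``tol``. Under (near) perfect
    separation the Hessian degenerates; an L2 penalty of 1e-6 is then applied
    to keep the solution bounded, with a warning.
    """
    n, p = Z.shape
    X = np.column_stack([np.ones(n), Z])
    beta = np.zeros(p + 1)
    lam = ridge
    for attempt in range(2):
        beta = np.zeros(p + 1)
        for _ in range(max_iter):
            mu = expit(X @ beta)
            grad = X.T @ (y - mu) - lam * beta
            if np.linalg.norm(grad) < tol:
                return beta[0], beta[1:]
            W = mu * (1 - mu)
            H = (X.T * W) @ X + (lam + 1e-12) * np.eye(p + 1)
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                break
            # dampen huge Newton steps (separation drives |beta| -> inf)
            norm = np.linalg.norm(step)
            if norm > 50:
                step *= 50 / norm
            beta = beta + step
            if np.abs(beta).max() > 1e3:
                break
        if attempt == 0:
            warnings.warn("logistic fit did not converge; "
                          "applying L2 penalty 1e-6 (possible separation)")
            lam = 1e-6
    return beta[0], beta[1:]


def fit_propensity(covariates: pd.DataFrame, labels) -> PropensityModel:
    """Standardize covariates and fit the logistic propensity model."""
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both case and control labels must be present")
    Z, (mean, sd) = standardize(covariates)
    intercept, coef = fit_logistic(Z.to_numpy(), y)
    return PropensityModel(coefficients=np.asarray(coef), intercept=float(intercept),
                           scaler_mean=mean, scaler_sd=sd,
                           columns=list(covariates.columns))


def match_knn(scores: pd.Series, labels: pd.Series, k: int = 3) -> pd.DataFrame:
    """Greedy 1:k nearest-neighbor matching on propensity, without replacement.

    Cases are processed in descending score order; for each case the k
    available controls with the smallest absolute score difference are taken
    (ties broken by smaller person_id). Returns a DataFrame with columns
    case_id, control_id, rank, case_score, control_score.
    """
    scores = pd.Series(scores)
    labels = pd.Series(labels).reindex(scores.index)
    case_ids = scores.index[labels == 1]
    ctrl_ids = np.asarray(scores.index[labels == 0])
    ctrl_scores = scores.loc[ctrl_ids].to_numpy(float)
    if len(ctrl_ids) == 0:
        warnings.warn("no controls available; empty matching")
        return pd.DataFrame(columns=["case_id", "control_id", "rank",
                                     "case_score", "control_score"])

    # descending case score; ties by smaller person_id
    case_order = sorted(case_ids, key=lambda pid: (-scores.loc[pid], pid))
    available = np.ones(len(ctrl_ids), dtype=bool)
    rows = []
    for cid in case_order:
        if not available.any():
            break
        s = float(scores.loc[cid])
        avail_idx = np.flatnonzero(available)
        diffs = np.abs(ctrl_scores[avail_idx] - s)
        order = np.lexsort((ctrl_ids[avail_idx], diffs))
        take = avail_idx[order[:k]]
        for rank, j in enumerate(take, start=1):
            rows.append({"case_id": cid, "control_id": ctrl_ids[j],
                         "rank": rank, "case_score": s,
                         "control_score": float(ctrl_scores[j])})
            available[j] = False
    return pd.DataFrame(rows)


def smd(x1: np.ndarray, x0: np.ndarray) -> float:
    """Absolute standardized mean difference |m1 - m0| / sqrt((s1^2+s0^2)/2)."""
    m1, m0 = np.mean(x1), np.mean(x0)
    s1 = np.var(x1, ddof=1) if len(x1) > 1 else 0.0
    s0 = np.var(x0, ddof=1) if len(x0) > 1 else 0.0
    denom = np.sqrt((s1 + s0) / 2.0)
    if denom == 0:
        return 0.0
    return float(abs(m1 - m0) / denom)


def balance_report(covariates: pd.DataFrame, labels: pd.Series,
                   matches: pd.DataFrame) -> pd.DataFrame:
    """Covariate balance before and after matching.

    Per covariate: case mean, control mean, raw difference and absolute SMD,
    computed on the full cohort (``before``) and the matched subset
    (``after``).
    """
    labels = pd.Series(labels).reindex(covariates.index)
    rows = []
    matched_cases = matches["case_id"].unique() if len(matches) else []
    matched_ctrls = matches["control_id"].unique() if len(matches) else []
    for col in covariates.columns:
        x = covariates[col]
        for stage, case_idx, ctrl_idx in (
            ("before", covariates.index[labels == 1],
             covariates.index[labels == 0]),
            ("after", matched_cases, matched_ctrls),
        ):
            x1 = x.loc[case_idx].to_numpy(float)
            x0 = x.loc[ctrl_idx].to_numpy(float)
            if len(x1) == 0 or len(x0) == 0:
                warnings.warn(f"empty group for {col} ({stage})")
                continue
            rows.append({
                "covariate": col, "stage": stage,
                "case_mean": float(np.mean(x1)),
                "control_mean": float(np.mean(x0)),
                "difference": float(np.mean(x1) - np.mean(x0)),
                "smd": smd(x1, x0),
            })
    return pd.DataFrame(rows)


class PropensityMatcher(BaseEstimator):
    """Scikit-learn-style propensity matcher.

    ``fit(X, y)`` standardizes the covariates and fits the logistic
    propensity model; ``match()`` then performs greedy 1:k nearest-neighbor
    matching without replacement on the fitted scores.

    Parameters
    ----------
    k : int, default 3
        Target controls per case.
    caliper : float or None
        Optional maximum |score difference| in propensity-SD units; pairs
        beyond the caliper are discarded.

    Attributes
    ----------
    model_ : PropensityModel
    scores_ : pd.Series of propensity scores indexed like X
    matches_ : pd.DataFrame, set by :meth:`match`
    """

    def __init__(self, k: int = 3, caliper: float | None = None):
        self.k = k
        self.caliper = caliper

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        self.model_ = fit_propensity(X, y)
        self.scores_ = pd.Series(self.model_.score(X), index=X.index,
                                 name="propensity")
        self._labels = pd.Series(np.asarray(y, dtype=int), index=X.index)
        self._X = X
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        p = self.model_.score(pd.DataFrame(X))
        return np.column_stack([1 - p, p])

    def match(self) -> pd.DataFrame:
        m = match_knn(self.scores_, self._labels, k=self.k)
        if self.caliper is not None and len(m):
            sd_score = float(self.scores_.std(ddof=0)) or 1.0
            keep = (m["case_score"] - m["control_score"]).abs() \
                <= self.caliper * sd_score
            m = m.loc[keep].reset_index(drop=True)
        self.matches_ = m
        return m

    def balance(self) -> pd.DataFrame:
        return balance_report(self._X, self._labels, self.matches_)
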