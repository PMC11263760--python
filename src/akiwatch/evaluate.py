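"""Discrimination metrics with bootstrap confidence intervals.

AUROC is computed by the Mann–Whitney formulation (fraction of case/control
score pairs ranked correctly, ties counted one half), which equals the
trapezoidal ROC area. AUPRC uses the step-wise average-precision rule.
Thresholded metrics follow the usual confusion-matrix definitions, and the
AUROC confidence interval is a seeded stratified percentile bootstrap.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score


def _check(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    return scores, labels


def auroc(scores, labels) -> float:
    """Mann–Whitney AUROC: P(score_case > score_control) + 0.5 P(tie)."""
    scores, labels = _check(scores, labels)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC requires both classes")
    ranks = rankdata(scores)  # midranks handle ties
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve (step rule)."""
    scores, labels = _check(scores, labels)
    if (labels == 1).sum() == 0:
        raise ValueError("AUPRC requires at least one positive")
    return float(average_precision_score(labels, scores))


def thresholded_metrics(scores, labels, threshold: float = 0.5
                        ) -> tuple[float, float, float]:
    """(accuracy, precision, F1) at ``score >= threshold``."""
    scores, labels = _check(scores, labels)
    pred = scores >= threshold
    y = labels == 1
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    fn = int((~pred & y).sum())
    tn = int((~pred & ~y).sum())
    accuracy = (tp + tn) / len(y)
    if tp + fp == 0:
        warnings.warn("no predicted positives; precision reported as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return float(accuracy), float(precision), float(f1)


def auroc_ci(scores, labels, n_boot: int = 1000, seed: int = 0,
             level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUROC over stratified resamples."""
    scores, labels = _check(scores, labels)
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError("bootstrap CI requires both classes")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        pi = rng.choice(pos_idx, size=len(pos_idx), replace=True)
        ni = rng.choice(neg_idx, size=len(neg_idx), replace=True)
        idx = np.concatenate([pi, ni])
        stats[b] = auroc(scores[idx], labels[idx])
    lo = (1 - level) / 2
    return (float(np.quantile(stats, lo)),
            float(np.quantile(stats, 1 - lo)))


@dataclass
class MetricsReport:
    """All headline metrics for one trained model on one evaluation split."""

    auroc: float
    auprc: float
    accuracy: float
    precision: float
    f1: float
    auroc_ci: tuple[float, float]
    n: int
    n_pos: int
    threshold: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def compute_metrics(scores, labels, threshold: float = 0.5,
                    n_boot: int = 1000, seed: int = 0) -> MetricsReport:
    scores, labels = _check(scores, labels)
    acc, prec, f1 = thresholded_metrics(scores, labels, threshold)
    return MetricsReport(
        auroc=auroc(scores, labels),
        auprc=auprc(scores, labels),
        accuracy=acc, precision=prec, f1=f1,
        auroc_ci=auroc_ci(scores, labels, n_boot=n_boot, seed=seed),
        n=int(len(labels)), n_pos=int((labels == 1).sum()),
        threshold=threshold)
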