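"""Evaluation of scored cohorts: ROC threshold, confusion metrics, survival.

The classification threshold is the Youden-optimal cutoff (maximizing
J = TPR + TNR - 1) learned on training scores, with "predicted responder"
meaning score strictly below the threshold — the score is oriented so lower
values favor response. Survival comparison between high- and low-score
groups uses Kaplan-Meier curves and the two-group log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .screen import pair_auc


@dataclass
class Metrics:
    auc: float
    threshold: float
    f1: float
    tpr: float
    tnr: float
    fpr: float
    fnr: float
    tp: int
    fp: int
    tn: int
    fn: int

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "threshold": self.threshold,
            "f1": self.f1,
            "tpr": self.tpr,
            "tnr": self.tnr,
            "fpr": self.fpr,
            "fnr": self.fnr,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
        }


@dataclass
class SurvivalComparison:
    n_group0: int
    n_group1: int
    chi_square: float
    p_value: float
    km_curves: dict[int, pd.DataFrame]  # group -> columns (time, survival)


def youden_threshold(score: np.ndarray, y: np.ndarray) -> float:
    """Cutoff maximizing J = TPR + TNR - 1 with responder = score < threshold.

    Candidates are midpoints between consecutive sorted unique scores plus
    -inf/+inf sentinels; ties break toward the smallest candidate. When all
    scores are equal J = 0 everywhere and the -inf sentinel is returned
    (every sample predicted non-responder).
    """
    score = np.asarray(score, dtype=float)
    y = np.asarray(y, dtype=int)
    if score.shape != y.shape:
        raise ValueError("score and y must have equal lengths")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("response has a single class")
    uniq = np.unique(score)
    candidates = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]))
    best_t, best_j = -np.inf, -np.inf
    for t in candidates:
        pred = score < t
        tpr = float(np.sum(pred & (y == 1))) / n_pos
        tnr = float(np.sum(~pred & (y == 0))) / n_neg
        j = tpr + tnr - 1.0
        if j > best_j + 1e-12:
            best_t, best_j = float(t), j
    return best_t


def confusion_metrics(predicted: np.ndarray, y: np.ndarray, threshold: float = np.nan,
                      auc: float = np.nan) -> Metrics:
    """All rates and F1 from the 2x2 table; positive class = responder."""
    predicted = np.asarray(predicted, dtype=int)
    y = np.asarray(y, dtype=int)
    if predicted.shape != y.shape:
        raise ValueError("predicted and y must have equal lengths")
    tp = int(np.sum((predicted == 1) & (y == 1)))
    fp = int(np.sum((predicted == 1) & (y == 0)))
    tn = int(np.sum((predicted == 0) & (y == 0)))
    fn = int(np.sum((predicted == 0) & (y == 1)))
    tpr = tp / (tp + fn) if tp + fn else np.nan
    tnr = tn / (tn + fp) if tn + fp else np.nan
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return Metrics(
        auc=float(auc),
        threshold=float(threshold),
        f1=float(f1),
        tpr=float(tpr),
        tnr=float(tnr),
        fpr=float(1 - tnr) if np.isfinite(tnr) else np.nan,
        fnr=float(1 - tpr) if np.isfinite(tpr) else np.nan,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


def evaluate_scores(score: np.ndarray, y: np.ndarray, threshold: float) -> Metrics:
    """AUC (responders ranked by low score) + thresholded confusion metrics."""
    score = np.asarray(score, dtype=float)
    y = np.asarray(y, dtype=int)
    auc = pair_auc(-score, y)  # lower score = responder, so rank by -score
    predicted = (score < threshold).astype(int)
    m = confusion_metrics(predicted, y, threshold=threshold, auc=auc)
    return m


def km_logrank(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> SurvivalComparison:
    """Two-group Kaplan-Meier + log-rank comparison.

    ``group`` is binary (e.g. 1 = high-score). Raises when either group is
    empty or no events were observed at all (the statistic is undefined).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=int)
    if not (time.shape == event.shape == group.shape):
        raise ValueError("time, event and group must have equal lengths")
    if np.any(time < 0):
        raise ValueError("times must be non-negative")
    n1 = int(np.sum(group == 1))
    n0 = int(np.sum(group == 0))
    if n0 == 0 or n1 == 0:
        raise ValueError("both groups must be non-empty")
    if event.sum() == 0:
        raise ValueError("no events observed; log-rank statistic undefined")
    res = logrank_test(
        time[group == 0], time[group == 1], event[group == 0], event[group == 1]
    )
    curves = {}
    for g in (0, 1):
        kmf = KaplanMeierFitter()
        kmf.fit(time[group == g], event[group == g])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[g] = sf
    return SurvivalComparison(
        n_group0=n0,
        n_group1=n1,
        chi_square=float(res.test_statistic),
        p_value=float(res.p_value),
        km_curves=curves,
    )
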