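"""Evaluation statistics: confusion-derived agreement rates, classification
metrics, association analyses, effect sizes and rerun repeatability.

Conventions
-----------
* ``reference`` is always the ground truth (the visual tau rating); the
  comparator may be a meta-ROI status vector or model predictions.
* Mismatch rates are 1−TPR (tau-positive mismatch) and 1−TNR (tau-negative
  mismatch); percentage report columns use round-half-even to 2 decimals.
* The independent-samples t-test defaults to the classical pooled-variance
  (Student) form; Welch is available behind ``equal_var=False``.
* Repeatability across model reruns is ICC(2,1): two-way random effects,
  absolute agreement, single measure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import (
    balanced_accuracy_score,
    f1_score,
    matthews_corrcoef,
    precision_score,
    recall_score,
    roc_auc_score,
)

from .errors import ConfigError

log = logging.getLogger(__name__)


@dataclass
class MetricsReport:
    tp: int
    tn: int
    fp: int
    fn: int
    tpr: Optional[float]
    tnr: Optional[float]
    pos_mismatch: Optional[float]  # 1 − TPR
    neg_mismatch: Optional[float]  # 1 − TNR
    balanced_accuracy: Optional[float] = None
    mcc: Optional[float] = None
    precision: Optional[float] = None
    recall: Optional[float] = None
    f1: Optional[float] = None
    roc_auc: Optional[float] = None

    def pos_mismatch_pct(self) -> Optional[float]:
        return None if self.pos_mismatch is None else round(100 * self.pos_mismatch, 2)

    def neg_mismatch_pct(self) -> Optional[float]:
        return None if self.neg_mismatch is None else round(100 * self.neg_mismatch, 2)


@dataclass
class AssociationReport:
    spearman_rho: Optional[float] = None
    ols_slope: Optional[float] = None
    ols_intercept: Optional[float] = None
    cohens_d: Optional[float] = None
    t_statistic: Optional[float] = None
    p_value: Optional[float] = None
    p_adjusted: Optional[float] = None
    n_pairs: int = 0


def _as_binary(values: Sequence) -> np.ndarray:
    arr = np.asarray(values).astype(int)
    if arr.ndim != 1:
        raise ConfigError("label vectors must be one-dimensional")
    if not np.isin(arr, (0, 1)).all():
        raise ConfigError("labels must be binary (0/1)")
    return arr


def confusion_rates(reference: Sequence, comparator: Sequence) -> MetricsReport:
    """2×2 agreement of a comparator against the reference rating.

    TPR = TP/(TP+FN), TNR = TN/(TN+FP); the mismatch rates are their
    complements.  A reference with no positives (or no negatives) leaves
    the corresponding rate undefined (None, with a warning).
    """
    ref = _as_binary(reference)
    cmp_ = _as_binary(comparator)
    if ref.shape != cmp_.shape:
        raise ConfigError("reference and comparator must have equal length")
    tp = int(np.sum((ref == 1) & (cmp_ == 1)))
    tn = int(np.sum((ref == 0) & (cmp_ == 0)))
    fp = int(np.sum((ref == 0) & (cmp_ == 1)))
    fn = int(np.sum((ref == 1) & (cmp_ == 0)))
    tpr = tnr = None
    if tp + fn > 0:
        tpr = tp / (tp + fn)
    else:
        log.warning("confusion_rates: no reference positives; TPR undefined")
    if tn + fp > 0:
        tnr = tn / (tn + fp)
    else:
        log.warning("confusion_rates: no reference negatives; TNR undefined")
    return MetricsReport(
        tp=tp, tn=tn, fp=fp, fn=fn, tpr=tpr, tnr=tnr,
        pos_mismatch=None if tpr is None else 1 - tpr,
        neg_mismatch=None if tnr is None else 1 - tnr,
    )


def classification_metrics(
    reference: Sequence,
    predicted: Sequence,
    probabilities: Optional[Sequence[float]] = None,
) -> MetricsReport:
    """Confusion rates plus balanced accuracy, MCC, precision/recall/F1 and
    ROC AUC (rank-based with midrank tie handling, i.e. the trapezoidal
    curve over all thresholds)."""
    report = confusion_rates(reference, predicted)
    ref = _as_binary(reference)
    pred = _as_binary(predicted)
    report.balanced_accuracy = float(balanced_accuracy_score(ref, pred))
    report.mcc = float(matthews_corrcoef(ref, pred))
    report.precision = float(precision_score(ref, pred, zero_division=0))
    report.recall = float(recall_score(ref, pred, zero_division=0))
    report.f1 = float(f1_score(ref, pred, zero_division=0))
    if probabilities is not None:
        proba = np.asarray(probabilities, dtype=float)
        if np.ptp(proba) == 0:
            log.warning("classification_metrics: constant probabilities; AUC = 0.5")
            report.roc_auc = 0.5
        else:
            report.roc_auc = float(roc_auc_score(ref, proba))
    return report


def spearman_ols(x: Sequence[float], y: Sequence[float]) -> AssociationReport:
    """Midrank Spearman rho plus an OLS fit of y on x, complete pairs only."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ConfigError(f"spearman_ols needs >= 3 complete pairs, got {n}")
    report = AssociationReport(n_pairs=n)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("spearman_ols: constant input; rho undefined")
        return report
    rho, _ = sps.spearmanr(x, y)
    fit = sps.linregress(x, y)
    report.spearman_rho = float(rho)
    report.ols_slope = float(fit.slope)
    report.ols_intercept = float(fit.intercept)
    return report


def cohens_d_ttest(
    group_a: Sequence[float],
    group_b: Sequence[float],
    n_comparisons: int = 1,
    equal_var: bool = True,
) -> AssociationReport:
    """Cohen's d (df-weighted pooled SD) with a two-tailed independent-samples
    t-test and Bonferroni adjustment (capped at 1)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ConfigError("both groups need n >= 2")
    if n_comparisons < 1:
        raise ConfigError("n_comparisons must be >= 1")
    report = AssociationReport(n_pairs=a.size + b.size)
    pooled_var = (
        (a.size - 1) * np.var(a, ddof=1) + (b.size - 1) * np.var(b, ddof=1)
    ) / (a.size + b.size - 2)
    if pooled_var == 0:
        log.warning("cohens_d_ttest: zero pooled variance; d undefined")
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
        report.p_value = float(p) if math.isfinite(p) else 1.0
        report.p_adjusted = min(1.0, report.p_value * n_comparisons)
        return report
    report.cohens_d = float((a.mean() - b.mean()) / math.sqrt(pooled_var))
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    report.t_statistic = float(t)
    report.p_value = float(p)
    report.p_adjusted = min(1.0, float(p) * n_comparisons)
    return report


def icc_across_runs(score_matrix: np.ndarray | pd.DataFrame) -> float:
    """ICC(2,1) of a participants × runs score matrix.

    Two-way random effects, absolute agreement, single measure, from the
    mean-squares decomposition (computed through pingouin).  Returns NaN for
    a constant matrix (agreement undefined).
    """
    M = np.asarray(score_matrix, dtype=float)
    if M.ndim != 2 or M.shape[1] < 2 or M.shape[0] < 3:
        raise ConfigError("need a 2-D matrix with >= 3 participants and >= 2 runs")
    if not np.all(np.isfinite(M)):
        raise ConfigError("score matrix must be finite")
    if np.ptp(M) == 0:
        log.warning("icc_across_runs: constant scores; ICC undefined")
        return float("nan")
    import pingouin as pg

    n, k = M.shape
    long = pd.DataFrame(
        {
            "targets": np.repeat(np.arange(n), k),
            "raters": np.tile(np.arange(k), n),
            "scores": M.ravel(),
        }
    )
    import warnings

    with warnings.catch_warnings():
        # perfect agreement makes pingouin's internal F-ratios divide by
        # zero; the returned ICC is still exact
        warnings.simplefilter("ignore", RuntimeWarning)
        table = pg.intraclass_corr(
            data=long, targets="targets", raters="raters", ratings="scores"
        )
    # two-way random, absolute agreement, single measure: labelled ICC(A,1)
    # in pingouin >= 0.6, ICC2 in earlier releases
    sel = table["Type"].isin(("ICC(A,1)", "ICC2"))
    value = table.loc[sel, "ICC"].iloc[0]
    return float(value)
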