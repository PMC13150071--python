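"""Metric engine: ROC/AUC, confusion-matrix metrics, average precision,
quantile-bin calibration, bootstrap AUC-difference CI, and feature-clinical
Spearman correlation.

AUC is computed through the Mann-Whitney identity (ties count 0.5), which
equals the trapezoidal area under the empirical ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .containers import binary_labels
from .differential import bh_fdr

CLINICAL_VARIABLES = ("HB", "CRP", "ESR", "IL6", "DAS28")


@dataclass
class MetricArray:
    """Pooled metric array for one evaluated classifier."""

    auc: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    ap: float
    calibration: pd.DataFrame
    bootstrap_ci: Optional[tuple] = None
    flags: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in ("auc", "accuracy", "precision", "recall", "f1", "ap")}
        if self.bootstrap_ci is not None:
            d["ci_low"], d["ci_high"] = self.bootstrap_ci
        return d


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if set(np.unique(y)) - {0, 1}:
        y = binary_labels(y)
    y = y.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return y


def roc_auc(scores, labels) -> float:
    """AUC via the Mann-Whitney U identity; tied scores count 1/2."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    ranks = stats.rankdata(s)  # average ranks handle ties as 0.5 wins
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def classification_metrics(pred_labels, true_labels) -> dict:
    """Accuracy/precision/recall/F1 of the positive class, with zero-
    denominator cases returning 0 and a flag."""
    yp = np.asarray(pred_labels).astype(int)
    yt = np.asarray(true_labels).astype(int)
    if yp.shape != yt.shape:
        raise ValueError("prediction/label length mismatch")
    tp = int(((yp == 1) & (yt == 1)).sum())
    fp = int(((yp == 1) & (yt == 0)).sum())
    fn = int(((yp == 0) & (yt == 1)).sum())
    tn = int(((yp == 0) & (yt == 0)).sum())
    flags = {}
    if tp + fp == 0:
        precision = 0.0
        flags["no_predicted_positives"] = True
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall = 0.0
        flags["no_true_positives"] = True
    else:
        recall = tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    accuracy = (tp + tn) / yt.size
    return {"accuracy": accuracy, "precision": precision, "recall": recall,
            "f1": f1, "flags": flags}


def average_precision(scores, labels) -> float:
    """Step-wise AP: sum over thresholds of (recall increment) x precision."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="mergesort")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # threshold boundaries: last index of each distinct score
    distinct = np.nonzero(np.diff(s_sorted))[0]
    idx = np.r_[distinct, s_sorted.size - 1]
    precision = tp[idx] / (tp[idx] + fp[idx])
    recall = tp[idx] / y.sum()
    recall_prev = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - recall_prev) * precision))


def calibration_bins(probs, labels, n_bins: int = 5) -> pd.DataFrame:
    """Quantile-bin calibration table (equal-count bins, ties kept together).

    Returns one row per effective bin: mean predicted probability, observed
    positive frequency, and count. Bin counts partition the sample.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    if p.size != y.size:
        raise ValueError("probs/labels length mismatch")
    if p.size < n_bins:
        raise ValueError("fewer samples than bins")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    bins = pd.qcut(p, q=n_bins, duplicates="drop")
    df = pd.DataFrame({"bin": bins, "p": p, "y": y})
    g = df.groupby("bin", observed=True)
    out = pd.DataFrame({
        "mean_predicted": g["p"].mean(),
        "observed_freq": g["y"].mean(),
        "n": g.size(),
    }).reset_index(drop=True)
    if out.empty:  # constant probabilities: a single effective bin
        out = pd.DataFrame({"mean_predicted": [p.mean()],
                            "observed_freq": [y.mean()], "n": [p.size]})
    out.insert(0, "bin", np.arange(len(out)))
    return out


def bootstrap_auc_diff_ci(scores_a, labels_a, scores_b, labels_b,
                          n_boot: int = 2000, conf: float = 0.95,
                          seed: int = 0) -> tuple:
    """Percentile bootstrap CI for AUC_a - AUC_b, resampling each set
    independently with class stratification."""
    rng = np.random.default_rng(seed)
    ya, yb = _check_binary(labels_a), _check_binary(labels_b)
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)

    def resample_auc(s, y):
        pos = np.nonzero(y == 1)[0]
        neg = np.nonzero(y == 0)[0]
        ip = rng.choice(pos, size=pos.size, replace=True)
        ineg = rng.choice(neg, size=neg.size, replace=True)
        idx = np.r_[ip, ineg]
        return roc_auc(s[idx], y[idx])

    diffs = np.empty(n_boot)
    for b in range(n_boot):
        diffs[b] = resample_auc(sa, ya) - resample_auc(sb, yb)
    lo = (1 - conf) / 2
    return (float(np.quantile(diffs, lo)), float(np.quantile(diffs, 1 - lo)))


def metric_array(scores, labels, threshold: float = 0.5, n_bins: int = 5) -> MetricArray:
    """Full metric array for probability scores at the default 0.5 cut."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    cm = classification_metrics((s >= threshold).astype(int), y)
    cal = calibration_bins(np.clip(s, 0, 1), y, n_bins=n_bins) if s.size >= n_bins else pd.DataFrame()
    return MetricArray(
        auc=roc_auc(s, y),
        accuracy=cm["accuracy"], precision=cm["precision"],
        recall=cm["recall"], f1=cm["f1"],
        ap=average_precision(s, y),
        calibration=cal,
        flags=cm["flags"],
    )


def feature_clinical_correlation(m, clinical: pd.DataFrame,
                                 variables=CLINICAL_VARIABLES) -> tuple:
    """Spearman correlation of every feature against each clinical variable.

    Returns (rho matrix, raw p matrix, BH-FDR matrix), all features x
    variables, computed on the shared samples.
    """
    feat = m.values if hasattr(m, "values") and not isinstance(m, pd.DataFrame) else m
    shared = feat.index.intersection(clinical.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    F = feat.loc[shared]
    C = clinical.loc[shared, list(variables)]
    rho = pd.DataFrame(index=F.columns, columns=variables, dtype=float)
    pmat = pd.DataFrame(index=F.columns, columns=variables, dtype=float)
    for v in variables:
        r, p = stats.spearmanr(F.to_numpy(), C[v].to_numpy())
        if F.shape[1] == 1:
            rho[v], pmat[v] = r, p
        else:
            rho[v] = np.asarray(r)[:-1, -1]
            pmat[v] = np.asarray(p)[:-1, -1]
    flat = bh_fdr(pmat.to_numpy().ravel())
    fdr = pd.DataFrame(flat.reshape(pmat.shape), index=pmat.index, columns=pmat.columns)
    return rho, pmat, fdr
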