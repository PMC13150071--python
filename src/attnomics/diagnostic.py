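"""Small-panel diagnostic classifiers with a 7:3 stratified split.

The panel (typically 5 metabolites or 5 genes) is fitted with an
L2-regularized logistic regression; standardization parameters come from the
training partition only, mirroring the leakage-confinement principle of the
cross-validation stage. Both partitions are scored with the full metric array
(AUC, accuracy, precision, recall, F1, AP, 5-quantile-bin calibration).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .containers import OmicsMatrix, binary_labels
from .evaluate import MetricArray, metric_array


def stratified_split(sample_ids, labels, train_frac: float = 0.7, seed: int = 0):
    """Disjoint, exhaustive, per-class randomized split; class counts in the
    training set are round(train_frac * n_class)."""
    ids = np.asarray(sample_ids)
    y = binary_labels(labels)
    if len(ids) != len(y):
        raise ValueError("sample_ids/labels length mismatch")
    rng = np.random.default_rng(seed)
    train_idx = []
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        if len(idx) < 2:
            raise ValueError("each class needs at least 2 samples")
        n_tr = int(round(train_frac * len(idx)))
        n_tr = min(max(n_tr, 1), len(idx) - 1)
        train_idx.extend(rng.choice(idx, size=n_tr, replace=False))
    train_idx = np.sort(np.asarray(train_idx))
    test_idx = np.setdiff1d(np.arange(len(ids)), train_idx)
    return list(ids[train_idx]), list(ids[test_idx])


@dataclass
class PanelModel:
    panel: list
    coef: np.ndarray
    intercept: float
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    train_ids: list
    test_ids: list
    seed: int

    def predict_proba(self, m: OmicsMatrix, sample_ids=None) -> pd.Series:
        missing = [f for f in self.panel if f not in m.values.columns]
        if missing:
            raise ValueError(f"matrix lacks panel features {missing}")
        vals = m.values.loc[sample_ids if sample_ids is not None else m.values.index,
                            self.panel]
        Z = (vals.to_numpy(dtype=float) - self.scaler_mean) / self.scaler_sd
        logit = Z @ self.coef + self.intercept
        return pd.Series(1.0 / (1.0 + np.exp(-logit)), index=vals.index)

    def to_json_dict(self) -> dict:
        return {
            "panel": list(self.panel),
            "coef": [float(c) for c in self.coef],
            "intercept": float(self.intercept),
            "scaler_mean": [float(v) for v in self.scaler_mean],
            "scaler_sd": [float(v) for v in self.scaler_sd],
            "train_ids": list(self.train_ids),
            "test_ids": list(self.test_ids),
            "seed": self.seed,
        }


def fit_panel(m: OmicsMatrix, panel, labels=None, train_ids=None,
              test_ids=None, train_frac: float = 0.7, seed: int = 0,
              C: float = 1.0) -> PanelModel:
    """L2 logistic regression on the panel features.

    If no split is supplied, a seeded stratified 7:3 split is drawn first.
    The L2 penalty keeps perfectly separable panels finite.
    """
    from sklearn.linear_model import LogisticRegression

    groups = m.group_labels if labels is None else pd.Series(
        np.asarray(labels), index=m.values.index)
    if groups is None:
        raise ValueError("labels required")
    missing = [f for f in panel if f not in m.values.columns]
    if missing:
        raise ValueError(f"matrix lacks panel features {missing}")
    if train_ids is None:
        train_ids, test_ids = stratified_split(m.values.index, groups,
                                               train_frac=train_frac, seed=seed)
    y = pd.Series(binary_labels(groups), index=m.values.index)
    Xtr = m.values.loc[train_ids, list(panel)].to_numpy(dtype=float)
    mean = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=2000, random_state=seed)
    clf.fit((Xtr - mean) / sd, y.loc[train_ids].to_numpy())
    return PanelModel(
        panel=list(panel), coef=clf.coef_[0].copy(), intercept=float(clf.intercept_[0]),
        scaler_mean=mean, scaler_sd=sd,
        train_ids=list(train_ids), test_ids=list(test_ids or []), seed=seed,
    )


def evaluate_panel(model: PanelModel, m: OmicsMatrix, labels=None) -> tuple:
    """Metric arrays on the training and test partitions."""
    groups = m.group_labels if labels is None else pd.Series(
        np.asarray(labels), index=m.values.index)
    y = pd.Series(binary_labels(groups), index=m.values.index)
    out = []
    for ids in (model.train_ids, model.test_ids):
        if not ids:
            out.append(None)
            continue
        prob = model.predict_proba(m, ids)
        out.append(metric_array(prob.to_numpy(), y.loc[ids].to_numpy()))
    return tuple(out)


def build_diagnostic(m: OmicsMatrix, panel, labels=None, train_frac: float = 0.7,
                     seed: int = 0) -> tuple:
    """Convenience wrapper: split, fit, evaluate. Returns
    (PanelModel, train MetricArray, test MetricArray)."""
    model = fit_panel(m, panel, labels=labels, train_frac=train_frac, seed=seed)
    train_ma, test_ma = evaluate_panel(model, m, labels=labels)
    return model, train_ma, test_ma
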