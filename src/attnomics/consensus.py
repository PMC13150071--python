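"""Five-model algorithmic consensus filter.

Each of KNN, SVM (RBF), random forest, RFE-RF, and XGBoost ranks the candidate
features (the dual-filter output); the consensus panel is the intersection of
the per-model top-k lists, ordered by mean rank. KNN and SVM have no native
importance, so a seeded permutation importance (20 repeats, AUC drop) is used.

Fixed hyperparameters (for reproducibility): KNN k=5; SVM RBF with default
regularization; RF 500 trees; XGBoost 200 rounds at depth 3.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import OmicsMatrix, binary_labels
from . import evaluate as ev

MODEL_NAMES = ("KNN", "SVM", "RF", "RFE-RF", "XGBoost")
METRIC_COLUMNS = ("auc", "accuracy", "precision", "recall", "f1")


def _make_model(model_name: str, seed: int):
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC
    from xgboost import XGBClassifier

    if model_name == "KNN":
        return KNeighborsClassifier(n_neighbors=5)
    if model_name == "SVM":
        return SVC(kernel="rbf", random_state=seed)
    if model_name == "RF":
        return RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1)
    if model_name == "RFE-RF":
        return RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1)
    if model_name == "XGBoost":
        return XGBClassifier(n_estimators=200, max_depth=3, random_state=seed,
                             n_jobs=1, eval_metric="logloss", verbosity=0)
    raise ValueError(f"unknown model {model_name!r}")


def _scores(model, X) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - X.mean(axis=0)) / sd


def _importance(model_name: str, model, X, y, seed: int) -> np.ndarray:
    from sklearn.feature_selection import RFE
    from sklearn.inspection import permutation_importance

    if model_name in ("RF", "XGBoost"):
        model.fit(X, y)
        return np.asarray(model.feature_importances_, dtype=float)
    if model_name == "RFE-RF":
        rfe = RFE(model, n_features_to_select=1, step=1)
        rfe.fit(X, y)
        return -np.asarray(rfe.ranking_, dtype=float)  # rank 1 = kept longest
    # KNN / SVM: permutation importance, AUC drop
    model.fit(X, y)
    perm = permutation_importance(model, X, y, scoring="roc_auc",
                                  n_repeats=20, random_state=seed, n_jobs=1)
    return np.asarray(perm.importances_mean, dtype=float)


def rank_features(m: OmicsMatrix, labels=None, model_name: str = "RF",
                  k: int = 10, seed: int = 0) -> list:
    """Top-k candidate features by the model's importance; deterministic,
    with ties broken lexicographically by feature id."""
    y = m.binary_labels() if labels is None else binary_labels(labels)
    if min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 samples per class")
    X = _standardize(m.values.to_numpy(dtype=float))
    feats = list(m.values.columns)
    model = _make_model(model_name, seed)
    imp = _importance(model_name, model, X, y, seed)
    order = sorted(range(len(feats)), key=lambda j: (-imp[j], str(feats[j])))
    return [feats[j] for j in order[:min(k, len(feats))]]


def consensus_intersection(lists) -> list:
    """Features present in all five top-k lists, ordered by mean rank."""
    lists = list(lists)
    if len(lists) < 5:
        raise ValueError("consensus requires 5 ranked lists")
    common = set(lists[0])
    for lst in lists[1:]:
        common &= set(lst)
    mean_rank = {f: np.mean([lst.index(f) for lst in lists]) for f in common}
    return sorted(common, key=lambda f: (mean_rank[f], str(f)))


def consensus_panel(m: OmicsMatrix, labels=None, k: int = 10, seed: int = 0) -> dict:
    """Per-model top-k rankings plus their intersection."""
    y = m.binary_labels() if labels is None else binary_labels(labels)
    rankings = {name: rank_features(m, y, name, k=k, seed=seed) for name in MODEL_NAMES}
    return {
        "rankings": rankings,
        "k": k,
        "intersection": consensus_intersection(list(rankings.values())),
    }


def benchmark_models(m: OmicsMatrix, labels=None, n_folds: int = 5,
                     seed: int = 0) -> pd.DataFrame:
    """Stratified-CV metric table: one row per model, columns = AUC,
    accuracy, precision, recall, F1 (fold means; fold SDs as a nested dict
    in ``.attrs['sd']``)."""
    from sklearn.model_selection import StratifiedKFold

    y = m.binary_labels() if labels is None else binary_labels(labels)
    if min(np.bincount(y)) < n_folds:
        raise ValueError("need at least n_folds samples per class")
    X = m.values.to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    per_model = {name: [] for name in MODEL_NAMES}
    for tr, te in skf.split(X, y):
        mean = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        Xtr, Xte = (X[tr] - mean) / sd, (X[te] - mean) / sd
        for name in MODEL_NAMES:
            model = _make_model(name, seed)
            model.fit(Xtr, y[tr])
            s = _scores(model, Xte)
            pred = model.predict(Xte)
            cm = ev.classification_metrics(pred, y[te])
            per_model[name].append({
                "auc": ev.roc_auc(s, y[te]),
                "accuracy": cm["accuracy"], "precision": cm["precision"],
                "recall": cm["recall"], "f1": cm["f1"],
            })
    means = pd.DataFrame(
        {name: pd.DataFrame(rows).mean() for name, rows in per_model.items()}
    ).T[list(METRIC_COLUMNS)]
    sds = pd.DataFrame(
        {name: pd.DataFrame(rows).std(ddof=1) for name, rows in per_model.items()}
    ).T[list(METRIC_COLUMNS)]
    means.attrs["sd"] = sds.to_dict()  # plain dict: keeps DataFrame.attrs hashable
    return means
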