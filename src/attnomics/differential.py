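"""Classical differential layers for the two-group (RA vs RA_ane) design.

* Metabolome: OPLS-DA VIP score (orthogonal-signal-corrected PLS with one
  predictive component) combined with a pooled-variance Student's t test;
  differential rule VIP > 1.0 AND raw P < 0.05 (both strict).
* Transcriptome: per-gene negative-binomial Wald test on median-of-ratios
  normalized counts; rule FDR < 0.01 AND |fold change| > 2.
* Proteome-style tables: symmetric fold-change filter |FC| >= 1.2 AND
  t-test P < 0.05 (inclusive >= on the fold change, as printed).

Fold changes are group2/group1 ratios of linear-scale means, with |FC|
defined symmetrically as max(FC, 1/FC). FDR is Benjamini-Hochberg step-up.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import OmicsMatrix, binary_labels

RESULT_COLUMNS = [
    "feature_id", "mean_g1", "mean_g2", "fc", "log2_fc",
    "stat", "p", "fdr", "vip", "significant",
]


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be 1-dimensional")
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# ---------------------------------------------------------------------------
# PLS-DA / OPLS-DA VIP
# ---------------------------------------------------------------------------

def plsda_vip(m: OmicsMatrix, labels=None, n_components: int = 2) -> pd.Series:
    """VIP scores from an orthogonal-signal-corrected PLS-DA model.

    The model removes ``n_components - 1`` y-orthogonal components (NIPALS
    OPLS filtering) and fits a single predictive PLS component on the
    deflated matrix. The VIP of feature j is

        VIP_j = sqrt(p * sum_a w_ja^2 SSY_a / sum_a SSY_a)

    over predictive components a, which with a single component reduces to
    sqrt(p) * |w_j| for the unit-norm weight vector w; hence mean(VIP^2) = 1
    identically. Constant feature columns carry no weight information and are
    dropped with a warning.
    """
    if labels is None:
        y01 = m.binary_labels()
    else:
        y01 = binary_labels(labels)
    if len(np.unique(y01)) < 2:
        raise ValueError("single-class labels")
    if min(np.bincount(y01)) < 3:
        raise ValueError("need at least 3 samples per group")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")

    X = m.values.to_numpy(dtype=float)
    cols = np.asarray(m.values.columns)
    sd = X.std(axis=0, ddof=1)
    const = sd == 0
    if const.any():
        warnings.warn(f"dropping {const.sum()} constant feature column(s) from VIP")
        X = X[:, ~const]
        cols = cols[~const]
    if X.shape[1] == 0:
        raise ValueError("no non-constant features")

    X = (X - X.mean(axis=0)) / X[:, :].std(axis=0, ddof=1)
    y = y01.astype(float)
    y = y - y.mean()

    # OPLS filtering: remove (n_components - 1) components orthogonal to y.
    for _ in range(n_components - 1):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w = w / nw
        t = X @ w
        p_load = X.T @ t / (t @ t)
        w_orth = p_load - (w @ p_load) * w
        n_orth = np.linalg.norm(w_orth)
        if n_orth < 1e-10:
            break
        w_orth = w_orth / n_orth
        t_orth = X @ w_orth
        p_orth = X.T @ t_orth / (t_orth @ t_orth)
        X = X - np.outer(t_orth, p_orth)

    # One predictive PLS component on the deflated matrix.
    w = X.T @ y
    nw = np.linalg.norm(w)
    if nw < 1e-12:
        raise ValueError("labels are orthogonal to every feature; VIP undefined")
    w = w / nw

    p_feat = X.shape[1]
    vip = np.sqrt(p_feat) * np.abs(w)
    return pd.Series(vip, index=cols, name="vip")


# ---------------------------------------------------------------------------
# Student's t test
# ---------------------------------------------------------------------------

def student_ttest(m: OmicsMatrix, labels=None) -> pd.DataFrame:
    """Pooled-variance two-sided t test per feature.

    Features with zero pooled variance get stat 0, p 1, and a ``degenerate``
    flag instead of NaN.
    """
    y = m.binary_labels() if labels is None else binary_labels(labels)
    if min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 samples per group")
    X = m.values.to_numpy(dtype=float)
    x1, x2 = X[y == 0], X[y == 1]
    n1, n2 = len(x1), len(x2)
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    v1 = x1.var(axis=0, ddof=1)
    v2 = x2.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    degenerate = se == 0
    stat = np.zeros(X.shape[1])
    np.divide(m2 - m1, se, out=stat, where=~degenerate)
    df = n1 + n2 - 2
    p = 2 * stats.t.sf(np.abs(stat), df)
    p[degenerate] = 1.0
    return pd.DataFrame(
        {"stat": stat, "p": p, "degenerate": degenerate},
        index=m.values.columns,
    )


def select_differential_metabolites(res: pd.DataFrame, vip_min: float = 1.0,
                                    p_max: float = 0.05) -> set:
    """Features with VIP strictly > ``vip_min`` AND p strictly < ``p_max``."""
    if "vip" not in res or "p" not in res:
        raise ValueError("result table must carry 'vip' and 'p' columns")
    if res["vip"].isna().any() or res["p"].isna().any():
        raise ValueError("vip and p must be present for all features")
    mask = (res["vip"] > vip_min) & (res["p"] < p_max)
    return set(res.index[mask])


def metabolome_differential(m: OmicsMatrix, labels=None, n_components: int = 2,
                            vip_min: float = 1.0, p_max: float = 0.05) -> pd.DataFrame:
    """Combined VIP + t-test table with the metabolome significance rule."""
    y = m.binary_labels() if labels is None else binary_labels(labels)
    vip = plsda_vip(m, y, n_components=n_components)
    tt = student_ttest(m, y)
    X = m.values
    m1 = X[y == 0].mean(axis=0)
    m2 = X[y == 1].mean(axis=0)
    # log10-scale data: express fold change on the linear scale
    lin1, lin2 = 10.0 ** m1, 10.0 ** m2
    fc = lin2 / lin1
    out = pd.DataFrame({
        "feature_id": X.columns,
        "mean_g1": m1.values,
        "mean_g2": m2.values,
        "fc": fc.values,
        "log2_fc": np.log2(fc.values),
        "stat": tt["stat"].values,
        "p": tt["p"].values,
        "fdr": bh_fdr(tt["p"].values),
        "vip": vip.reindex(X.columns).values,
    }).set_index("feature_id", drop=False)
    vipf = out["vip"].fillna(0.0)
    out["significant"] = (vipf > vip_min) & (out["p"] < p_max)
    return out


# ---------------------------------------------------------------------------
# Negative-binomial Wald differential expression
# ---------------------------------------------------------------------------

def _nb_group_mle(y: np.ndarray, s: np.ndarray, alpha: np.ndarray,
                  max_iter: int = 50, tol: float = 1e-10):
    """Vectorized per-gene Newton solver for the NB group mean.

    Model: y_ig ~ NB(mean = s_i * m_g, dispersion alpha_g). Solves the score
    equation for beta = log m jointly over genes. Returns (beta, fisher_info,
    converged) arrays; genes where Newton fails fall back to the moment
    estimate log(sum y / sum s) with convergence flagged False.
    """
    G = y.shape[1]
    tot = y.sum(axis=0)
    s_tot = s.sum()
    # moment start; half-count continuity for all-zero groups
    m0 = np.maximum(tot, 0.5) / s_tot
    beta = np.log(m0)
    converged = np.zeros(G, dtype=bool)
    for _ in range(max_iter):
        mu = s[:, None] * np.exp(beta)[None, :]
        denom = 1.0 + alpha[None, :] * mu
        # score and observed information w.r.t. beta
        score = (y - mu) / denom
        score = score.sum(axis=0)
        info = (mu * (1.0 + alpha[None, :] * y) / denom ** 2).sum(axis=0)
        info = np.maximum(info, 1e-12)
        step = score / info
        step = np.clip(step, -5.0, 5.0)
        beta = beta + step
        converged = np.abs(step) < tol
        if converged.all():
            break
    mu = s[:, None] * np.exp(beta)[None, :]
    fisher = (mu / (1.0 + alpha[None, :] * mu)).sum(axis=0)
    bad = ~np.isfinite(beta)
    if bad.any():
        beta[bad] = np.log(m0[bad])
        converged[bad] = False
    return beta, np.maximum(fisher, 1e-12), converged


def _mom_dispersion(q1: np.ndarray, q2: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Method-of-moments NB dispersion pooled over the two groups,
    estimated on size-factor-normalized counts (floored)."""
    m1, m2 = q1.mean(axis=0), q2.mean(axis=0)
    v1 = q1.var(axis=0, ddof=1)
    v2 = q2.var(axis=0, ddof=1)
    n1, n2 = q1.shape[0], q2.shape[0]
    excess = ((n1 - 1) * (v1 - m1) + (n2 - 1) * (v2 - m2)) / (n1 + n2 - 2)
    msq = (m1 ** 2 + m2 ** 2) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(msq > 0, excess / msq, 0.0)
    return np.maximum(alpha, floor)


def nb_wald_de(counts: OmicsMatrix, labels=None, size_factors: pd.Series | None = None,
               fdr_max: float = 0.01, fc_min: float = 2.0) -> pd.DataFrame:
    """Two-group negative-binomial Wald differential expression.

    Per gene: method-of-moments dispersion on normalized counts, maximum-
    likelihood group means under the NB model with sample-specific size
    factors (log link), Wald test on the log mean ratio referred to a
    t distribution with n1+n2-2 degrees of freedom (the dispersion is
    estimated, so the normal reference is anticonservative at these group
    sizes), BH-FDR. Significance: fdr < ``fdr_max`` AND symmetric
    |FC| > ``fc_min`` (strict).
    """
    from .preprocess import size_factors_median_of_ratios

    y01 = counts.binary_labels() if labels is None else binary_labels(labels)
    if min(np.bincount(y01)) < 2:
        raise ValueError("need at least 2 samples per group")
    if size_factors is None:
        size_factors = size_factors_median_of_ratios(counts)
    s = np.asarray(size_factors.reindex(counts.values.index), dtype=float)
    if (s <= 0).any() or np.isnan(s).any():
        raise ValueError("size factors must be positive for all samples")

    Y = counts.values.to_numpy(dtype=float)
    g1, g2 = y01 == 0, y01 == 1
    q = Y / s[:, None]
    alpha = _mom_dispersion(q[g1], q[g2])

    b1, i1, c1 = _nb_group_mle(Y[g1], s[g1], alpha)
    b2, i2, c2 = _nb_group_mle(Y[g2], s[g2], alpha)
    converged = c1 & c2
    if not converged.all():
        warnings.warn(
            f"{(~converged).sum()} gene(s) fell back to moment estimates "
            "(quasi-likelihood approximation)"
        )

    se = np.sqrt(1.0 / i1 + 1.0 / i2)
    delta = b2 - b1
    z = delta / se
    df_resid = int(g1.sum() + g2.sum() - 2)
    p = 2 * stats.t.sf(np.abs(z), df_resid)
    fdr = bh_fdr(p)
    m1, m2 = np.exp(b1), np.exp(b2)
    fc = m2 / m1
    log2_fc = delta / np.log(2.0)
    abs_fc = np.maximum(fc, 1.0 / fc)
    out = pd.DataFrame({
        "feature_id": counts.values.columns,
        "mean_g1": m1,
        "mean_g2": m2,
        "fc": fc,
        "log2_fc": log2_fc,
        "stat": z,
        "p": p,
        "fdr": fdr,
        "vip": np.nan,
        "significant": (fdr < fdr_max) & (abs_fc > fc_min),
        "direction": np.where(log2_fc > 0, "up", np.where(log2_fc < 0, "down", "none")),
        "converged": converged,
    }).set_index("feature_id", drop=False)
    return out


# ---------------------------------------------------------------------------
# Proteome-style fold-change filter
# ---------------------------------------------------------------------------

def fold_change_filter(m: OmicsMatrix, labels=None, fc_min: float = 1.2,
                       p_max: float = 0.05) -> pd.DataFrame:
    """Symmetric fold-change + t-test filter for linear-scale tables.

    Significance: |FC| >= ``fc_min`` (inclusive, with |FC| = max(FC, 1/FC))
    AND t-test p < ``p_max``.
    """
    y = m.binary_labels() if labels is None else binary_labels(labels)
    X = m.values
    if (X <= 0).any().any():
        raise ValueError("fold-change filter requires positive linear-scale values")
    tt = student_ttest(m, y)
    m1 = X[y == 0].mean(axis=0).to_numpy()
    m2 = X[y == 1].mean(axis=0).to_numpy()
    fc = m2 / m1
    abs_fc = np.maximum(fc, 1.0 / fc)
    out = pd.DataFrame({
        "feature_id": X.columns,
        "mean_g1": m1,
        "mean_g2": m2,
        "fc": fc,
        "log2_fc": np.log2(fc),
        "stat": tt["stat"].values,
        "p": tt["p"].values,
        "fdr": bh_fdr(tt["p"].values),
        "vip": np.nan,
        "significant": (abs_fc >= fc_min) & (tt["p"].values < p_max),
    }).set_index("feature_id", drop=False)
    return out
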