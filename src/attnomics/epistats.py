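"""Clinical-epidemiology layer.

Anemia is flagged by sex-specific hemoglobin cutoffs (HB < 120 g/l for adult
males, < 110 g/l for adult non-pregnant females). Annual incidence per cohort
is cases/tested with Wilson score 95% intervals and a per-year Pearson
chi-square comparison between cohorts. The HB-inflammation association is
validated across linear regression, ridge regression, and random forest, with
Bonferroni correction over the tested markers. Post hoc power uses the
noncentral-t distribution of the two-sample t test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

ADJUSTMENT_COVARIATES = ("age", "sex", "disease_duration", "treatment")
DEFAULT_MARKERS = ("CRP", "ESR", "IL6", "DAS28")

HB_CUTOFF = {"male": 120.0, "female": 110.0}


def anemia_flag(hb: float, sex: str) -> bool:
    """Sex-specific anemia rule: HB < 120 g/l (male) / < 110 g/l (female),
    strict inequalities."""
    if hb <= 0:
        raise ValueError("HB must be positive")
    try:
        cutoff = HB_CUTOFF[str(sex).lower()]
    except KeyError:
        raise ValueError(f"unknown sex category {sex!r}") from None
    return bool(hb < cutoff)


def wilson_ci(k: int, n: int, conf: float = 0.95) -> tuple:
    """Wilson score interval for a binomial proportion; bounds stay in [0,1]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    z = stats.norm.ppf((1 + conf) / 2)
    phat = k / n
    denom = 1 + z ** 2 / n
    center = (phat + z ** 2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z ** 2 / (4 * n ** 2)) / denom
    lo = 0.0 if k == 0 else max(0.0, center - half)  # exact endpoints, no
    hi = 1.0 if k == n else min(1.0, center + half)  # floating-point dust
    return (lo, hi)


def chisq_2x2(a: int, b: int, c: int, d: int, yates: bool = False) -> tuple:
    """Pearson chi-square on the 2x2 table [[a, b], [c, d]].

    No continuity correction by default; ``yates=True`` applies it. A zero
    row or column marginal returns (0.0, 1.0).
    """
    obs = np.array([[a, b], [c, d]], dtype=float)
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    total = obs.sum()
    if total <= 0:
        raise ValueError("table total must be positive")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        return (0.0, 1.0)
    expected = np.outer(rows, cols) / total
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float((diff ** 2 / expected).sum())
    return (chi2, float(stats.chi2.sf(chi2, df=1)))


def annual_incidence(records: pd.DataFrame, conf: float = 0.95) -> pd.DataFrame:
    """Per (year, cohort) anemia incidence with Wilson CIs and per-year
    cohort-comparison chi-square.

    ``records`` needs columns individual_id, year, cohort, sex, HB (or a
    precomputed boolean ``anemia`` column). Each individual may appear once
    per enrollment year.
    """
    req = {"individual_id", "year", "cohort"}
    if not req.issubset(records.columns):
        raise ValueError(f"records need columns {sorted(req)}")
    dup = records.duplicated(subset=["individual_id", "year"])
    if dup.any():
        raise ValueError("duplicate individual within a year")
    rec = records.copy()
    if "anemia" not in rec.columns:
        rec["anemia"] = [
            anemia_flag(h, s) for h, s in zip(rec["HB"], rec["sex"])
        ]
    rows = []
    for (year, cohort), grp in rec.groupby(["year", "cohort"]):
        n = len(grp)
        k = int(grp["anemia"].sum())
        lo, hi = wilson_ci(k, n, conf)
        rows.append({"year": year, "cohort": cohort, "n_tested": n,
                     "n_anemia": k, "rate": k / n, "ci_low": lo, "ci_high": hi})
    out = pd.DataFrame(rows)
    # per-year 2x2 chi-square between the (exactly two) cohorts
    out["chi2"] = np.nan
    out["p"] = np.nan
    for year, grp in out.groupby("year"):
        if len(grp) == 2:
            g = grp.sort_values("cohort")
            a = int(g.iloc[0]["n_anemia"]); b = int(g.iloc[0]["n_tested"]) - a
            c = int(g.iloc[1]["n_anemia"]); d = int(g.iloc[1]["n_tested"]) - c
            chi2, p = chisq_2x2(a, b, c, d)
            out.loc[grp.index, ["chi2", "p"]] = chi2, p
    return out.sort_values(["year", "cohort"]).reset_index(drop=True)


def _design_matrix(clinical: pd.DataFrame, markers) -> tuple:
    """Standardized markers + adjustment covariates (one-hot treatment,
    reference level dropped)."""
    missing = [c for c in list(markers) + list(ADJUSTMENT_COVARIATES)
               if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table lacks columns {missing}")
    if clinical[list(ADJUSTMENT_COVARIATES)].isna().any().any():
        raise ValueError("adjustment covariates must be complete")
    Xm = clinical[list(markers)].astype(float)
    Xm = (Xm - Xm.mean()) / Xm.std(ddof=1)
    cov = pd.DataFrame(index=clinical.index)
    cov["age"] = clinical["age"].astype(float)
    cov["sex_female"] = (clinical["sex"].astype(str).str.lower() == "female").astype(float)
    cov["disease_duration"] = clinical["disease_duration"].astype(float)
    treat = pd.get_dummies(clinical["treatment"], prefix="treatment", drop_first=True, dtype=float)
    X = pd.concat([Xm, cov, treat], axis=1)
    return X, list(markers)


def hb_association(clinical: pd.DataFrame, markers=DEFAULT_MARKERS,
                   seed: int = 0, rf_trees: int = 300) -> pd.DataFrame:
    """HB ~ markers + covariates across three model families.

    Returns one row per marker: linear coefficient, raw and Bonferroni-
    adjusted p (family = the tested markers), ridge coefficient (penalty by
    5-fold CV over a log grid), and RF importance normalized to sum 1 over
    all design columns.
    """
    import statsmodels.api as sm
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.linear_model import RidgeCV

    X, marker_names = _design_matrix(clinical, markers)
    y = clinical["HB"].astype(float).to_numpy()
    Xc = sm.add_constant(X.to_numpy())
    ols = sm.OLS(y, Xc).fit()
    coef = ols.params[1:1 + len(marker_names)]
    pvals = ols.pvalues[1:1 + len(marker_names)]
    cond = np.linalg.cond(Xc)

    ridge = RidgeCV(alphas=np.logspace(-3, 3, 13), cv=5).fit(X.to_numpy(), y)
    ridge_coef = ridge.coef_[:len(marker_names)]

    rf = RandomForestRegressor(n_estimators=rf_trees, random_state=seed, n_jobs=1)
    rf.fit(X.to_numpy(), y)
    imp = rf.feature_importances_
    imp = imp / imp.sum()

    bonf = np.minimum(pvals * len(marker_names), 1.0)
    out = pd.DataFrame({
        "marker": marker_names,
        "linear_coef": coef,
        "linear_p": pvals,
        "bonferroni_p": bonf,
        "ridge_coef": ridge_coef,
        "rf_importance": imp[:len(marker_names)],
        "significant": bonf < 0.05,
    }).set_index("marker", drop=False)
    out.attrs["condition_number"] = float(cond)
    out.attrs["rf_importance_all"] = {c: float(v) for c, v in zip(X.columns, imp)}
    out.attrs["ridge_alpha"] = float(ridge.alpha_)
    return out


def two_sample_power(n1: int, n2: int, d: float, alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample t test at standardized effect |d|,
    via the noncentral t distribution."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    d = abs(float(d))
    df = n1 + n2 - 2
    nc = d * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    power = stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
    return float(power)
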