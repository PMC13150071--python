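"""Preprocessing for metabolite intensity and gene count matrices.

Metabolome: drop features with >20% missing values, impute remaining missing
entries with the per-feature observed minimum, sum-normalize each sample to a
fixed constant (10^4) and log10-transform. Transcriptome: drop genes with more
than 50% zero counts and compute median-of-ratios size factors for
normalization of the downstream differential stage.

All filters use strict inequalities, preserve feature order, and are
idempotent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import OmicsMatrix

#: Fixed sum-normalization constant. Any positive constant only shifts the
#: log10 values uniformly; 1e4 keeps typical normalized intensities >= 1.
SUM_NORM_CONSTANT = 1e4


def filter_metabolite_missingness(m: OmicsMatrix, max_missing_frac: float = 0.20) -> OmicsMatrix:
    """Drop metabolite features whose missing fraction is strictly greater
    than ``max_missing_frac`` (default: the >20% rule)."""
    if m.modality != "metabolome":
        raise ValueError("missingness filter applies to metabolome matrices")
    frac = m.values.isna().mean(axis=0)
    keep = frac.index[(frac <= max_missing_frac).to_numpy()]
    if len(keep) == 0:
        raise ValueError("all features exceed the missingness threshold")
    return m.with_values(m.values.loc[:, keep])


def impute_min(m: OmicsMatrix) -> OmicsMatrix:
    """Replace each missing entry with the per-feature observed minimum."""
    if m.values.isna().all(axis=0).any():
        bad = m.values.columns[m.values.isna().all(axis=0)].tolist()
        raise ValueError(f"features with no observed values cannot be imputed: {bad[:5]}")
    filled = m.values.fillna(m.values.min(axis=0))
    return m.with_values(filled)


def sum_normalize_log10(m: OmicsMatrix, pseudocount: float = 0.0,
                        constant: float = SUM_NORM_CONSTANT) -> OmicsMatrix:
    """Per-sample sum normalization to ``constant`` followed by log10.

    Back-transformed rows sum to ``constant`` exactly. Requires strictly
    positive values (after adding ``pseudocount``).
    """
    vals = m.values + pseudocount
    if (vals <= 0).any().any() or vals.isna().any().any():
        raise ValueError("sum normalization requires strictly positive, complete values")
    totals = vals.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("non-positive sample total")
    normed = vals.div(totals, axis=0) * constant
    return m.with_values(np.log10(normed))


def filter_zero_rows(m: OmicsMatrix, max_zero_frac: float = 0.50) -> OmicsMatrix:
    """Drop genes whose zero-count fraction is strictly greater than
    ``max_zero_frac`` (default: the 'more than 50% zeros' rule)."""
    if m.modality != "transcriptome":
        raise ValueError("zero-row filter applies to transcriptome matrices")
    frac = (m.values == 0).mean(axis=0)
    keep = frac.index[(frac <= max_zero_frac).to_numpy()]
    if len(keep) == 0:
        raise ValueError("all genes exceed the zero-fraction threshold")
    return m.with_values(m.values.loc[:, keep])


def size_factors_median_of_ratios(m: OmicsMatrix) -> pd.Series:
    """Median-of-ratios size factors (the DESeq-style estimator).

    For each gene expressed in every sample, compute the ratio of each
    sample's count to the gene's geometric mean; the sample's size factor is
    the median of those ratios.
    """
    counts = m.values.to_numpy(dtype=float)
    all_pos = (counts > 0).all(axis=0)
    if not all_pos.any():
        raise ValueError("no gene has nonzero counts in every sample")
    sub = counts[:, all_pos]
    log_gm = np.log(sub).mean(axis=0)
    ratios = sub / np.exp(log_gm)[None, :]
    sf = np.median(ratios, axis=1)
    return pd.Series(sf, index=m.values.index, name="size_factor")


def filter_qc_rsd(m: OmicsMatrix, qc_sample_ids, max_rsd: float = 0.30) -> OmicsMatrix:
    """Optional QC filter: drop features whose relative standard deviation
    across designated QC injections exceeds ``max_rsd``. Disabled by default
    in the pipeline because synthetic data carries no QC samples."""
    qc = m.values.loc[list(qc_sample_ids)]
    mean = qc.mean(axis=0)
    rsd = qc.std(axis=0, ddof=1) / mean.replace(0, np.nan)
    keep = m.values.columns[(rsd <= max_rsd).fillna(False).to_numpy()]
    if len(keep) == 0:
        raise ValueError("all features exceed the QC RSD threshold")
    return m.with_values(m.values.loc[:, keep])


def preprocess_metabolome(m: OmicsMatrix, max_missing_frac: float = 0.20,
                          pseudocount: float = 0.0) -> tuple[OmicsMatrix, dict]:
    """Full metabolome chain: missingness filter -> min imputation ->
    sum normalization + log10. Returns the matrix and a removal log."""
    n0 = m.n_features
    filtered = filter_metabolite_missingness(m, max_missing_frac)
    imputed = impute_min(filtered)
    out = sum_normalize_log10(imputed, pseudocount=pseudocount)
    log = {
        "input_features": n0,
        "removed_missingness": n0 - filtered.n_features,
        "output_features": out.n_features,
    }
    return out, log


def preprocess_transcriptome(m: OmicsMatrix, max_zero_frac: float = 0.50
                             ) -> tuple[OmicsMatrix, pd.Series, dict]:
    """Full transcriptome chain: zero-row filter + size factors."""
    n0 = m.n_features
    filtered = filter_zero_rows(m, max_zero_frac)
    sf = size_factors_median_of_ratios(filtered)
    log = {
        "input_features": n0,
        "removed_zero_rows": n0 - filtered.n_features,
        "output_features": filtered.n_features,
    }
    return filtered, sf, log
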