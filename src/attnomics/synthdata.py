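"""Seeded synthetic generators for every input the pipeline consumes.

The generators emulate the study inputs with planted, known ground truth:

* transcriptome — negative-binomial counts with a log-normal gene mean
  spectrum, mean-dependent dispersion alpha(mu) = dispersion_scale/mu + 0.01,
  gamma-distributed library sizes, a configurable fraction of near-silent
  genes (to exercise the >50%-zeros filter), and planted fold changes;
* metabolome — feature-wise log-normal intensities generated on the raw
  scale (so sum normalization and log10 are exercised), MCAR missingness,
  a configurable block of high-missingness features (to exercise the >20%
  filter), and planted mean shifts in per-feature SD units;
* clinical — covariates plus inflammation markers with a planted negative
  HB dependence on standardized ESR/CRP;
* incidence — per-year Bernoulli anemia events per cohort at stated rates,
  emitted as visit-level records with HB values consistent with the
  sex-specific anemia cutoffs.

Every generator is a pure function of its parameters including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GROUP_NEGATIVE, GROUP_POSITIVE, GroundTruth, OmicsMatrix


@dataclass(frozen=True)
class SynthOmicsParams:
    """Study conditions for one synthetic omics matrix.

    ``effect_log2fc`` applies to transcriptome counts (group-2 mean is
    multiplied by 2**effect_log2fc for planted genes); ``effect_shift_sd``
    applies to metabolome intensities (planted features are shifted by that
    many per-feature log-scale SDs in group 2).
    """

    n_per_group: int = 40
    n_features: int = 500
    n_planted: int = 20
    effect_log2fc: float = 2.0
    effect_shift_sd: float = 1.5
    missing_rate: float = 0.05
    dispersion_scale: float = 5.0
    libsize_cv: float = 0.2
    zero_gene_frac: float = 0.10
    n_high_missing: int = 10
    high_missing_rate: float = 0.30
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 1 or self.n_features < 1:
            raise ValueError("counts must be positive integers")
        for f in ("n_per_group", "n_features", "n_planted", "n_high_missing", "seed"):
            if int(getattr(self, f)) != getattr(self, f):
                raise ValueError(f"{f} must be an integer")
        if self.n_planted < 0 or self.n_planted > self.n_features:
            raise ValueError("n_planted must lie in [0, n_features]")
        if not 0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must lie in [0, 0.5)")
        if self.dispersion_scale <= 0:
            raise ValueError("dispersion_scale must be > 0")
        if self.libsize_cv < 0:
            raise ValueError("libsize_cv must be >= 0")
        if not 0 <= self.zero_gene_frac < 1:
            raise ValueError("zero_gene_frac must lie in [0, 1)")


def _group_labels(n_per_group: int) -> pd.Series:
    ids = [f"S{i:04d}" for i in range(2 * n_per_group)]
    groups = [GROUP_NEGATIVE] * n_per_group + [GROUP_POSITIVE] * n_per_group
    return pd.Series(groups, index=ids, name="group")


def generate_transcriptome(params: SynthOmicsParams) -> tuple:
    """Negative-binomial count matrix plus ground truth."""
    rng = np.random.default_rng(params.seed)
    n, p = params.n_per_group, params.n_features
    genes = np.array([f"gene{j:05d}" for j in range(p)])
    labels = _group_labels(n)

    # log-normal mean spectrum; a fraction of near-silent genes
    base_mean = rng.lognormal(mean=3.0, sigma=1.5, size=p)
    n_zero = int(round(params.zero_gene_frac * p))
    zero_idx = rng.choice(p, size=n_zero, replace=False) if n_zero else np.array([], dtype=int)
    base_mean[zero_idx] = 0.05  # ~95% zero counts at typical library size

    # plant fold changes in adequately expressed genes only
    candidates = np.setdiff1d(np.nonzero(base_mean >= 5.0)[0], zero_idx)
    if params.n_planted > len(candidates):
        raise ValueError("not enough expressed genes to plant the requested effects")
    planted_idx = rng.choice(candidates, size=params.n_planted, replace=False)
    planted_idx.sort()

    mult = np.ones(p)
    mult[planted_idx] = 2.0 ** params.effect_log2fc
    group2 = np.arange(2 * n) >= n

    if params.libsize_cv > 0:
        shape = 1.0 / params.libsize_cv ** 2
        lib = rng.gamma(shape=shape, scale=1.0 / shape, size=2 * n)
    else:
        lib = np.ones(2 * n)

    alpha = params.dispersion_scale / np.maximum(base_mean, 1e-6) + 0.01
    mean_mat = lib[:, None] * base_mean[None, :]
    mean_mat[group2] = mean_mat[group2] * mult[None, :]
    r = 1.0 / alpha
    prob = r[None, :] / (r[None, :] + mean_mat)
    counts = rng.negative_binomial(n=np.broadcast_to(r, mean_mat.shape), p=prob)

    values = pd.DataFrame(counts, index=labels.index, columns=genes, dtype=np.int64)
    matrix = OmicsMatrix(values=values, modality="transcriptome", group_labels=labels)
    effects = pd.Series(0.0, index=genes)
    effects.iloc[planted_idx] = params.effect_log2fc
    truth = GroundTruth(
        planted_feature_ids=list(genes[planted_idx]),
        effect_sizes=effects,
        group_assignment=labels,
    )
    return matrix, truth


def generate_metabolome(params: SynthOmicsParams) -> tuple:
    """Raw-scale log-normal intensity matrix with MCAR missingness."""
    rng = np.random.default_rng(params.seed)
    n, p = params.n_per_group, params.n_features
    feats = np.array([f"met{j:05d}" for j in range(p)])
    labels = _group_labels(n)

    mu = rng.uniform(np.log(1e3), np.log(1e7), size=p)
    sigma = rng.uniform(0.2, 0.6, size=p)
    planted_idx = rng.choice(p, size=params.n_planted, replace=False)
    planted_idx.sort()

    z = rng.standard_normal(size=(2 * n, p))
    log_int = mu[None, :] + sigma[None, :] * z
    group2 = np.arange(2 * n) >= n
    shift = np.zeros(p)
    shift[planted_idx] = params.effect_shift_sd
    log_int[group2] += (shift * sigma)[None, :]
    intensities = np.exp(log_int)

    # MCAR mask at the base rate, plus a high-missingness block (chosen among
    # non-planted features so the planted signal survives the >20% filter)
    mask = rng.random(size=intensities.shape) < params.missing_rate
    if params.n_high_missing:
        pool = np.setdiff1d(np.arange(p), planted_idx)
        hi = rng.choice(pool, size=min(params.n_high_missing, len(pool)), replace=False)
        mask[:, hi] |= rng.random(size=(2 * n, len(hi))) < params.high_missing_rate
    vals = intensities.copy()
    vals[mask] = np.nan

    values = pd.DataFrame(vals, index=labels.index, columns=feats)
    matrix = OmicsMatrix(values=values, modality="metabolome", group_labels=labels)
    effects = pd.Series(0.0, index=feats)
    effects.iloc[planted_idx] = params.effect_shift_sd
    truth = GroundTruth(
        planted_feature_ids=list(feats[planted_idx]),
        effect_sizes=effects,
        group_assignment=labels,
    )
    return matrix, truth


TREATMENT_LEVELS = ("none", "csDMARD", "biologic")
TREATMENT_PROBS = (0.2, 0.5, 0.3)
TREATMENT_HB_OFFSET = {"none": 0.0, "csDMARD": 0.5, "biologic": 1.0}


def generate_clinical(n: int, seed: int = 0, beta_esr: float = -0.4,
                      beta_crp: float = -0.2, noise_sd: float = 1.0) -> pd.DataFrame:
    """Clinical covariate table with a planted HB-inflammation dependence.

    HB (g/l) = 128 - 0.05*(age-55) - 3*female - 0.1*duration
               + treatment offset + beta_esr*z_ESR + beta_crp*z_CRP + noise,
    where z_* are the standardized marker values. Markers share a latent
    inflammation factor (pairwise correlation ~0.3) and are linear in their
    z-scores so regression on standardized raw values recovers the betas.
    """
    if n < 10:
        raise ValueError("need n >= 10")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    rng = np.random.default_rng(seed)
    ids = [f"P{i:05d}" for i in range(n)]
    age = np.clip(rng.normal(55.8, 12.6, n), 18, 90)
    female = rng.random(n) < 0.78
    duration = rng.exponential(6.0, n)
    treatment = rng.choice(TREATMENT_LEVELS, size=n, p=TREATMENT_PROBS)

    latent = rng.standard_normal(n)
    def marker_z():
        return np.sqrt(0.3) * latent + np.sqrt(0.7) * rng.standard_normal(n)
    z_esr, z_crp, z_il6, z_das = (marker_z() for _ in range(4))

    hb = (128.0 - 0.05 * (age - 55.0) - 3.0 * female - 0.1 * duration
          + np.array([TREATMENT_HB_OFFSET[t] for t in treatment])
          + beta_esr * z_esr + beta_crp * z_crp
          + noise_sd * rng.standard_normal(n))

    return pd.DataFrame({
        "sample_id": ids,
        "age": age,
        "sex": np.where(female, "female", "male"),
        "disease_duration": duration,
        "treatment": treatment,
        "HB": hb,
        "CRP": 20.0 + 4.0 * z_crp,
        "ESR": 40.0 + 8.0 * z_esr,
        "IL6": 15.0 + 3.0 * z_il6,
        "DAS28": 4.5 + 0.9 * z_das,
    }).set_index("sample_id", drop=False)


def generate_incidence(years, rates_by_cohort: dict, n_by_cohort: dict,
                       seed: int = 0) -> pd.DataFrame:
    """Visit-level records with per-year Bernoulli anemia events per cohort.

    ``rates_by_cohort``/``n_by_cohort`` map cohort name to a scalar or a
    per-year sequence. HB values are drawn consistent with the sex-specific
    anemia cutoffs so the flagging rule reproduces the planted outcome.
    """
    years = list(years)
    rng = np.random.default_rng(seed)

    def per_year(val, what):
        if np.isscalar(val):
            return [val] * len(years)
        val = list(val)
        if len(val) != len(years):
            raise ValueError(f"{what} length must match the number of years")
        return val

    rows = []
    for cohort in sorted(rates_by_cohort):
        rates = per_year(rates_by_cohort[cohort], f"rates for {cohort}")
        ns = per_year(n_by_cohort[cohort], f"n for {cohort}")
        for year, rate, n in zip(years, rates, ns):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
            if n < 1:
                raise ValueError("n must be positive")
            anemia = rng.random(n) < rate
            female = rng.random(n) < 0.6
            cutoff = np.where(female, 110.0, 120.0)
            offset = rng.uniform(1.0, 40.0, n)
            hb = np.where(anemia, cutoff - offset, cutoff + offset)
            for i in range(n):
                rows.append({
                    "individual_id": f"{cohort}_{year}_{i:06d}",
                    "year": int(year),
                    "cohort": cohort,
                    "sex": "female" if female[i] else "male",
                    "HB": float(hb[i]),
                    "anemia": bool(anemia[i]),
                })
    return pd.DataFrame(rows)
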