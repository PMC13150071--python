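# Methods

`attnomics` implements a two-group multiomics biomarker-selection procedure
for rheumatoid arthritis with anemia (RA_ane, defined by hemoglobin < 120 g/l
in adult males and < 110 g/l in adult non-pregnant females) versus RA without
anemia, together with the clinical-epidemiology statistics that motivate the
contrast. Because no cohort data are publicly deposited, every stage is
exercised on seeded synthetic data with planted, known ground truth; this note
records the models, the defaults, and the design choices that were genuinely
open.

## The attention stage

### Model

Within each fold of a stratified 5-fold cross-validation, the feature matrix
is standardized and projected onto the leading principal components — 10 for
the metabolome, 30 for the transcriptome — with both the scaler and the PCA
fitted **only** on the fold's training portion ("confined" CV). Each component
score becomes one token of a 3-layer post-norm transformer encoder
(multi-head self-attention with 2 heads for the metabolome and 6 for the
transcriptome, GELU feed-forward of width 2d, dropout 0.5 after each sublayer,
embedding dimension d = 24). A learnable classification token is prepended;
the sigmoid head reads its final state. Training minimizes binary
cross-entropy with Adam (learning rate 5e-4 metabolome / 1e-4 transcriptome)
under an L2 weight-decay penalty λ = 0.1, with early stopping on a stratified
20% validation split of the training portion (patience 8 / 10 epochs,
at most 200 epochs, minibatches of 16).

The network is implemented directly on numpy arrays with hand-derived
gradients for every block (embedding, attention softmax, LayerNorm,
feed-forward, pooling head); the backward pass is checked against central
finite differences in the test suite. All randomness (initialization, dropout
masks, batch order, validation split) flows from a single integer seed, so a
fixed configuration reproduces byte-identical weights and histories.

### Architecture choices that mattered

Three choices were open and were settled by measurement on planted synthetic
data; each is a property of how small transformers train, not a tuning knob:

* **Per-component token embeddings.** With one shared scalar-to-embedding map,
  a pooled readout can only see the *mean* of the component scores at
  initialization; separating an informative component then requires learning
  positional routing first, a plateau of roughly a hundred epochs that the
  8-epoch early-stopping patience always aborts. Giving each component its own
  embedding vector makes the pooled state a full-rank linear view of the score
  vector from the first gradient step, and the model trains inside the
  patience window.
* **CLS-token readout.** With mean pooling plus residual connections the
  classifier can read the component values without ever moving attention off
  its near-uniform initialization, which leaves the attention weights
  uninformative. Reading only the classification token forces all predictive
  information through attention, which is what makes attention weights
  meaningful as component usage.
* **Decoupled weight decay.** Applying λ = 0.1 as a classic coupled L2 term
  inside Adam lets the decay gradient dominate the second-moment estimate;
  the data gradient is normalized away and the network never leaves
  initialization. The penalty is therefore applied in decoupled (AdamW) form
  to weight matrices only (biases, LayerNorm parameters, and positional
  embeddings are exempt), which is the standard practice for transformers.

### Attention-derived importance

Per-component importance is the attention mass each component token receives:
the column means of every softmax attention matrix (CLS column excluded),
averaged over heads, layers, and samples, renormalized to sum to 1.
Per-feature importance propagates component importance through **squared**
PCA loadings — feature j's variance share of component c times the attention
c receives, summed over components, averaged over folds. Squared loadings
were chosen over absolute loadings after measurement: attention concentration
under the early-stopping regime is mild, and with |loading| weighting the
planted features' bump on the informative components is buried under the
additive |loading| noise of the uninformative ones (planted-feature recovery
0.68 vs 0.82 over five seeds, at lower false-discovery proportion). Both
mappings are invariant to component sign flips.

The **dual filter** intersects the classically differential features with the
top 20% of features by this importance (computed over the full feature
universe, by ceiling count, ties broken lexicographically by feature id).

### The deliberate-leakage mode

`cross_validate(..., leak_mode=True)` exists only to demonstrate that the
confinement matters. Note that fitting the scaler/PCA on all samples is
*unsupervised* leakage: under label permutation it cannot raise the expected
AUC above 0.5, so on its own it is undetectable by a permutation null. The
leak mode therefore also monitors early stopping on the evaluation fold
itself — a supervised leak (the stopping epoch is chosen to flatter the test
fold) that biases fold AUC upward and makes the regression test meaningful.

## Classical differential layers

* **Metabolome** — OPLS-DA VIP with one predictive component after removing
  one y-orthogonal component (NIPALS), on column-standardized log10 data.
  With a single predictive component VIP_j = sqrt(p)·|w_j| for the unit-norm
  weight vector, so mean(VIP²) = 1 identically; this is asserted on every
  input. Combined with a pooled-variance two-sided t test; the differential
  rule is VIP > 1.0 AND raw P < 0.05, both strict. FDR is deliberately not
  applied at this stage (collinear metabolite panels make strict FDR very
  conservative); false positives are instead handled by the dual filter.
* **Transcriptome** — genes with more than 50% zeros are removed (strict),
  counts are normalized by median-of-ratios size factors, and a two-group
  negative-binomial Wald test is fitted per gene: method-of-moments
  dispersion pooled over groups (floored at 1e-8, no empirical-Bayes
  shrinkage), group means by a vectorized Newton solver of the NB score
  equation with sample-specific size factors, Wald statistic on the log mean
  ratio referred to a t distribution with n1+n2−2 degrees of freedom. The t
  reference replaces the asymptotic normal because the dispersion is a
  plug-in estimate: at n = 30/group the normal reference rejected 6.1% of
  null genes at nominal 5%, the t reference 5.6%. The residual ~0.5%
  inflation is inherent to plug-in Wald tests without shrinkage and is
  documented rather than hidden; calibration is asserted against the
  per-replicate binomial band, since genes within a replicate share the
  size-factor estimate. Significance: BH-FDR < 0.01 AND symmetric
  |FC| = max(FC, 1/FC) > 2.
* **Proteome-style tables** — |FC| ≥ 1.2 (inclusive) AND t-test P < 0.05 on
  positive linear-scale values.

Non-convergent NB fits (non-finite Newton updates) fall back to moment
estimates and are flagged in a `converged` column with a warning.

## Preprocessing

Metabolome: features with **more than** 20% missing values are dropped
(strict inequality), remaining missing entries are imputed with the
per-feature observed minimum (per-feature rather than global, preserving
feature-specific detection floors), each sample is sum-normalized to 10⁴
(any fixed constant only shifts the log values uniformly) and
log10-transformed. An optional QC relative-standard-deviation filter
(> 30% across designated QC injections) is provided but disabled by default —
synthetic data carries no QC injections. All filters are idempotent and
preserve feature order.

## Consensus, diagnostic model, evaluation

Five models rank the dual-filter candidates on standardized full-data fits:
KNN (k = 5) and RBF-SVM via seeded permutation importance (20 repeats, AUC
drop), random forest (500 trees) and XGBoost (200 rounds, depth 3) via
impurity/gain importance, and RFE-RF via elimination order. The consensus
panel is the intersection of the five top-10 lists, ordered by mean rank;
it is monotone in k and invariant to list order.

The diagnostic model takes the top 5 consensus features, splits samples
7:3 with per-class randomization (train counts are round(0.7·n_class)), and
fits an L2 logistic regression (C = 1) with standardization parameters from
the training partition only. The paper-style evaluation suite reports AUC
(Mann–Whitney identity, ties at 1/2 — identical to the trapezoidal ROC area),
accuracy/precision/recall/F1 at the 0.5 probability cut (zero-denominator
cases return 0 with a flag), step-wise average precision, 5-quantile-bin
calibration (equal-count bins, ties kept together; constant scores collapse
to a single bin), and a stratified percentile bootstrap CI (2000 resamples)
for AUC differences. Feature–clinical correlation uses Spearman's rho with
BH-FDR across the whole feature × {HB, CRP, ESR, IL-6, DAS28} matrix
(Spearman chosen for robustness on omics scales).

## Clinical epidemiology

Annual anemia incidence per cohort is cases/tested among individuals
enrolled that year (duplicate individuals within a year are rejected), with
Wilson score 95% intervals (closed form; exact 0/1 endpoints at k = 0 and
k = n) and a per-year Pearson chi-square between cohorts without continuity
correction (a Yates flag is provided). The HB association fits
HB ~ standardized markers (CRP, ESR, IL-6, DAS28) + age + sex + disease
duration + one-hot treatment (reference level dropped) by OLS, ridge (penalty
by 5-fold CV over a log grid 1e-3..1e3), and a random-forest regressor whose
importances are normalized to sum to 1; Bonferroni correction multiplies the
OLS p-values by the number of tested markers only. Post hoc power for the
two-sided two-sample t test is evaluated from the noncentral t distribution.

## Synthetic data: what it emulates and what it does not

* **Transcriptome** — log-normal gene mean spectrum (log-mean 3, log-SD 1.5),
  negative-binomial counts with the mean–dispersion trend
  α(μ) = dispersion_scale/μ + 0.01 (dispersion_scale = 5), gamma library
  sizes with CV 0.2, 10% near-silent genes (mean 0.05) to exercise the
  zero-row filter, planted genes (default 30 of 2000 at log2FC 2, drawn from
  genes with base mean ≥ 5 so the planted contrast is estimable) have their
  group-2 mean multiplied by 2^log2FC.
* **Metabolome** — per-feature log-normal intensities on the raw scale
  (log-locations uniform over ln 10³..ln 10⁷, log-SDs 0.2–0.6) so that sum
  normalization and the log transform are genuinely exercised; MCAR
  missingness at 5% plus a block of 10 high-missingness features (30%) drawn
  from the non-planted pool; planted features (default 20 of 500) shifted by
  1.5 per-feature log-scale SDs in group 2.
* **Clinical** — age ~ N(55.8, 12.6²) clipped at 18, 78% female, exponential
  disease duration (mean 6 y), three treatment levels (none/csDMARD/biologic
  at 0.2/0.5/0.3). The four inflammation markers share a latent factor
  (pairwise correlation ≈ 0.3) and are *linear* in their z-scores, so a
  regression on standardized raw values recovers the planted coefficients;
  HB = 128 − 0.05(age−55) − 3·female − 0.1·duration + treatment offset
  − 0.4·z_ESR − 0.2·z_CRP + N(0, 1) g/l by default. The HB scale is
  compressed relative to clinical reality so that coefficient recovery is
  sharp at n = 1000; it is a statistical test bench, not a physiological
  simulator.
* **Incidence** — per-year Bernoulli anemia events per cohort at stated
  rates (defaults: RA 0.40, non-RA 0.10, years 2020–2025), with HB values
  drawn consistent with the sex-specific cutoffs so the flagging rule
  reproduces the planted outcome exactly.

Not modeled: intensity-dependent (non-MCAR) missingness, batch effects,
QC-injection structure, skewed marker distributions, microbial communities,
and proteomic spectra. Consequently, passing tests demonstrate the
statistical machinery and its calibration under the stated generative
models — not robustness to the messier failure modes of real cohorts.

## Numerical conventions

Strict vs inclusive thresholds follow the printed rules exactly
(>20% missing, >50% zeros, VIP > 1.0, P < 0.05, FDR < 0.01, |FC| > 2,
|FC| ≥ 1.2, HB < 120/110). Ties in top-fraction and ranking selections break
lexicographically by feature id. The positive class is RA_ane everywhere.
Degenerate inputs return flagged values rather than NaN (t test with zero
pooled variance → p = 1; zero chi-square marginal → p = 1; empty dual-filter
intersection → logged, downstream stages skipped). Problem sizes in the test
suite and acceptance script (e.g., 2000-gene calibration runs, n = 200
permutation nulls, 5-seed recovery studies) were chosen as the smallest sizes
at which the asserted properties are stable.

## Known limitations

The NB Wald engine is mildly anticonservative at small n (see above) and
deliberately omits dispersion shrinkage, so it will not numerically reproduce
reference DE packages. Attention concentration under the prescribed
early-stopping regime is modest; feature importance therefore leans on the
loading propagation, and the dual filter — not the attention ranking alone —
is the unit with demonstrated false-discovery control. The bootstrap CI is
percentile-based and unstudentized. Incidence analysis assumes exactly two
cohorts for the per-year chi-square comparison.
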