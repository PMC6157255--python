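# Methods

This note documents the statistical models implemented in `stratomics`,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Drug-response phenotype

The response is binary: `TG_pre` is the mean of the two pre-treatment
triglyceride visits, `TG_post` the mean of the two post-treatment visits,
`change = (TG_post − TG_pre)/TG_pre`, and `response = 1` iff
`change < −0.30`. The boundary is strict: "reduced by more than 30%" is
read literally, so a change of exactly −30% codes as non-response. The
derivation is scale-invariant (units of TG cancel).

## SNP screening: GEE logistic regression

Each SNP is tested marginally in a logistic model with an intercept and
the additive dosage (covariates optional, off by default), fitted by
generalized estimating equations over family clusters:

- logit link, binomial variance, **exchangeable** working correlation
  (one parameter α for every within-family pair);
- Fisher-scoring updates of β alternated with a moment update of α from
  Pearson residuals (with the usual p and dispersion corrections), to a
  relative coefficient change below 1e−8 or 100 iterations;
- robust (sandwich) covariance `B⁻¹ M B⁻¹`; two-sided Wald p-values on
  the normal reference.

The exchangeable working inverse has the closed form
`R⁻¹ = [I − α/(1+(n_i−1)α) J] / (1−α)`, applied per cluster in O(n) with
vectorized cluster sums, which is what makes genome-scan loops cheap.
With singleton clusters the procedure reduces exactly to ordinary
logistic IRLS with an HC0 sandwich — this is tested against statsmodels.
Fits with |β| > 15 are flagged as separated; non-converged or separated
fits report missing p-values and are never selected. The dispersion
parameter cancels from both the β update and the sandwich and is not
estimated.

Assumptions: outcomes are exchangeable within family given the marker;
the marginal (population-averaged) log-odds is the estimand. The GEE is
robust to misspecification of the working correlation; the sandwich
relies on the number of families (~170 and up here) being large enough
for its asymptotics.

## CpG screening: kinship linear mixed model

The 0/1 response is treated as quantitative (a linear probability model)
— the pragmatic convention that lets a mixed model with a continuous
random effect handle a binary phenotype. The null model is

    y = Wβ + g + ε,  g ~ N(0, σ²_g K),  ε ~ N(0, σ²_e I)

with `K` the empirical kinship. REML estimation follows the
single-spectral-decomposition scheme: diagonalize `K = U S Uᵀ` once,
rotate `y` and `W` by `Uᵀ`, and profile the restricted likelihood down to
the ratio `δ = σ²_e/σ²_g`; each δ evaluation is then O(n). δ is optimized
on a 121-point grid of log δ ∈ [−10, 10] followed by bounded Brent
refinement between the bracketing grid points (xatol 1e−10). A boundary
optimum is reported as such (σ²_g = 0 at the upper edge); a flat kinship
spectrum (e.g. K = I) is flagged non-identifiable — only the total
variance is then determined, and it equals the OLS residual variance.

Per-site tests hold δ at the null fit and test the site's beta-value
column by GLS in the rotated, whitened space. The residual **scale is
re-estimated per marker** and the reference is t with n−p−1 degrees of
freedom, so with K = I the test collapses exactly onto the standard OLS
t-test (tested to 1e−6 against statsmodels). Holding the variance *ratio*
at the null while re-estimating the scale is the standard fast
approximation for screening; per-marker exact REML differs negligibly at
screen thresholds. Constant sites get effect 0 and p = 1.

## Relatedness: LD pruning and the GRM

Pruning is a deterministic greedy left-to-right scan within each
chromosome: a SNP is kept iff its squared Pearson correlation (on imputed
dosages) with every already-kept SNP within the base-pair window is below
the threshold. Defaults: r² < 0.2, 500 kb window (the window size is a
package choice; it is configurable). Duplicate SNPs therefore resolve to
the leftmost copy. The threshold applies to r² on dosages — with
complete (imputed) data this is the natural deterministic reading of an
LD threshold of 0.2.

Kinship is the VanRaden genomic relationship matrix from the pruned set:
`K = ZZᵀ / (2Σ p_j(1−p_j))` with `Z` the dosage matrix centered by `2p_j`
(sample alt-allele frequencies), monomorphic SNPs excluded from both
numerator and scale. Under this scaling unrelateds average ≈ 0, the
diagonal ≈ 1, and full siblings ≈ 0.5 off-diagonal. Because `Z` is
column-centered the grand mean of each row of K is ~0, so the
off-diagonal mean sits mechanically at ≈ −1/(n−1) rather than exactly 0.
Negative eigenvalues (possible with fewer SNPs than samples) are clipped
at zero.

## Marker selection

Selection is `p < 10⁻⁴`, strict, per scan, with no further
multiple-testing correction — the threshold is an explicitly arbitrary
device to pass a moderate number of predictors to the network. Selected
ids are ordered by ascending p with ties broken by marker id, so
selection is deterministic and permutation-stable.

## The neural network

Three layers: inputs → one hidden layer of `n_hidden` tansig units
(`tansig(n) = −1 + 2/(1+e^{−2n})`, algebraically `tanh`) → a single
purelin (identity) output. Targets are coded 0/1; the decision rule is
score ≥ 0.5 (equivalent to a sign rule under ±1 coding). The loss is the
least-mean-squares criterion `L = mean((score − y)²)/2`, minimized by
**full-batch** gradient descent with momentum and an adaptive rate:

    Δw_t = μ Δw_{t−1} − η_t ∇L

After each epoch, if the new loss exceeds `error_ratio_limit` (1.04)
times the previous loss the step is rejected, the momentum buffer zeroed,
and η cut by 0.7; otherwise the step is accepted and, when the loss fell,
η grows by 1.05. η₀ = 0.01 and μ = 0.4 are the study configuration; the
schedule constants are the conventional adaptive-GD-with-momentum
defaults and are exposed in `TrainConfig`. Setting μ = 0 and freezing the
rate factors at 1 reduces the optimizer exactly to plain gradient descent
(tested to 1e−10 against an independent loop). Full-batch training makes
runs deterministic given the seed and invariant to sample order.

Defaults: 10 hidden units (unstated in the source protocol; configurable),
uniform(−0.5, 0.5) seeded weight init with zero biases, epoch cap 5000
with early stop when the accepted-loss change falls below 1e−10. The
pipeline caps training at 600 epochs per fold — at ~500 samples and ≤110
features the loss plateau is reached well before that, and the cap keeps
a 20-replicate evaluation tractable on one CPU.

## Cross-validated stepwise evaluation

Folds are **family-blocked**: whole families are assigned greedily
(largest first into the currently smallest fold, seeded random
tie-break), because siblings split across folds would leak familial
correlation into the test estimate. A `folds_ignore_family` flag
reproduces the naive per-sample assignment for comparison.

Marker screening runs **inside each fold** on training samples only; the
per-fold selected sets are shared across the nested predictor sets (they
are identical by construction). Standardization (per-column z-score) is
fitted on training rows only and applied unchanged to held-out rows; both
leakage guards are property-tested. A `select_once` flag reproduces
whole-sample selection for comparison with protocols that screen before
splitting. LD pruning and kinship use genotypes only (no response
information) and are computed once.

The four models run in a fixed order: 100 random autosomal SNPs
(baseline), screened SNPs, + screened CpGs, + age/sex/smoking. When both
screened blocks of a model come up empty in a fold — routine under the
null, where the expected number of selections per fold is ~0.2 — the
model falls back to the baseline SNP block (plus clinical covariates if
in the set), i.e. it degrades to the step it was built on rather than to
a bias-only network. This keeps the stepwise chain well-defined and makes
the all-null configuration behave as it should: four models of equivalent
(uninformative) content that are statistically indistinguishable.

Consecutive models are compared by the two-sided Wilcoxon rank-sum test
on their five fold test errors: exact enumeration with mid-ranks for
combined n ≤ 20 (p = twice the smaller tail, capped at 1), tie-corrected
normal approximation with continuity correction above. Reported SDs are
sample SDs (divisor k−1) over fold errors.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, at desk scale:

- **Families**: 174 sibships of 2–4 siblings (uniform), expected cohort
  ≈ 522, matching the ~523-sibling design of the motivating study. Two
  founders per family are simulated for transmission and excluded from
  the analysis cohort by default.
- **Genotypes**: per-SNP founder allele frequency uniform on (0.05, 0.5];
  founders in Hardy–Weinberg proportions; siblings inherit one uniformly
  chosen allele from each founder, so sib pairs share alleles identical
  by descent and the realized GRM reproduces pedigree expectations.
  Missing calls at 2%. 2,000 SNPs spread over 22 autosomes with 1–10 kb
  spacing.
- **Methylation**: 1,000 CpG sites generated on the M-value (logit)
  scale as site mean + family effect + individual noise with family ICC
  0.3 of a unit total variance; betas are the inverse logit. Effects
  *enter* the phenotype via standardized M-values while the *analysis*
  scans betas — a deliberate, documented transform mismatch matching
  common practice.
- **Covariates**: age ~ uniform 20–70 y, sex ~ Bernoulli(0.5), smoking ~
  Bernoulli(0.25) (no distributions are given by the source protocol).
- **Phenotype**: a liability score sums 4 causal SNPs at log-OR 1.2 per
  allele, 4 causal CpGs at log-OR 1.0 per SD of M-value, covariate
  effects (0.05/yr on centered age, 1.2 sex, 1.5 smoking), a per-family
  polygenic effect (SD 0.5), and logistic noise. The threshold is
  calibrated by root finding so the expected responder fraction is 0.576;
  status is then Bernoulli. TG visits are constructed afterwards so the
  derived change is < −30% exactly for responders (responders draw change
  from U(−0.60, −0.35), matching the drug's typical 30–60% reduction;
  non-responders from U(−0.25, 0.10)), with ±5% within-pair visit noise
  that cannot flip status.

Effect sizes were fixed once by a design-time power analysis: at n ≈ 520
with a p < 10⁻⁴ screen, a marginal per-allele log-OR near 1.2 gives
~50–60% per-SNP selection power after attenuation by the other liability
components, which is the regime in which a stepwise benchmark is
informative (many weak effects would make every model indistinguishable
at this sample size; that regime is available via the config).

**What the generator does not emulate**: probe-type (Infinium I/II)
artifacts, cross-reactive probes, or cell-type composition in
methylation; realistic LD (SNPs are ancestrally independent, so pruning
bites only on chance correlation at desk scale); multi-generation
pedigrees (sibships only); genotype-phenotype confounding through
population stratification. The fully shared per-family polygenic effect
has within-family correlation 1, slightly more than the 0.5 a sib
kinship can represent — a deliberate stress on the adjustment rather than
a perfectly specified case. Passing tests therefore demonstrate the
statistical machinery (calibration under family correlation, leakage-free
evaluation, qualitative stepwise gains), not robustness to array
artifacts or ancestry structure in real data.

## QC

Order: sample alignment/complete-case intersection → MAF filter
(< 0.01 excluded, computed on non-missing calls) → stochastic imputation
of missing genotypes from each SNP's empirical {0,1,2} distribution
(seeded; "expected dosage" imputation would shrink variance and is
deliberately not used) → PCA outlier flag → re-run of the MAF filter if
samples dropped. The outlier stage is a transparent surrogate for
clustering/eigenanalysis-based removal: samples whose score on any of the
top 10 principal components of the column-standardized genotype or
methylation matrix exceeds 6 score-SDs are flagged, and the two flags are
unioned. At the defaults this flags essentially nobody in homogeneous
synthetic data (as it should; the synthetic cohort plants no outliers).

## Numerical details

- GEE convergence 1e−8 relative on coefficients, 100 iterations max;
  variance floor 1e−10 on μ(1−μ); α clipped to its valid range
  (−1/(max nᵢ−1), 1).
- REML grid 121 points over log δ ∈ [−10, 10]; kinship eigenvalues
  clipped at 0; spectra with range below 1e−10 flagged non-identifiable.
- LD r² of a constant dosage vector is defined as 0 (cannot conflict).
- Standardization maps zero-SD columns to 0.
- All seeds derive from explicit integer seeds; the pipeline derives
  per-fold, per-model ANN seeds from (master seed, fold, model label
  CRC32), so reports are bit-identical across runs and machines.

## Problem sizes

The default test-suite and acceptance problem sizes are: 20 replicate
cohorts (~520 samples, 2,000 SNPs, 1,000 CpGs) for the stepwise pattern;
one 300-family null cohort with 5,000 SNPs and 5,000 CpGs for scan
calibration; 50 replicates of 900 samples for REML recovery; 5,000 SNPs
for GRM checks. These sizes give Monte-Carlo standard errors comfortably
inside the asserted bands while keeping a complete run in the minutes
range on a single CPU.

## Known limitations

- The GEE uses only exchangeable (and trivially independence) working
  correlations; no GLMM alternative is provided.
- The LMM treats the binary response linearly; p-values are calibrated
  (verified empirically) but effect sizes are on the probability scale.
- The sandwich covariance is first-order; with few families (< ~50) its
  small-sample anticonservatism would need a correction that is not
  implemented.
- Exact Wilcoxon enumeration is O(C(n₁+n₂, n₁)) and switches to the
  normal approximation above combined n = 20.
- No hyperparameter search for the network; width and epochs are fixed
  configuration.
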