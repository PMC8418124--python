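# Methods

This note documents the statistical machinery in `tmescore`, the defaults
it ships with, and what the synthetic benchmark does and does not
demonstrate.

## Preprocessing

Expression enters as a genes × samples matrix with a declared scale.
FPKM/linear input is renormalised per sample to TPM (columns sum to 10⁶),
log2(x+1)-transformed (pseudocount 1 by default), and — when several
cohorts/batches are present — batch-corrected on the log scale.
Quantile normalisation replaces each sample's order statistics with the
across-sample mean of order statistics; tied values receive the mean of
their tied positions' reference values so ties stay tied, which makes the
operation idempotent. Duplicate gene ids collapse to the row with the
highest mean expression (the usual probe-collapse convention); gene ids
are otherwise opaque, case-sensitive strings.

Batch correction is the parametric empirical-Bayes location/scale
adjustment: per gene, data are standardised against a batch-design fit
(optionally with protected biological covariates), per-batch means and
variances are shrunk toward priors pooled across genes (inverse-gamma for
scale, normal for location, hyperparameters by moments, coupled posterior
equations iterated to 1e-4), then the shrunk effects are removed and the
data back-transformed. A single batch is an identity. Note that shrinkage
deliberately leaves the *sampling noise* of per-gene batch means in the
data — only the systematic component is removed; with b batches of n
samples the observed per-gene batch-mean gap after correction is of order
√(2/n), which is the correct behaviour, not a residual artefact.

All stages downstream of deconvolution run on log2 TPM; deconvolution and
the CYT readout use linear TPM. This split is a package convention and is
recorded in every run log.

## Deconvolution

Each bulk sample is modelled as a non-negative mixture of reference cell
type profiles. On the genes shared with the reference, the reference
matrix is standardised *globally* (one mean/SD over all entries) and the
mixture column by its own mean/SD; global reference standardisation keeps
the regression weights proportional to the underlying fractions, which is
what makes noiseless recovery near-exact. A linear ν-SVR (C = 1) is fit
for each ν in {0.25, 0.5, 0.75}; negative coefficients are clipped and
the rest renormalised to a simplex; the ν minimising reconstruction RMSE
wins, with ties toward smaller ν. The per-sample Pearson r of the
reconstruction feeds a permutation p-value computed against a single
shared null: each of B permutations gene-permutes a randomly chosen
mixture column and records its best-fit r. Sharing one null across
samples costs B fits instead of n×B; the p-values of samples scored
against the same null are therefore correlated, which matters only when
aggregating significance across samples. Gene coverage below 50% of the
reference is an error, 50–80% a warning.

ssGSEA ranks genes within each sample (average ranks on ties) and
integrates the difference between the rank^α-weighted ECDF of set genes
(α = 0.25) and the uniform ECDF of non-set genes; scores are reported
unnormalised, with a global max−min rescaling available. Scores are
invariant under any strictly increasing per-sample transform. The
immune/stromal summary is the ssGSEA score of an immune and a stromal set
plus their per-sample sum.

## Consensus clustering

PAM is the classic BUILD (greedy seeding from the 1-medoid optimum) plus
SWAP (steepest descent over all medoid/non-medoid exchanges, applied one
best swap per pass until no swap strictly lowers cost). It is
deterministic given the input order. As a local search it occasionally
converges to a non-global optimum on small adversarial instances (we
measure ≈7% of random n ≤ 8 instances, the same optima as the canonical
implementations); it never reports a cost below the exhaustive optimum.

Consensus clustering subsamples 80% of items (without replacement) in
each of `n_resamples` runs, clusters the subsample with the base method
(PAM on Euclidean distances for samples; average-linkage hierarchical on
1 − Pearson for genes), and records co-cluster proportions among
co-sampled pairs. Final labels cluster 1 − consensus. For k selection the
empirical CDF of consensus entries is integrated per k; the first k on
the scan takes its full area and later k their relative area increment,
and the k with the largest increment wins (ties toward smaller k). With
two well-separated planted groups this selects k = 2 and reproduces the
planted partition exactly. Defaults: k scanned 2–6, 1000 resamples for
real runs (50 in the benchmark profile, which is already stable for the
planted-structure sizes used here).

## Differential expression

Two-group empirical-Bayes moderated t: per gene a pooled two-sample
variance s²_g with d = n₁+n₂−2 df; hyperparameters (d₀, s₀²) fitted by
matching moments of log s²_g (Fisher-z style: e_g = log s²_g − ψ(d/2) +
log(d/2); excess variance beyond ψ′(d/2) inverts the trigamma via Newton);
posterior variance (d₀s₀² + ds²_g)/(d₀+d); t referenced to d₀+d df. When
the excess variance is non-positive, d₀ = ∞, s₀² is the arithmetic mean of
the gene variances, every gene is fully shrunk to s₀² and the reference
becomes normal — with exactly equal gene variances this collapses to the
ordinary two-sample t. Genes constant in both groups report t = 0, p = 1.
BH adjustment is the exact step-up rule (reverse cumulative minimum of
m·p₍ⱼ₎/j). DEGs are genes with FDR < 0.01, ranked by |t|.

## Survival machinery

All survival code is implemented in-package and cross-checked in the test
suite against an independent implementation. Kaplan–Meier is the product-
limit estimator (censorings shrink the risk set without a step). The
log-rank test is the observed-minus-expected statistic with the
hypergeometric variance, generalised to g groups (df = g−1). Cox models
maximise the partial likelihood by Newton–Raphson with step-halving;
Efron's tie correction is the default (Breslow available; both coincide
without ties); convergence requires max|score| < 1e-8 within 50
iterations; a monotone likelihood is warned and the coefficient capped at
|β| = 15. The score test at β = 0 is exposed and equals the log-rank test
for a binary covariate without ties. The univariate screen z-scores each
feature so hazard ratios are per SD; features with p < 0.05 are flagged
"representative"; constant features are skipped with a flag.

The maximally selected cutpoint scans every split of a continuous score
that leaves at least `minprop` = 0.1 of samples on each side, maximising
the two-group log-rank statistic; the reported p from the χ²₁ reference
ignores the selection multiplicity (warned), and an optional permutation
p (score permuted against survival) provides the corrected version.
AUC is the Mann–Whitney concordance probability with ties counted ½.

## Signature and TME-score

SVM-RFE trains a linear soft-margin SVM (C = 1) on z-scored candidate
genes, eliminates the ⌈10%⌉ of surviving genes with the smallest squared
weights (one at a time at ≤ 20 genes), and returns the elimination order.
The signature size is the prefix of that ranking maximising stratified
5-fold CV accuracy over a 10–300 size grid, ties toward smaller — so on
cleanly separable synthetic data the selected signature is small (often
the smallest grid size); the 63-gene scale reported for real tumor
cohorts reflects harder class boundaries, not a constant of the method.

Signature genes are consensus-clustered (1 − Pearson, hierarchical base).
Each cluster's genes are z-scored over the training samples and the first
right singular vector of the samples × genes matrix gives unit-norm
loadings, sign-oriented so the PC1 sample score correlates positively
with the cluster's mean z-scored expression (removing PCA's sign
ambiguity; without it the score's sign would be arbitrary). A univariate
Cox fit of each cluster's PC1 score assigns direction *i* (HR > 1) or *j*
(HR ≤ 1, including exactly 1). The TME-score is Σᵢ PC1 − Σⱼ PC1, one PC1
per cluster by default; a flag refits one PC1 per pooled direction set
instead. If every cluster lands in one direction the other sum is empty
(warned) — the formula degrades gracefully to a one-sided sum.

Applying a model to a new cohort re-standardises genes within that cohort
before projection (appropriate for cross-platform application after batch
correction); a flag switches to the stored training standardisation. At
least 80% of signature genes must be present; missing genes' loadings are
dropped and the remaining loading vector renormalised with a warning.
Dichotomisation uses the trained cutoff by default or a cohort-specific
maximally selected cutoff on request. Models serialise to JSON and
round-trip bit-exactly.

CYT is the geometric mean of GZMA and PRF1 linear TPM with a 0.01
pseudocount; GEP is the unweighted mean log2 expression of an 18-gene
panel supplied as input (the panel's published weights are deliberately
not reproduced here; the gene list is an input file, not a bundled
asset — as is the deconvolution reference).

## Synthetic benchmark

The generator is a pure function of (config, seed). Cell-type profiles:
each of 8 types gets 40 marker genes at log2 ≈ 6 ± 0.5 in its own type
and ≈ 1 ± 0.5 elsewhere; 1680 background genes are flat across types. The
deconvolution reference exposes all markers plus an 80-gene flat panel
(real references are compact differential panels, not transcriptomes).
Two phenotypes mix cell types with mirrored geometric Dirichlet
concentrations (8 → 1 and 1 → 8 across types), giving clearly distinct
but overlapping infiltration profiles. Expression = profiles × fractions
with multiplicative log-normal noise (σ = 0.2 natural log, ≈ 20% CV),
100 planted DEGs (+2 log2 in phenotype 1, chosen among background genes
so planted truth is disjoint from mixture-driven marker DE), an additive
per-batch log2 shift (2 batches, +1), and a final TPM rescale. Survival
is exponential with hazard doubled in phenotype 1 (log HR = log 2, the
"biology" and planted set are fixed by `config.seed` while an optional
sampling seed redraws patients, enabling held-out cohorts from the same
system); censoring is uniform with its horizon calibrated by bisection to
the requested 30% fraction. Default scale: 400 samples × 2000 genes —
large enough for stable recovery, small enough for minutes-scale runs.

What passing recovery tests shows: the implementation correctly inverts
the data-generating assumptions it encodes (linear mixing, log-normal
noise, proportional hazards, two phenotypes). What it does not show:
robustness to real-tumor gene–gene correlation, platform effects beyond
additive shifts, non-proportional hazards, or reference mismatch — the
generator is deliberately free of those.

## Numerical choices and limitations

- Seeds: every stochastic stage takes an explicit seed; the pipeline
  derives stage seeds as fixed offsets from the run seed, and reruns are
  bitwise identical.
- Tie-breaks: ν-grid ties toward smaller ν; signature-size ties toward
  smaller size; delta-area ties toward smaller k; RFE weight ties resolve
  by stable sort order.
- Degenerate inputs: all-zero sample columns, constant covariates,
  constant scores, single-class labels and empty gene intersections are
  errors; zero-variance genes are dropped (PC1) or skipped (Cox screen)
  with flags.
- The Cox implementation handles the two-group and small-p regimes this
  pipeline needs; it has no time-varying covariates, stratification or
  robust variance.
- Deconvolution reports relative immune fractions (simplex rows); there
  is no absolute-abundance mode.
- The permutation null for deconvolution significance is shared across
  samples (see above); per-sample nulls would be B-fold more expensive.
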