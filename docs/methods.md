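# Methods

This note documents the statistical procedures `serialdex` implements, the
generative model behind the synthetic cohorts, the defaults and why they
were chosen, and the numerical conventions that affect results at small
sample sizes.

## Study design and data model

A serial neoadjuvant cohort consists of log2-ratio expression profiles at
up to three time points per patient — pretreatment (T1), 24–96 h after the
first chemotherapy dose (T2), and surgery (TS) — with incomplete pairing.
Clinical annotations: print batch (technical covariate), residual cancer
burden (RCB: 0, I, II, III or undetermined), hormone-receptor status, and
recurrence-free survival (time in months, event indicator).

Two derived groupings are deliberately distinct:

- **Response groups**: RCB 0/I → responder, II/III → nonresponder,
  undetermined → NA. Used by the outcome contrasts.
- **Residual disease**: RCB I/II/III. Used as the inclusion rule for every
  TS-based analysis — RCB I patients are responders under the dichotomy but
  still carry residual tumor, so they are eligible for surgical-specimen
  analyses.

Missing expression values (`NA`/empty on disk, `NaN` in memory) are
distinct from 0 and excluded, never imputed: batch means, probe averages
and per-gene test sample sizes all skip them, and each gene records the
number of complete pairs/samples it was tested on.

## Normalization

Replicate probes of a gene are collapsed by the arithmetic mean of their
non-missing values. Print-batch effects are removed per gene by fitting the
one-way linear model `x ~ batch` (categorical) and keeping the residuals;
because the design is a one-way layout this is computed in closed form as
batch-mean subtraction — exact, fast and identical to iterative least
squares. Genes observed in a single batch are mean-centered; a (gene,
batch) cell that is entirely missing stays missing. The operation is
idempotent and leaves every (gene, batch) cell with mean 0 to 1e-10. The
pipeline collapses probes before residualizing by default (a config switch
reverses the order); the two orders commute exactly because batches are
per-sample.

## Permutation differential expression

**Paired contrast** (T1 vs T2; T1 vs TS). Per gene, differences
`d_i = x_B,i − x_A,i` over patients with both time points;
`t = d̄/(s_d/√n)` with the n−1 sample standard deviation. The null flips
the sign of each `d_i` independently. If `2^n ≤ n_perm` all sign vectors
are enumerated (exhaustive flag set); otherwise `n_perm` random vectors
plus the identity are used, so the two-sided
`p = #{|t_perm| ≥ |t_obs|}/total` is never 0 and `p·total` is an integer.
Degenerate contract: all differences 0 → `t = 0, p = 1`.

**Two-group contrast** (responder vs nonresponder at T1, T2, or on the
per-patient change T2−T1). The statistic is the Welch (unequal-variance)
*t*; the source analysis states only "t-statistic", and Welch is the robust
default for groups as unbalanced as 7 vs 26. The null reassigns group
labels preserving sizes, enumerated exhaustively when `C(n, n1) ≤ n_perm`.

Defaults: `n_perm = 10 000`, explicit seed; within a cohort-level contrast
all genes with complete data share one permutation ensemble (a single
matrix multiplication per block), which leaves the per-gene p-values exact
and induces only negligible cross-gene dependence; genes with missing
entries fall back to per-gene permutation on their complete pairs.

**Multiplicity.** Time-point contrasts use Benjamini–Hochberg step-up
adjustment (via `statsmodels`) and the adjusted *p* < 0.05 rule; outcome
contrasts use the relaxed raw *p* < 0.005 **without** correction, matching
the small-sample convention of the study design. Missing p-values pass
through BH as missing and are excluded from *m*.

Note an interaction between permutation granularity and BH: with
`n_perm = 10 000` the smallest achievable raw p is ~1e-4, so on a null
cohort of *m* = 1000–2000 genes the step-up can essentially never reject
(it would need `p ≤ 0.05·k/m` at rank *k*); empirical null false-discovery
proportions in the tests are therefore ~0 rather than merely ≤ 0.05.

## Molecular subtyping

A generic nearest-centroid classifier over a user-supplied genes × subtypes
panel: each sample is assigned the subtype whose centroid maximizes the
correlation (Spearman default, Pearson selectable) over the panel genes
present and non-missing in the sample (≥ 30 by default). Full PAM50
preprocessing — reference-population gene centering, risk-of-relapse
scores — is intentionally out of scope: published centroid values and
calibration data are external inputs. Correlation ties are broken by panel
column order and flagged. Concordance between paired time points is
`100·identical/pairs` rounded to the nearest integer, **half away from
zero** — the convention forced by matching printed rates such as
24/39 = 61.5 → 62 % — plus a label→label transition table.

## Survival analysis

Per-gene Cox proportional hazards with the gene's expression (T1 or TS) or
change (TS−T1) as a continuous covariate; optional adjustment for an
hormone-receptor indicator, retained in both models of the nested
comparison. The partial likelihood uses **Breslow** tie handling (Efron
selectable) and is maximized by Newton–Raphson with step halving (≤ 100
iterations; |β| > 50 is treated as monotone likelihood and flagged
non-converged). The reported p-value is the likelihood-ratio test
`2(ℓ(β̂) − ℓ(0))` on 1 df — not Wald — applied uniformly to gene screens
and to covariates such as Ki-67 scores. Degenerate contracts: constant
covariate or no events → `β = 0, p = 1`, flagged. Screens continue past
per-gene failures and report NaN rows. Significance threshold raw
*p* < 0.005, no correction. TS/TS−T1 screens include only residual-disease
patients.

Kaplan–Meier curves and the two-group log-rank test are delegated to
`lifelines` behind small wrappers; with no censoring the product-limit
estimate equals 1 − ECDF, which the tests assert. Tertile dichotomization
for KM illustration cuts at the linear-interpolated empirical quantile
(2/3 for top-vs-rest, 1/3 for bottom-vs-rest); membership is `value ≥ cut`
(resp. `≤`), so boundary ties all fall on the extreme-group side —
deterministic, with group sizes reported, because at n ≈ 30 the tie
convention visibly changes group sizes.

The paired Wilcoxon signed-rank test drops zero differences, averages tied
ranks, and enumerates the exact sign-flip null by dynamic-programming
convolution for ≤ 20 nonzero differences (two-sided
`p = 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w))`, capped at 1); larger samples use the
normal approximation.

## Overrepresentation

Each gene set is intersected with the **universe = all features tested in
the upstream contrast** (standard microarray practice; no proprietary
background is assumed) and crossed with the significant list in a 2×2
table. The one-sided enrichment p-value is the hypergeometric upper-tail
sum (`scipy.stats.fisher_exact`, alternative "greater"); *p* < 0.05 is the
significance convention and no multiplicity correction is applied by
default (an optional BH column is provided and marked as an extension).
Symbols are upper-cased before matching across matrix, GMT and centroid
files.

## Synthetic cohort: generative model and defaults

Per patient *p* and gene *g* (log2-ratio scale):

1. subtype ~ categorical(0.35 LumA, 0.20 LumB, 0.15 Her2, 0.25 Basal,
   0.05 Normal); responder ~ Bernoulli(0.21); RCB class consistent with the
   label (responders mostly RCB 0; nonresponders II/III at 60/40); 8 % of
   patients recorded as RCB-undetermined.
2. T1: `x = 1.0·c(subtype, g) + N(0, 0.5²)`, where `c` is a 50-gene × 5
   synthetic centroid panel (N(0,1) entries) and 0 elsewhere.
3. T2 = T1 + shift, shift ~ N(μ, 0.5²) with μ = −0.5 for the 100 + 80
   planted proliferation/immune genes, and μ = −0.8 for the 80 planted
   response genes of true nonresponders (0 for responders).
4. TS (residual disease only) = T1 + N(0, 0.5²), plus a patient frailty
   `f_p ~ N(0, 3²)` added to each of the 30 planted hazard genes.
5. RFS: event time ~ Exponential with rate `0.02·exp(0.8·m_p)` per month,
   `m_p` = realized mean TS expression of the hazard genes; censoring ~
   Uniform(0, 60]; patients without residual disease are censored at 60.
6. Each sample draws one of 6 print batches; a batch × gene offset
   ~ N(0, 0.3²) is added. T2 biopsies of 25 % of patients (exactly 12 of
   48, so 36 complete T1–T2 pairs) and 10 % of TS biopsies are dropped.

Defaults mirror the serial-biopsy design the package targets: 36 T1–T2
pairs, a ≈ 7:26 responder split among evaluable pairs, six print batches,
and log2 noise scales typical of two-color arrays. All draws derive from
one seed through named `SeedSequence` sub-streams, so a fixed seed gives a
bit-identical cohort regardless of evaluation order.

**Truth accounting.** The truth set of the paired T1-vs-T2 contrast is
`t2_marginal_shift_genes` = proliferation + immune + response genes:
because the response planting moves nonresponders only and groups are
unequal, it also shifts the marginal T2−T1 mean, so response genes are
genuinely differentially expressed in the paired contrast and counting
them as false discoveries would misstate the observed FDR.

**Why frailty sd = 3.0.** The recurrence hazard is planted on the *mean*
hazard-gene expression, but recovery is assessed by per-gene Cox fits, so
each fit regresses on a noisy proxy of the planted score and the estimated
log-hazard is attenuated (classical regression dilution: the linear factor
is `(τ² + σ²/K)/(τ² + σ²)` for frailty variance τ², per-gene noise σ² ≈ 0.5
and K = 30 genes, and the Cox nonlinearity shrinks somewhat further).
The frailty scale is therefore set large enough that the shared prognostic
signal dominates per-gene noise: at τ = 3 the per-gene estimates average
≈ 0.70 against the planted 0.8, while Cox on the exact planted score
recovers 0.8 without bias (≈ 0.82, the residual being small-sample
inflation). Pushing τ higher does not reduce the gap (recovery saturates
near 0.71), so 3.0 is the documented operating point, not a fitted value.

**What the generator does not emulate** — hence what passing tests do not
show about real data: raw two-color intensity artifacts and array QC
failures; probe-level cross-hybridization (the optional probe expansion
adds only iid noise); cell-type composition drift between biopsies, which
in real serial data drives part of the T2/TS signal and causes subtype
switching (the synthetic subtype signal is stable by design, so synthetic
concordance is ~100 % and the printed-rate arithmetic is verified
separately); correlated gene modules (genes are independent given the
planted structure, making permutation-null calibration cleaner than on
real co-expressed data); and non-proportional or time-varying hazards.

## Problem sizes used in the checks

The verification suite runs on cohorts of 300–2000 genes and 48–130
patients: full-size default cohorts for planted-signal recovery (2000
genes, 36 pairs, 10 000 permutations), 20 replicate cohorts of 1000 genes
for null FDR behavior, 10 000 independent null genes of 12 pairs
(exhaustive 4096-vector null) for type-I calibration, and 20 replicate
130-patient cohorts for Cox recovery. These sizes make every check
re-runnable in seconds to minutes on one CPU while keeping the Monte-Carlo
intervals tight; they are stated here as the package's reference
configuration.

## Known limitations

- The nearest-centroid classifier is generic; results with the published
  50-gene panel depend on preprocessing (gene centering, reference
  population) that this package deliberately leaves to the user.
- Cox screens are univariate (plus at most a few adjustment covariates);
  no penalized or multivariable modeling, and no proportionality
  diagnostics.
- The two-group permutation test fixes group sizes; it does not model
  covariate imbalance between response groups.
- Batch residualization assumes additive, gene-specific batch offsets; it
  cannot correct multiplicative or intensity-dependent artifacts, which
  belong to upstream array normalization.
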