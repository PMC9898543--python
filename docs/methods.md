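# Methods

This note documents the models, defaults, and numerical choices behind
`apatwas`, and what the synthetic-data tests do and do not establish.

## PDUI quantification (apaquant)

**Model.** Each 3′UTR is assumed to carry exactly two poly(A) sites. Reads
from both isoforms cover the region upstream of the proximal site; only
long-isoform reads cover the downstream segment, so the expected per-base
depth is a step function with a single change point *P* shared across
samples. Per sample and segment, depth is modeled as normal with free mean
and variance; the joint objective is the profile log-likelihood

    sum_s [ -(n1/2) ln(RSS1_s/n1) - (n2/2) ln(RSS2_s/n2) ]

(equivalently, minimizing sum n_k ln(sigma_hat_k^2)), maximized by
exhaustive grid search. Each sample's distal usage is
`PDUI = clip(mu_dist / mu_prox, 0, 1)` — a ratio of segment means, hence
invariant to per-sample depth scaling.

**Parameters.**

- `min_seg = 100` nt: minimum segment length on either side of *P*. UTRs
  shorter than 2×`min_seg` are not fitted.
- `step = 1` nt: breakpoint grid stride. UTRs are short enough that
  exhaustive search is cheap and removes a heuristic.
- `min_mean_cov = 20` (mean depth over the region, after depth
  normalization): samples below it get missing PDUI and do not contribute
  to the fit. No threshold is canonical for this quantity; it is exposed
  as config.
- `min_sample_fraction = 0.5`: rows with more missingness are dropped.
- Objective ties break to the smallest *P* (deterministic output). A pure
  least-squares objective (`objective="least_squares"`) is available;
  the profile-likelihood form is the default because it lets each sample
  and segment carry its own variance. On noiseless segments the RSS is
  floored at 1e-12 per base before the log.

**3′UTR extraction.** From BED12 with CDS thick coordinates: the UTR is
the transcript portion downstream of the CDS restricted to the last exon
(mirrored for minus strand). Non-coding records (thickStart == thickEnd)
are skipped and counted. Coordinates follow BED conventions (0-based
half-open); VCF positions are 1-based; coverage profiles are always
transcript-oriented (position 0 = 5′ end of the UTR).

**Scope.** One proximal/distal pair per transcript; intronic APA and
de-novo site discovery are out of scope. Multiple transcripts per gene are
fitted independently and reported at transcript level.

## Phenotype preparation (phenoprep)

Fixed order: inverse-normal transform → residualize on known covariates +
genotype PCs → hidden factors on the residual matrix → residualize on the
factors.

- The transform maps ranks to Phi^-1(rank/(n+1)) with average ranks on
  ties; it is robust to the bounded [0,1] support of PDUI, where a raw
  Gaussian assumption would be strained near the boundaries.
- Genotype PCs (default 5) come from the SVD of dosages mean-imputed,
  centered, and scaled by sqrt(2f(1-f)); PC signs are fixed by the largest
  loading.
- Hidden factors are the top principal factors of the gene-standardized
  residual matrix (truncated SVD). This is a deliberately light-weight
  estimator of hidden expression confounders: it captures the same linear
  batch/technical structure a probabilistic factor model targets, without
  the variational machinery. The factor count defaults follow the common
  cohort-size ladder (n<150: 15, <250: 30, <350: 35, else 60) and are
  config-driven.
- Missing PDUI cells are mean-imputed for factor estimation only; they
  remain missing for association testing so no phenotype values are
  fabricated in inference.
- Covariates are declarative config rather than a hard-coded list, since
  which known covariates exist (sex, RIN, platform, post-mortem interval,
  ancestry PCs) varies by cohort.

## cis-aQTL mapping (aqtlmap)

- cis window: variants within 1 Mbp of the UTR (closed interval, both
  boundaries included), default `window = 1,000,000`.
- Per-pair statistics: simple OLS slope of residualized phenotype on
  dosage, two-sided t-test with n-2 df, listwise deletion of missing
  pairs; monomorphic variants are skipped and logged.
- Gene-level inference: observed statistic is the minimum nominal p across
  cis variants; 1000 permutations shuffle the residualized phenotype
  (covariates were removed once upstream, so no per-permutation refit);
  empirical p = (1 + #{perm <= obs}) / (n_perm + 1). Because nominal p is
  monotone in squared correlation at fixed n, permutation comparisons are
  done on max r^2 after column mean-imputation (the complete-data fast
  path). No beta-approximation of the permutation null is applied — the
  empirical p is reported directly, so its resolution is 1/(n_perm+1).
- FDR: Storey q-values with pi0 estimated at a single lambda = 0.5 (no
  spline smoothing — robust at the gene counts used here), or
  Benjamini-Hochberg; Storey with pi0 = 1 reduces exactly to BH.
- Enrichment diagnostics: QQ tables stratified by annotation membership
  with genomic inflation lambda = median(chi^2)/0.4549, and a 2×2 odds
  ratio on an optionally LD-pruned, MAF-bin-stratified background with a
  percentile bootstrap CI and Haldane-Anscombe correction. The output
  labels this method "simplified": it matches on MAF and prunes LD but
  does not model distance-to-gene or perform the full matched-permutation
  enrichment of dedicated tools.

## Prediction models and the TWAS scan (twas)

**cis-h².** One-component mixed model y ~ N(0, sg²·K + se²·I) with
K = XX'/m from standardized, mean-imputed cis dosages. The likelihood is
profiled over total variance and maximized over h² = sg²/(sg²+se²) on
[0, 1−1e−6] by bounded 1-D search on the spectral decomposition (computed
from the thin SVD of X, so no n×n kernel is formed). The test against
h² = 0 uses the boundary mixture 0.5·χ²₀ + 0.5·χ²₁. With the phenotype
centered and covariates already removed, the ML profile and REML coincide
up to the single mean parameter.

**Gate and training.** Genes pass only with heritability LRT p below the
gate. Both gate conventions are implemented — nominal p < 0.05 (default)
and Bonferroni-corrected p < 0.05 (`--bonferroni`) — because both appear
in common practice; the choice is recorded in the run config. Weights are
fitted on standardized genotypes by

- BLUP/ridge: w = (X'X + λI)⁻¹X'y with λ = m(1−h²)/h²,
- LASSO and Elastic Net (mixing 0.5) with penalty chosen by inner 3-fold CV
  over a fixed log-spaced grid.

Model selection uses 5-fold outer CV; CV R² is the squared correlation of
out-of-fold predictions with the phenotype, set to 0 when the correlation
is non-positive (an anti-predictive model is not skill). Ties break
BLUP > Elastic Net > LASSO, a fixed order for determinism. Genes whose best
CV R² is 0 are gated out. Folds are seeded and the seed stored in the
weight file.

**Scan.** Harmonization drops strand-ambiguous (A/T, C/G) variants,
indels, variants with reference-panel MAF ≤ 0.01, and variants absent from
the sumstats or LD reference; z is negated when the sumstats allele
orientation is swapped relative to the model. The LD matrix is shrunk,
Σ_used = (1−θ)Σ_ref + θI with θ = 0.1 by default, guaranteeing a positive
denominator with finite reference panels. The association statistic is
Z = wᵀz/√(wᵀΣw) (invariant to positive rescaling of w since weights are on
the standardized-genotype scale), p = 2Φ(−|Z|), scan-level FDR by BH
(Storey by flag). Missing-variant imputation of summary statistics is not
implemented; the scan restricts to overlapping variants and logs the
overlap. An explicit LD source is required — there is no implicit default
panel.

**Follow-up.** Conditional z-scores use c = Σw/√(wᵀΣw) and
z_cond = (z − c·Z)/√(max(1−c², 1e−6)); the epsilon floor handles variants
perfectly correlated with the predicted phenotype. The weight-permutation
test shuffles the weight-to-variant assignment (default 100,000 rounds)
with the plus-one empirical p; all-equal weights give p = 1 by construction
and are flagged.

## Colocalization (colocal)

Single-causal-variant ABFs per variant and trait, with prior effect SD
W = 0.15 for quantitative traits and 0.2 for case-control (log-odds
scale), priors p1 = p2 = 1e−4, p12 = 1e−5 — the conventional defaults, all
config. When only z and n are available, the sampling variance is
approximated by V = 1/(2nf(1−f)); beta/se input is also accepted and the
mode is recorded in output metadata. All accumulation is in log space; the
H3 cross-term (sum over ordered pairs of distinct variants) is computed as
lse1 + lse2 + log(−expm1(lse12 − lse1 − lse2)), which is stable for loci
with thousands of variants and large z. Single-variant loci set PP3 = 0 by
convention. PP4 ≥ 0.5 is the colocalization call.

## Synthetic data (simdata)

What it emulates, and the fixed study conditions used by the test suite
and `scripts/acceptance.py`:

- **Genotypes**: haplotypes walk along the chromosome carrying a latent
  uniform copied from the previous site with probability `ld_rho` and
  redrawn otherwise; thresholding at the allele frequency gives the
  allele, and haplotypes pair into diploid dosages. With equal adjacent
  frequencies the haplotype correlation is exactly `ld_rho`; with unequal
  frequencies it is the maximal (comonotone) correlation scaled by
  `ld_rho`. This is the simplest model giving tunable local LD for
  harmonization and tagging tests; it has no long-range LD, no
  recombination hotspots, and no population structure.
- **PDUI phenotypes**: baseline + sum of centered-dosage effects + Gaussian
  noise, clipped to [0,1] after noise (a usage fraction cannot leave the
  unit interval). Effect sizes are set so the causal SNP explains a chosen
  h² of phenotype variance.
- **Coverage**: two-segment expected depth (mean_depth upstream,
  mean_depth × PDUI downstream) with negative-binomial noise,
  Var = μ + dispersion·μ²; dispersion 0 returns the exact expectation
  (deterministic, not Poisson), giving machine-precision fixtures for
  breakpoint tests.
- **GWAS summary statistics**: z ~ MVN(√n·Σγ, Σ), the standard model for
  marginal association statistics. The mediated mode sets γ = α·w with w
  on the standardized-genotype scale, so the simulated trait acts on SNPs
  only through PDUI and the end-to-end positive control is internally
  consistent with the TWAS estimand.

Default conditions (chosen once as realistic for this data type): depth
50×, NB dispersion 0.05, UTR length 400–600 nt with the proximal site
mid-UTR, per-gene cis blocks of 20–30 variants with `ld_rho` 0.6–0.9,
cis-h² 0.3 for heritable genes (0.05 for the power check), reference
panels of 300–500 individuals, GWAS n = 5,000–50,000, and a mediation
coefficient α = 0.1 (the causal gene explains ~1% of trait variance
through PDUI — modest for a molecular mediator, strong enough that a
50k-sample GWAS carries the signal). The end-to-end control uses 50 genes
(one causal) × 20 replicate runs; the null calibration uses 200 genes with
1000 permutations each.

**What passing does not show.** The generator has clean two-segment
coverage (no GC or 3′ bias, no multimapping), a single causal variant per
gene, Gaussian phenotype noise, and exact allele labels. Recovery and
calibration on this structure validate the estimators and their
implementation, not robustness to alignment artifacts, annotation error,
multi-signal loci, or cross-population LD mismatch.

## Numerical and degenerate-input choices

- All randomness flows through `numpy.random.default_rng`; per-stage seeds
  derive from the master seed by CRC-32 of "seed:stage" (kept below 2³¹),
  so stages are independently reproducible and CLI reruns are
  byte-identical.
- Empirical p-values use the plus-one rule everywhere: never 0, floor
  1/(n_perm+1).
- Monomorphic dosage columns: skipped in association, zero-scored in
  standardization.
- Zero proximal mean in a passing sample: that sample's PDUI is missing.
- Rank-deficient covariate designs raise with the collinear columns named
  rather than silently dropping them.
- Chromosome-name dialects ("chr1" vs "1") are detected at ingest and
  raise an explicit error naming both dialects.

## Known limitations

- Two poly(A) sites per UTR; no intronic APA.
- Hidden-confounder estimation is the SVD factor estimator described
  above, by design; no probabilistic (variational Bayes) factor model is
  implemented.
- Enrichment is the simplified MAF/LD-matched odds ratio, not a full
  LD/distance-matched permutation framework.
- No summary-statistic imputation of missing GWAS variants.
- Single-causal-variant colocalization only (no multi-signal extension).
- Trans effects, interaction QTLs, and multi-tissue joint models are out
  of scope.
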