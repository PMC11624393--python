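# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices behind the implementation, and its known limits.

## Model

The package fits the reliability-weighted kernel regression

```
y = Xb + g + e,    g ~ N(0, K σ²g),    e ~ N(0, R⁻¹ σ²e)
```

to one phenotypic record per bull. `y` holds sire-conception-rate (SCR)
deviations on a percent scale around a zero population mean. `X` always
carries a leading intercept; optional further columns are recessive 0/1
indicators, equal to 1 only for bulls carrying two copies of a designated
recessive allele at a major-effect SNP — the coding that captures purely
nonadditive (recessive) locus effects as fixed covariates. `K = SS′/p` is
the linear kernel over the matrix `S` of centered, standardized dosages
(`s_ij = (g_ij − 2p_j)/√(2p_j(1−p_j))`, observed counted-allele frequency
`p_j`), i.e. the VanRaden additive genomic relationship matrix, which
makes the model GBLUP. In the equivalent RKHS view, the kernel
coefficients minimize `(y−Kα)′(y−Kα) + λ α′Kα` with shrinkage
`λ = σ²e/σ²g`. `R = diag(rᵢ)` holds record reliabilities, so
`var(eᵢ) = σ²e/rᵢ`: records backed by more breedings are trusted more.

### Gibbs sampler

`KernelBLUP.fit()` draws from the joint posterior of `(b, g, σ²g, σ²e)`:

* **Spectral reparameterization.** `K = U diag(d) U′` is computed once per
  fit; eigenvalues below `1e−8 · max(d)` are dropped (a column-centered
  kernel always carries one exact zero eigenvalue, since K·1 = 0). With
  `W = U diag(√d)` and `g = Wz`, the prior on z is iid `N(0, σ²g)`. This
  avoids the `K⁻¹` that the prior notation `α ~ N(0, K⁻¹σ²g)` would
  otherwise require, which does not exist for centered or rank-deficient
  kernels.
* **Diagonalized kernel update.** Because the reliabilities are fixed,
  `A = W′ₜ R Wₜ` (training rows t) is constant across sweeps; one further
  eigendecomposition `A = V Λ V′` makes the full conditional of the
  rotated coordinates `ζ = V′z` diagonal. Each sweep then costs
  O(n·m) for an n-individual, rank-m kernel, so chains of tens of
  thousands of sweeps are cheap even at n in the thousands.
* **Fixed effects** are drawn jointly from their multivariate-normal full
  conditional under a flat prior; rank deficiency of `X` is detected at
  model construction via pivoted QR, naming the collinear columns.
* **Variance components** get scaled-inverse-χ² full conditionals. Priors:
  df = 5 for both; "auto" scales put the prior mode at half the
  training-phenotype variance for each component. All configurable
  (`McmcConfig`). Defaults: 30,000 sweeps, 5,000 burn-in, thinning 5 —
  conventional settings for this model family; the package's internal
  checks use shorter chains scaled to their problem sizes.
* **Draw order** per sweep is fixed (ζ, b, σ²e, σ²g) and all randomness
  comes from one seeded generator, so every fit is exactly reproducible.
* **Masked records** (cross-validation test folds) contribute no
  likelihood; their genetic values are still drawn through the kernel —
  the missing-phenotype convention. `fixed_variances=(σ²g, σ²e)` disables
  variance sampling; `σ²g = 0` is accepted there as the degenerate
  no-signal override (g pinned at 0, b reduces to weighted least squares).

### Closed-form BLUP

`KernelBLUP.fit_blup(σ²g, σ²e)` solves the weighted mixed-model equations
in the same eigenbasis. It is the exact posterior mode/mean for known
variances, hence the oracle for the sampler: with variances fixed at
truth the two agree to Monte-Carlo error (checked in the test suite at
correlation > 0.999). Masked individuals are predicted through the kernel
cross-block, equivalently `K_test,train K⁺_train,train g_train` on the
retained eigenspace.

## Genotype QC

Filters and defaults: individual call rate ≥ 0.95 first (so SNP
statistics reflect retained animals), then SNP-level removals in order —
monomorphic, minor-allele frequency strictly below 0.01 (MAF = 0.01
exactly is kept), call rate below 0.99. Each removed item is listed once
under its first failing rule, making the report lists disjoint and the
filter idempotent. Missing dosages are mean-imputed (standardized value
exactly 0) when building `S`; the intended use case is a densely imputed
panel where missingness is rare, and mean imputation is the neutral
choice there.

The recessive allele of a major marker defaults to the cohort-minor
allele (deleterious recessives are typically rare); `code_recessive`
accepts a per-SNP override when the recessive allele is known. Major
markers stay in the kernel as well as appearing as fixed effects;
`exclude_majors_from_kernel` removes them from `K` if desired.

## Cross-validation

`cross_validate` runs k-fold CV (default k = 5) with r repetitions
(default 10). Within a repetition both model variants see identical
folds, so the Polygenic vs Polygenic+MajorMarkers comparison is paired.
Metrics — Pearson correlation and MSEP between observed records and
pooled out-of-fold predictions — are computed once per repetition over
the pooled predictions (one value per repetition, matching how repeated
CV is conventionally summarized), and are unweighted by default
(`weighted_metrics=True` reweights by reliability). If a training fold
contains no recessive homozygote for a major SNP, that inestimable
column is dropped for the fold with a warning.

## Recessive genome scan

`scan_recessive` is a deliberately simplified marginal scan: per SNP, a
weighted least-squares contrast of the recessive-homozygote group mean
against everyone else (weights = reliabilities), with a two-sided t-test
and a Bonferroni threshold over tested SNPs. SNPs with fewer than 5
recessive homozygotes (configurable) are skipped with a reason. It does
not adjust for polygenic background, so on strongly structured cohorts
its p-values are anticonservative; its role here is locus rediscovery in
unstructured synthetic cohorts, where its type-I rate is calibrated (the
acceptance suite checks this). `manhattan_table` emits the plotting
coordinates; the package draws no figures itself.

## Synthetic-data generator

`SimConfig`/`simulate_population` emulate a progeny-tested dairy-bull
cohort:

* genotypes in Hardy–Weinberg proportions, counted-allele frequency
  uniform on `maf_range` (default 0.05–0.5), assigned round-robin to 29
  autosomes; optional uniform missingness;
* polygenic values `u = Sβ`, β iid normal, rescaled so var(u) equals
  `h² · phenotypic_var` exactly (infinitesimal model on standardized
  dosages, matching the linear-kernel/GBLUP equivalence);
* major loci: purely recessive — only two copies of the recessive allele
  add the configured deviation (defaults: two loci, −8 SCR points,
  recessive-allele frequencies 0.29 and 0.31);
* records: breedings uniform on 50–8,110; reliability `r = n/(n + k)`
  with k = 200 — the phenotype source never defines reliability
  numerically, so this standard repeatability-style mapping (monotone in
  breedings, bounded in (0,1)) is adopted; residuals `N(0, σ²e/rᵢ)`;
* the finished phenotype is centered to mean exactly 0.

Defaults: 1,102 bulls (the cohort scale this workflow targets), 5,000
SNPs (a desk-scale panel — nothing downstream depends on panel size
beyond kernel averaging), h² = 0.35, `phenotypic_var = 25` (SD 5%, which
makes cohort-scale phenotypes span roughly −22 to +10). With h² = 1 the
residual variance is simply zero. Internal checks and the acceptance
study run at 500 bulls × 2,000 SNPs with chains of 3,000–8,000 sweeps —
sizes chosen so the full statistical structure (planted-locus recovery,
variance-component recovery, paired CV gain) is measurable while the
whole suite stays desk-scale.

**What the generator does not emulate:** linkage disequilibrium (SNPs are
independent, so the planted "markers" are the causal loci themselves,
whereas real major markers merely tag causal variants), pedigree and
population structure, selection, genotyping/imputation error, and the
upstream national-evaluation machinery that produces real SCR records.
Passing tests therefore demonstrate the estimator's correctness under its
own assumptions, not field performance on structured cattle populations;
in particular, predictive correlations on synthetic cohorts need not
match real-data values.

## Numerical choices and degenerate inputs

* Kernel symmetry is enforced by construction; PSD is required up to
  −1e−6·λmax at fit time, and eigenvalues ≤ 1e−8·λmax are truncated.
* Standardization refuses monomorphic columns by name (divide-by-zero
  guard); QC must run first. All-heterozygous columns (frequency 0.5) are
  valid and standardize to zero.
* Constant prediction vectors make the Pearson correlation undefined:
  this raises (or, inside CV repetitions, records NaN with a warning) —
  never a silent 0.
* Scan p-values are floored at the smallest positive double so −log10 p
  is always finite.
* Fold assignment is simple randomization (unstratified), balanced to
  within one individual.
* Seeds: simulation splits one seed into independent genotype and
  phenotype streams; CV derives per-repetition fold seeds and per-fit
  chain seeds from a single root seed, so entire CV runs are bit
  reproducible.

## Limitations

Single kernel only (no Gaussian/multi-kernel averaging), no REML
alternative to the sampler, no marker-effect (BayesA/B/C) models, no
pedigree relationships, no mixed-model (GRM-adjusted) association scan,
and no genotype imputation. Whether real large-effect fertility markers
should also be excluded from the kernel when fitted as fixed effects is
left to the user (`exclude_majors_from_kernel`); both behaviors are
supported and the default keeps them in.
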