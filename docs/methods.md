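# Methods

This note documents the statistical procedures implemented in `vqtlscan`,
the assumptions behind them, the defaults and why they were chosen, what the
synthetic-cohort generator does and does not emulate, and the package's
known limitations.

## The variance-QTL model

A variance QTL (vQTL) is a marker at which the conditional variance of a
quantitative trait differs across genotype classes. The canonical generative
explanations, all of which the package can both inject (simulator) and probe
(mechanism battery), are:

- **gene × covariate interaction**: y = β₁g + β₂ g·E + ε gives
  Var(y|g) = σ² + (β₂g)² Var(E) — variance grows quadratically in genotype
  even when β₁ = 0;
- **gene × gene interaction**: the same with a second marker's genotype in
  place of E; if one side is a vQTL the partner must be too;
- **locus-specific ancestry** in an admixed cohort: when the local ancestry
  dose at a locus modulates residual scale, genotype classes (whose
  composition differs by ancestry) inherit unequal variances;
- **multiple causal haplotypes**: heterogeneous mean effects hidden within
  one genotype class inflate its variance.

## Stage 1 — quality control

Defaults follow common practice for array-genotyped, imputation-augmented
data: individual call rate ≥ 0.90 (applied first, so site statistics use
retained individuals), marker call rate ≥ 0.95, exact-test HWE p ≥ 1e-10
(an extreme threshold: the scan *probes* mild HWE departure later, QC only
removes gross genotyping failure), imputation r² ≥ 0.3, MAF ≥ 0.005, and
removal of monomorphic and strand-ambiguous (A/T, C/G) markers. Each removed
site is logged with the first rule it failed, in that order. Site identity
is always the full (chrom, pos, ref, alt) tuple; merging cohorts intersects
sites and harmonizes swapped ref/alt by flipping dosages to 2−d. The HWE
filter uses the same exact test as the mechanism probe (one implementation
everywhere) on most-probable genotypes from all individuals; restricting to
founders would be marginally cleaner for family data but the filter
threshold is so extreme that the distinction is immaterial.

## Stage 2 — mixed-model residualization

The trait is residualized on fixed covariates (age, sex, study/array
dummies, top GRM eigenvectors; 1 PC for a discovery-like cohort, 2 for a
replication-like cohort by default) and a polygenic random effect with
covariance σ²_g G:

- **GRM**: centred-and-standardized dosage cross-products over post-QC
  markers with MAF ≥ 0.01 (rarer markers destabilize the 1/(2p(1−p))
  weights and the leading eigenvectors); missing genotypes are excluded
  pairwise.
- **REML**: one eigendecomposition G = UDU′ diagonalizes the covariance for
  every variance ratio δ = σ²_g/σ²_e; the profile restricted likelihood
  (with β and σ²_e profiled out analytically) is maximized over log₁₀δ on a
  41-point grid spanning [−6, 6] followed by bounded Brent refinement to
  1e-8, with an explicit comparison against the δ = 0 boundary. Negative
  GRM eigenvalues (possible with pairwise-complete missingness) are clipped
  at zero with a warning.
- **Residual type**: *conditional* residuals y − Xβ̂ − ĝ (BLUP removed) are
  the default and are what the scan consumes. The rank test downstream
  assumes observations are exchangeable within genotype groups; removing
  the family/polygenic effect is what makes that approximately true in
  related samples. Marginal residuals (y − Xβ̂) are available behind
  `residual_type="marginal"` since the design choice is genuinely open —
  with an essentially unstructured GRM the two coincide.

The estimator is exposed sklearn-style (`LinearMixedModel().fit(X, y,
grm=...)` with `sigma2_g_`, `heritability_`, `residuals_` attributes), so it
composes with sklearn tooling; `fit_lmm` is the functional wrapper.

## Stage 3 — the variance scan

Imputed dosages collapse to most-probable genotypes (nearest integer, ties
at .5 rounding up). Genotype classes smaller than `min_class_count`
(default 2) are dropped before testing and logged: the variance of a
handful of rare homozygotes is unestimable and can dominate the statistic —
the motivating cautionary case is a genome-wide-significant rare-variant
signal that collapses by eight orders of magnitude when four minor-allele
homozygotes are excluded.

The Fligner–Killeen test uses median centring, joint mid-ranks of the
absolute deviations, normal scores Φ⁻¹(½ + r/(2(N+1))), and the sample
variance (divisor N−1) of all scores — matching the standard R
implementation exactly; p is the upper chi-square tail on k−1 df (the
statistic is inherently one-tailed). Alongside the variance p the scan
records the additive-model p (OLS of residual on dosage — the minimal
consistent choice for a mean-effect reference), the exact HWE p, MAF, class
counts, and r²_adj computed from the FK p at that marker's complete-case n.

**Variance explained.** A two-sided p maps to t on n−2 df, r = t/√(t²+n−2),
and the small-sample adjustment r²_adj = r² − (1−r²)/(n−2). r²_adj is
negative when p is near 1 (floor −1/(n−2) at p = 1): the adjustment
subtracts the chance-association expectation.

**Loci and replication.** Greedy clumping: the most significant unassigned
marker below 5e-8 (the conventional genome-wide threshold) leads a locus;
unassigned significant markers within 1 Mb with squared dosage correlation
≥ 0.2 join it. Clumping is distance+LD based, not chromosome based — one
chromosome can host several loci. A marker replicates at uncorrected
per-marker p < 0.05 in the replication cohort (matched on full site id);
a locus replicates if any member does. These defaults reproduce the
published six-of-fifteen marker / three-of-eight locus replication outcome
from the printed summary statistics.

**Test validity.** `validate_test` measures size/power by two-group
simulation from a configurable distribution menu (normal, scaled normal,
Student-t, lognormal, chi-square), reporting the rejection rate with each
distribution's skewness and excess kurtosis — the axis along which the
test's size degrades. The acceptance suite runs the null design at
1,000 observations per group × 1,000 replicates (scaled down from the
original 100,000 × 10,000 design; the binomial envelope it checks is the
same) and the suite documents, without pinning a number, that equal-variance
lognormal-vs-normal comparisons inflate size above nominal.

## Stage 4 — mechanism probes

- **HWE exact test**: conditional on allele counts, summing probabilities of
  heterozygote counts no more probable than observed; computed by the
  mode-anchored two-step recurrence (numerically exact and overflow-safe to
  at least the tens of thousands of genotypes used here). Verified against
  direct log-factorial enumeration for every total ≤ 200 and exact rational
  enumeration on spot cases.
- **Haplotype tests**: two-group test on the dose of the second-most-frequent
  haplotype (mirroring a biallelic genotype test); all-group test on
  unordered diplotypes with haplotypes rarer than 1% pooled; difference
  test as the upper chi-square tail of (stat_all − stat_two) on
  (df_all − df_two) df. The nested chi-square difference is an
  interpretation — no published construction exists for this comparison —
  and is flagged as such; with only two segregating haplotypes it
  degenerates correctly to p = 1.
- **Ancestry probes**: FK of residuals across local-ancestry strata (0/1/2
  chromosomes from the minority background), the genotype test repeated
  within the stratum homozygous for the majority background, and the
  admixture **signal fraction** 1 − r²_adj(stratified)/r²_adj(full),
  reported raw and clipped to [0, 1]. The variance (FK) test is treated as
  primary for the ancestry association since the quantity of interest is
  variance by ancestry; signal fractions from different probes come from
  separate comparisons and are deliberately *not* summed or normalized.
  Per-background allele frequencies (for Hudson F_ST, numerator
  (p₁−p₂)² minus finite-sample corrections, denominator p₁(1−p₂)+p₂(1−p₁))
  come from haplotypes labelled by local ancestry, not external panels.
- **Interaction probes**: OLS y ~ g₁ + x₂ + g₁x₂ with a t-test on the
  product; the partial r²_adj of the interaction term (from its t at the
  residual df) divided by a vQTL's own r²_adj gives the interaction signal
  fraction. Gene×sex and gene×study use the nested-model F-test with
  dummy-coded strata.
- **Parental-ancestry check**: per-individual genome-wide proportion of
  markers homozygous for the majority background, inverse-normal transformed
  (Blom offset 3/8, average ranks on ties) alongside the residuals, compared
  by Wilcoxon signed-rank on the paired differences. Because both vectors
  are forced to the same marginal before pairing, the differences are
  near-symmetric under independence *and* under monotone dependence: the
  probe is intrinsically conservative, acts only as a guard against gross
  asymmetric rank discrepancies, and returns a flagged NaN when the
  relationship is exactly monotone (all differences tied at zero). Its
  p-values are not uniform under the null and should not be read as a
  calibrated association test.

## The synthetic-cohort generator

Emulates a two-way admixed study population: individual global ancestry
α ~ Beta(0.8c, 0.2c) with concentration c = 10 (mean 0.8 matching the
typical African-ancestry fraction of African Americans; the spread,
sd ≈ 0.12, is a free choice in a realistic range since the generative
ancestry distribution of real cohorts is summarized only by its mean);
per-haplotype ancestry tracts follow a two-state Markov chain along the
marker index with switch scale 0.01 per inter-marker step and stationary
mass α on the majority background; alleles draw from background-specific
frequencies (uniform on (0.05, 0.95) unless supplied); sib pairs inherit
one whole parental haplotype per parent; covariates comprise age, sex,
eight contiguous study blocks with Normal(0, 0.5) intercepts, and a
standardized continuous exposure E (blood-pressure-like). Phenotypes are
injected separately (defaults: age 0.02/yr, sex 0.5, E 0.3, unit noise)
with any combination of gxe/gxg/ancestry_scale/none mechanisms;
`ancestry_scale` multiplies residual sd by ratio^(copies of minority
background), giving a constant sd ratio between successive strata.

**Not emulated** — and therefore not demonstrated by passing tests:
realistic LD beyond tract structure (no recombination map, no coalescent),
within-chromosome transmission recombination for sibs, three-way admixture,
genotyping/imputation error (simulated r² is 1), missing data patterns, and
phenotype skew/kurtosis beyond what the mechanisms induce (real BMI-like
traits are right-skewed, which the test-validity machinery exists to
quantify). Tract truth stands in for ancestry *inference*; real local
ancestry calls carry error that the probes here would inherit.

## Numerical and interface choices

- Determinism: every stochastic routine takes an explicit seed
  (`numpy.random.default_rng`); pipeline outputs carry a config-hash + seed
  header line, and serialized cohorts round-trip bit-exactly (phenotype TSVs
  are written at %.17g and re-read with round-trip float parsing) so
  re-running a stage from its files reproduces in-memory results.
- FK degenerate inputs: fewer than two usable groups yields a flagged
  undefined result (NaN statistic), never an exception; all-tied scores
  yield statistic 0, p 1.
- Eigenvector sign convention: largest-magnitude loading positive, for
  reproducible PCs.
- The chi-square null of the FK statistic is asymptotic: at very small
  N (≲ 20) it tracks the permutation null to ~0.02 on balanced groups but
  can deviate by > 0.05 for strongly unbalanced tiny groups — precisely the
  configurations `min_class_count` dropping avoids.
- Problem sizes in the test and acceptance suites (e.g. 1,000×1,000 null
  replicates, n = 2,000 heritability recovery over 20 replicates,
  n = 5,000 scan-ranking over 20 replicates, HWE sweep to totals of 200)
  are the package's chosen simulation scales: large enough for the stated
  tolerances' Monte Carlo error, small enough to run routinely.

## Known limitations

- Single random effect; no non-Gaussian links, no leave-one-chromosome-out
  GRM, no meta-analysis across cohorts (merge-then-scan only).
- The additive-model p is an OLS on residuals, not a joint mixed-model
  refit.
- The haplotype difference test's chi-square reference distribution for a
  difference of non-independent statistics is approximate.
- Ancestry probes assume truth-quality local-ancestry calls.
- The parental-ancestry Wilcoxon check is conservative by construction (see
  above); a null result from it is weak evidence.
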