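# Methods

## The analysis model

The package compares the burden of reported disease risk alleles between two
populations (labelled `afr` and `eur` by default, but any pair of labels
works). The data model is a curated catalog: one row per SNP with a risk
allele, an odds ratio from an association study, and per-database
risk-allele frequency observations for each population. The analysis makes
three substantive assumptions:

1. **Pooling.** Database frequency reports for the same SNP and population
   estimate one underlying frequency; they are pooled by an
   allele-count-weighted mean (weights 2n for n individuals), which is the
   maximum-likelihood combination under binomial sampling. An unweighted
   mean is available (`pooling="unweighted"`) because the appropriate
   weighting of heterogeneous databases is debatable; the weighted form is
   the default.
2. **Attributable-risk weighting.** The weighted frequency
   F_w = F · OR / OR_max rescales each SNP by its odds ratio relative to the
   strongest variant in the catalog. OR_max is computed once on the full
   harmonized catalog and held fixed across sensitivity subsets (default)
   so F_w values remain comparable between runs; `recompute_or_max=True`
   recomputes it per subset.
3. **Unit independence.** The t-test and regression treat per-SNP (or
   per-collapsed-unit) frequencies as independent observations. LD
   collapsing exists precisely to reduce the double counting this
   assumption would otherwise suffer from.

## Inference

**Mean comparison.** One-tailed t-test, direction chosen by the disease
hypothesis. The per-SNP pairing of the two frequency vectors makes the
paired variant the natural default; pooled-variance Student and Welch
variants are provided because the analysis is sometimes run unpaired. With
zero-variance differences the statistic is undefined and a
`DegenerateDataError` is raised rather than returning an arbitrary value.

**Regression.** Deming errors-in-variables regression of the comparison
population's frequencies on the reference population's. The error-variance
ratio λ is defined as var(x-error)/var(y-error): λ = 1 (the default, and
the only value the headline analysis uses) gives orthogonal regression;
λ → 0 recovers ordinary least squares of y on x. The slope is the closed
form

    β = [λ s_yy − s_xx + √((λ s_yy − s_xx)² + 4 λ s_xy²)] / (2 λ s_xy),

with the s terms (co)variances about the means; the intercept passes
through the centroid. When s_xy = 0 exactly, the slope falls back to
√(s_yy/(λ s_xx)), positive by convention. The slope standard error is a
delete-one jackknife, SE² = ((n−1)/n) Σ(b_i − b̄)², standard practice for
Deming fits without a closed-form variance; slope-vs-reference tests use a
t distribution with n − 2 degrees of freedom and are two-sided (the
identity-line comparison has no privileged direction), while the mean
comparison is one-tailed by design.

## LD collapsing

Same-chromosome pairs with r² strictly above the threshold (default 0.8)
form edges; groups are graph connected components rather than cliques,
because pairwise LD reports do not guarantee clique structure. A group
collapses to one unit — per-population frequency = unweighted mean of
member pooled frequencies, unit OR = max of member ORs (`or_rule="mean"`
selectable) — unless an exclusion rule fires: (1) members annotated to two
or more distinct genes, (2) any member in a functional region, (3)
opposite signs of the between-population frequency difference among
members (a zero difference is compatible with either sign). Rules are
evaluated in that fixed order purely so the recorded reason is
deterministic. The `ignore_locations` mode disables rules 1–2, leaving
only the direction rule, for the location-blind variant of the analysis.
Kept-separate members continue to contribute individually.

## Synthetic data generator

`SyntheticConfig` defaults describe a prostate-scale study: 226 SNPs, base
frequencies Uniform(0.05, 0.95) clipped to [0.01, 0.99], a configurable
mean shift δ between populations plus per-SNP Normal(0, 0.02) heterogeneity
(without which a constant shift would make the paired test degenerate),
lognormal odds ratios (log-mean log 1.15, log-sd 0.15) floored at 1, and
per-database binomial sampling with 661 / 50,000 / 8,000 individuals for
the 1000G-, ALFA- and gnomAD-like sources, reflecting their real scale
ordering. LD groups share one latent frequency and declare r² values in
(0.85, 0.99); r² is asserted, not derived from genotypes.

The generator reproduces the statistical structure the estimators assume —
binomial sampling noise, OR heterogeneity, LD blocks — but not features of
real catalogs such as ascertainment toward European-discovery GWAS,
correlated errors between databases (which share source cohorts),
frequency-dependent OR distributions, or realistic per-chromosome SNP
clustering. Calibration results on synthetic data therefore validate the
estimators under the stated model, not the biases of any real catalog.

Replicate r of a run with root seed s uses
`numpy.random.SeedSequence(s, spawn_key=(r,))`, so each replicate is
independently reproducible.

## Numerical choices and problem sizes

* Frequencies are proportions throughout; output tables round to 6 decimals.
* The t-test and Deming slope are exact closed forms; the only iterative
  numerics live in test oracles (bounded 1-D search for the perpendicular
  least-squares slope).
* Monte-Carlo studies use 1,000 replicates for type-I error and 500 for
  power, shift recovery and null-slope recovery, at 226 SNPs per
  replicate — large enough that binomial/Monte-Carlo error is well inside
  each check's band, and each study runs in seconds.
* Degenerate inputs fail loudly: zero-variance samples, all-equal x,
  undecided LD groups, OR > OR_max, empty observation lists.

## Known limitations

* The tool ships no genome annotation: cytoband-based removal matches the
  catalog's own `cytoband` column by prefix; position-interval removal
  requires user-supplied coordinates.
* No meta-analytic OR pooling, no confidence intervals on F, no multiple
  -testing correction across sensitivity runs, and no r² computation from
  genotype data.
* Duplicate rsIDs are a hard error; deciding which of two conflicting
  literature reports to keep is curation, not computation.
* The jackknife slope SE is an approximation; it tracks a parametric
  bootstrap within ~25% at n = 10 and tightens with n, which is adequate
  for catalog-scale n (≥ 79) but conservative inference at very small n
  should use the bootstrap directly.
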