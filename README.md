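# riskallele

Cross-population comparison of disease risk-allele frequencies.

Cancers such as prostate and testicular cancer show striking incidence
differences between men of African and European ancestry. One testable
genetic hypothesis is that the populations differ systematically in how
often they carry the risk alleles reported by association studies. Given a
curated catalog of risk SNPs — each with a risk allele, an odds ratio, and
allele-frequency observations from several reference databases (1000
Genomes, ALFA, gnomAD) — this package asks whether one population's mean
risk-allele frequency exceeds the other's, and whether the per-SNP
frequency scatter deviates from the identity line.

## Method

For SNP *i* with database frequencies *f_d* reported from *n_d* individuals,
the pooled frequency is the allele-count-weighted mean

    F_i = Σ_d (2 n_d) f_d / Σ_d (2 n_d),

and the OR-weighted frequency, reflecting relative attributable risk, is

    F_w,i = F_i · OR_i / OR_max,

where OR_max is the largest odds ratio in the catalog (catalogs are first
harmonized so every OR ≥ 1, flipping alleles and frequencies where needed).

Two procedures compare populations A and B:

* **One-tailed t-test** on the per-SNP frequency vectors (paired by SNP by
  default; pooled-variance Student and Welch variants available), since
  each disease hypothesis has a single direction of interest.
* **Deming errors-in-variables regression** of F(A) on F(B), which treats
  both axes as noisy. With error-variance ratio λ (default 1, orthogonal
  regression) the slope is

      β = [λ s_yy − s_xx + √((λ s_yy − s_xx)² + 4 λ s_xy²)] / (2 λ s_xy),

  the line passes through the centroid, the slope SE is a delete-one
  jackknife, and the fitted slope is tested against the identity slope 1
  with a t reference distribution on n − 2 degrees of freedom.

SNPs on the same chromosome linked at r² > 0.8 are collapsed to one
frequency-averaged unit unless they lie in different coding genes, sit in a
functional region, or show opposite-direction frequency differences.
Sensitivity re-analyses (locus removal by cytoband or position, named-SNP
removal, LD-collapsed variants) re-run the whole inference stage. A
synthetic catalog generator with known latent structure supports type-I
error, power, and parameter-recovery calibration without any downloads.

## Worked example

```python
import riskallele as ra

cfg = ra.SyntheticConfig(n_snps=226, delta=0.03, seed=1)   # A is shifted +3%
catalog, ld_pairs, truth = ra.simulate_catalog(cfg)
model = ra.DisparityModel(catalog, ld_pairs, pop_a="afr", pop_b="eur")
print(model.fit(use_weighted=True, variant="paired").summary())
```

```
Risk-allele frequency disparity analysis
========================================================
Dataset:            synthetic
Analysis units:     226   (OR_max = 1.732)
LD mode:            off
Frequency compared: weighted (F_w)
--------------------------------------------------------
mean[afr]          0.3628
mean[eur]          0.3437
t (paired, one-tailed greater)   t = 22.3448, df = 225.0, p = 2.425e-59
--------------------------------------------------------
Deming (afr on eur, lambda = 1)
  slope     1.0101  (SE 0.0053)
  intercept 0.0235
  H0 slope = 1:  p = 0.05896
  H0 slope = 0:  p = 1.229e-249
========================================================
```

The mean weighted frequency is about 1.9 points higher in the shifted
population, the paired one-tailed test detects the shift decisively, and the
Deming slope stays near 1 because a constant shift moves the intercept, not
the slope. Sensitivity suites run off the same model:

```python
specs = [
    ra.SensitivitySpec("primary"),
    ra.SensitivitySpec("no_8q24", removal="by_region", region=ra.Region(cytoband="8q24")),
    ra.SensitivitySpec("ld_collapsed", ld_mode="full_rules"),
]
table = model.run_sensitivity(specs)   # one row per spec
```

A `riskallele` console script exposes the same stages
(`simulate`, `collapse-ld`, `compare`, `regress`, `sensitivity`, `power`);
real catalogs are read from a tab-separated dialect documented in
`riskallele.catalog`.

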