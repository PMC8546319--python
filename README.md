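# pcssreg

Covariate-adjusted linear models for **products** of phenotypes — including
ratios (via reciprocals) and logical **AND**/**OR** combinations of binary
phenotypes — computed from **pre-computed summary statistics (PCSS)** alone:
per-variable means, the joint variance–covariance matrix, the sample size,
and an assumed marginal law per predictor. No individual participant data
(IPD) is required.

Given exact moments of any response, the OLS fit is reconstructed exactly
(`X'X`, `X'w`, and `w'w` are algebraic functions of means and covariances).
For a product `w = y1·y2···ym` the response moments are not published, so the
package approximates them: conditional means from implied simple
regressions, conditional correlations from partial correlations, and
expectations over each predictor's assumed law (exact sums for genotype and
Bernoulli predictors, Gauss–Hermite quadrature for Gaussian ones). Products
of three or more phenotypes are handled recursively over all `m!/2`
multiplication orders (unique up to the first two factors), taking the
median of each moment summary across orders. Binary phenotypes use clamped
conditional means, Bernoulli conditional variances, and the Bernoulli
product-variance formula; OR combinations are reduced to products through
complements (`y1 ∨ y2 = 1 − (1−y1)(1−y2)`).

## Layout

| module | contents |
| --- | --- |
| `pcssreg.pcss_model` | `PcssSet`, variable metadata, marginal-law descriptors, exact OLS reconstruction (`ols_from_pcss`) |
| `pcssreg.product_moments` | product mean/variance/covariance approximations for a pair of phenotypes |
| `pcssreg.combine` | recursion across `m` phenotypes, permutation-median aggregation, AND/OR via complements |
| `pcssreg.pcss_derive` | filling missing PCSS from GWAS-repository quantities (HWE moments, slope→covariance, Z-statistic correlation) |
| `pcssreg.synthetic` | IPD generators, exact-PCSS extraction, IPD fitting oracles, Type-I-error and factorial comparison studies |
| `pcssreg.fileio`, `pcssreg.cli` | TSV ingestion/emission and the `pcssreg` command-line tool |

## CLI

Summary statistics live in two TSV files: a *means* file
(`variable role vtype mean dist_kind dist_params`, with a `# n=<int>` header
line) and a square *covariance* file. See `pcssreg.fileio`.

```bash
# fit a product model from summary statistics
pcssreg product --means means.tsv --cov cov.tsv \
    --pheno 'y1*y2' --design intercept,snp --out fit.tsv

# logical combinations of binary phenotypes
pcssreg and --means means.tsv --cov cov.tsv --pheno 'y1&y2' \
    --design intercept,snp --out and.tsv
pcssreg or  --means means.tsv --cov cov.tsv --pheno 'y1|y2' \
    --design intercept,snp --out or.tsv

# per-marker scan from a GWAS summary table (snp, maf, n, <pheno>_beta, ...)
pcssreg scan --means means.tsv --cov cov.tsv --markers markers.tsv \
    --pheno 'y1*y2' --design intercept,snp --alpha 0.05 --out scan.tsv

# simulation studies
pcssreg simulate-type1 --m 2 --phenotype-type continuous \
    --replicates 50000 --seed 1 --out type1.tsv
pcssreg simulate-compare --m 2 --reps-per-cell 1000 --seed 1 --out compare.tsv
```

Every command writes a `.meta.yaml` file next to its output capturing the
configuration and seed, so runs are reproducible.

## Notes

* Covariances are stored with the sample (`n − 1`) denominator throughout.
* Each predictor's assumed marginal law should be parameterised
  consistently with its stored mean (e.g. a genotype's HWE law from the
  published MAF); a mismatch degrades the covariance approximation.
* Linear models are used for binary responses (with a logistic IPD oracle
  available for comparison in the simulation harness); logistic regression
  *from summary statistics* is out of scope, as are score-test-based
  summary statistics and family/cluster adjustment.
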