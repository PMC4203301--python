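# hfcsurv

Heterozygosity–fitness correlation (HFC) analysis toolkit for
capture–mark–recapture study systems: microsatellite diversity measures,
pedigree inbreeding, identity-disequilibrium statistics, Cormack–Jolly–Seber
(CJS) survival modelling with quasi-likelihood multimodel inference, and a
synthetic population generator with known ground truth.

## Components

| module | what it does |
|---|---|
| `hfcsurv.genotypes` | GENEPOP / long-CSV genotype IO, allele frequencies, per-locus summaries, and the SH / HL / IR multilocus heterozygosity measures plus a paternal rare-allele score |
| `hfcsurv.pedigree` | recursive memoized kinship, inbreeding coefficients *f*, dataset-restriction rules (both parents / ≥1 grandparent / all 4 grandparents), inbred classification (*f* ≥ 0.125) |
| `hfcsurv.identity` | identity disequilibrium: multilocus g2 (bootstrap SE, permutation p), heterozygosity–heterozygosity correlations over random panel halves, expected vs observed r(SH, f) |
| `hfcsurv.cjs` | MARK-style model notation (`"Phi(a2-t/sex) p(t)"`), vectorized CJS likelihood with analytic gradients, covariate standardization (2-SD convention), bootstrap goodness-of-fit ĉ, QAICc |
| `hfcsurv.mmi` | Δ / Akaike weights / evidence ratios, zero- and natural-method model averaging with unconditional SEs, relative importance, VIF collinearity screening, single-locus vs multilocus comparison |
| `hfcsurv.simulate` | group-structured multi-cohort populations: Dirichlet allele frequencies, Mendelian transmission, configurable incest rate, genotyping error (allelic dropout / false alleles / completeness), covariate-dependent survival, detection |
| `hfcsurv.pipeline` / `hfcsurv.cli` | staged reduced-model search and the full end-to-end analysis with CSV reports and a JSON run manifest |

## CLI

```sh
# generate an analysis-ready fixture directory with known truth
hfcsurv simulate --scenario paternal_x_rain --seed 1 --out fixture/

# per-individual heterozygosity profiles and marker summary
hfcsurv het fixture/genotypes.gen --out het_out/

# pedigree inbreeding with restriction levels
hfcsurv ped fixture/pedigree.csv --level ge1_grandparent --out inbreeding.csv

# identity disequilibrium (g2, HHC)
hfcsurv idiseq fixture/genotypes.gen --n-iter 1000 --seed 1 --out id.json

# fit one CJS model
hfcsurv cjs fixture/captures.csv --model "Phi(a2-t/sex) p(t)" \
    --year-covariates fixture/year_covariates.csv

# staged reduced-model search (age -> sex -> cohort -> population size)
hfcsurv reduce fixture/captures.csv --year-covariates fixture/year_covariates.csv

# full analysis (profiles, inbreeding, g2/HHC, covariate model sets,
# model averaging, local-vs-general comparison, manifest)
hfcsurv hfc fixture/ --seed 1 --out hfc_out/
hfcsurv report hfc_out/
```

An optional `--config` file for `hfc` is a flat `key = value` text file
(e.g. `c_hat = 1.03`, `seed = 7`) overriding the command options.

## Conventions worth knowing

* Deviance is −2 log L (saturated term 0); bootstrap ĉ uses the
  goodness-of-fit deviance relative to a saturated release-cohort
  multinomial, and ĉ < 1 is truncated to 1 for QAICc.
* Continuous predictors are standardized to mean 0, SD 0.5
  (divide by 2 SD); binary sex is coded −0.5/+0.5.
* Effective sample size for QAICc is the number of release events.
* Missing genotype calls are first-class throughout: untyped loci never
  enter any heterozygosity measure, and covariate imputation (column
  means) is explicit and mask-reporting.
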