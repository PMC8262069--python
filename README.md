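# epiblup

Genomic prediction with non-additive genetic effects, end to end on
simulated data:

- **Simulator** (`epiblup.simulate`): paternal half-sib (optionally full-sib)
  family genotypes via Mendelian transmission from simulated haplotypes, with
  tunable adjacent-SNP LD (first-order latent Gaussian chain) and MAF
  filtering; true additive / dominance / epistatic (SNP-pair or
  MVN-from-kernel) effects with exact empirical variance fractions;
  phenotypes with categorical factors, covariates and directional dominance
  via a mean shift of dominance effects.
- **Relationship matrices** (`epiblup.kernels`): orthogonal (NOIA) additive
  and dominance marker codings from observed genotype frequencies; A and D
  kernels plus AA / AD / DD as trace-scaled Hadamard products; an exact
  pairwise additive-by-additive construction (unordered SNP pairs only,
  no same-SNP squares); SNP-density thinning in consecutive blocks; adjacent
  LD (r²) quantile summaries; off-diagonal distribution summaries.
- **REML engine** (`epiblup.reml`): multi-kernel single-trait mixed models by
  AI-REML with active-set boundary handling and EM fallback; variance
  components with SEs from the inverse average-information matrix, variance
  proportions with delta-method SEs, AIC, BLUPs for all animals (phenotyped
  or not) and BLUP extrapolation to arbitrary animals.
- **Model suite** (`epiblup.models`): the A / D / AA / AA2 / AD / Full model
  variants; fixed-effect design building (one-hot factors with rare-level
  merging, standardized covariates); directional-dominance slope on
  standardized and per-percentage-point scales; adjusted phenotypes
  (y − Xβ̂).
- **Evaluation** (`epiblup.evaluation`): stratified 10-fold cross-validation
  (every factor level kept in every training split), pooled and per-fold
  predictive accuracy (Pearson r between adjusted phenotypes and predicted
  total genotypic values) and dispersion bias (slope of predictions on
  adjusted phenotypes); PCA structure checks on the additive kernel.
- **Subsampling** (`epiblup.subsample`): stability experiment contrasting
  variance-component estimates with correlations of additive / AA effect
  estimates (sampled and unsampled animals) against a full-data fit.

## CLI

```bash
epiblup simulate --n-sires 50 --offspring-per-sire 25 --n-snps 5000 \
    --frac-a 0.45 --frac-aa 0.15 --n-pairs 500 --seed 1 --out-prefix sim
epiblup kernels --genotypes sim.genotypes.vcf --out-prefix k --which A,D,AA
epiblup fit --phenotypes sim.phenotypes.csv --kernels k_A.mat,k_AA.mat \
    --fixed sex,farm --covariates age_months,het_percent --model AA2 \
    --out fit.json
epiblup cv --phenotypes sim.phenotypes.csv --kernels k_A.mat,k_AA.mat \
    --fixed sex,farm --covariates age_months,het_percent --model AA2 \
    --n-folds 10 --seed 1 --out cv.json
epiblup subsample --phenotypes adj.csv --genotypes sim.genotypes.vcf \
    --sizes 500,1000,1800 --replicates 10 --seed 1 --out sub.json
```

Genotypes are read/written as minimal VCF (GT field, biallelic) or a TSV
dosage matrix; kernels use a tab-separated text format (header row of animal
IDs, then one row per animal).

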