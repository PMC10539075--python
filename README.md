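# wip-gwas

Weighted imputed-phenotype association testing for case–control GWAS.

Many disease cohorts contain subjects whose case/control status is
intermediate or missing — for dementia GWAS, the large group with mild
cognitive impairment (MCI) or no usable diagnosis.  Discarding them wastes
power.  This package implements the **WIP** (weighting imputed phenotypes)
framework:

1. fit a disease prediction model on the labeled subjects from
   disease-related endophenotypes (MRI measures, cognitive scores, sex),
   selecting the classifier by nested cross-validated AUC;
2. assign every unlabeled subject an affection probability *p*, the imputed
   label *y* = 1{*p* ≥ 0.5} and the analysis weight *w* = max(*p*, 1 − *p*);
3. test SNP association on the enlarged cohort with a weighted GEE
   (working independence) logistic model,
   logit μᵢ = Zᵢᵀα + Gᵢᵀβ, solving Σᵢ xᵢ wᵢ (yᵢ − μᵢ) = 0,
   with Wald or generalized score tests (sandwich or model-based
   covariance);
4. optionally correct the misclassification-induced attenuation of β̂:
   β̂_adj = β̂*/(B·d* + 1 − d*), where
   B = (1 − γ₁ − γ₀)/[(1 + γ₁ − γ₀)(1 − γ₁ + γ₀)] is the attenuation
   factor of the label-error rates and d* the proportion of SNP effect
   acting directly on disease rather than through the endophenotypes.

Three methods share one estimator and differ only in subset and weights:
**LR** (labeled subjects, unit weights), **IP** (labeled + imputed, unit
weights), **WIP** (labeled + imputed, probability weights).  A simulation
module generates synthetic cohorts under a mediated SNP-effect disease
model and reproduces the framework's type-I error and power study; a GWAS
module applies the tests genome-wide from PLINK bed or VCF input.

## Worked example

```python
import numpy as np
from wip import SimConfig, run_experiment

# fully mediated SNP effect (nu = 1), 5000 subjects with masked labels
cfg = SimConfig.desk(nu=1.0, h_d2=1e-4, h_i2=1e-3, n_missing=5000, reps=200)
res = run_experiment(cfg, seed=7)
print("effects (beta_D, beta_I):", np.round(res.effects, 3))
print(res.rates()[["method", "alpha", "rate", "se", "mean_beta"]]
      .query("alpha == 0.05").to_string(index=False))
```

prints

```
effects (beta_D, beta_I): [0.049 0.088]
method  alpha  rate       se  mean_beta
    LR   0.05 0.190 0.027740   0.051520
    IP   0.05 0.345 0.033614   0.061167
   WIP   0.05 0.360 0.033941   0.062169
```

With the SNP effect fully mediated through the traits, adding 5000
imputed-and-weighted subjects raises the empirical power at α = 0.05 from
0.19 (labeled-only logistic regression, `LR`) to 0.36 (`WIP`); `rate` is
the fraction of replicates with Wald p < 0.05 and `se` its binomial
Monte-Carlo standard error at 200 replicates.  Under the null calibration
(`h_d2=0, h_i2=0`) all three rates sit at the nominal level.

Command-line equivalents:

```sh
wip predict --traits traits.tsv --labels pheno.tsv --algos logistic,penalized \
    --folds 5 --seed 1 --out probs.tsv
wip assoc --bed cohort --covar covar.tsv --pheno pheno.tsv --probs probs.tsv \
    --method wip --test wald --out assoc.tsv
wip adjust --beta 0.08 --gamma0 0.05 --gamma1 0.1 --dstar 0.54
wip simulate --config sim.yaml --preset desk --out rates.tsv
wip make-fixtures --out fixtures/ --seed 1
```

`wip assoc` writes a per-variant table (CHR, BP, SNP, MA, MAF, N, OR,
ORADJ, P, GWS_FLAG, NOTE) flagging genome-wide significance at 5×10⁻⁸.

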