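# epiclock

Multi-tissue DNA-methylation age clocks for mice, end to end: from
bisulfite-sequencing CpG counts to a filtered methylation matrix, penalized
-regression age predictors, cross-validated accuracy, epigenetic age
acceleration under anti-aging interventions, and a mixed-model GWAS that
treats predicted age as the phenotype.

## Who this is for

Groups working with mouse RRBS/WGBS data who want a reproducible,
library-grade implementation of the standard epigenetic-clock workflow:
methylation levels as read frequencies k/n gated by a Jeffreys-prior
confidence filter, glmnet-style ridge (α = 0) and elastic-net (α = 0.5)
clocks with internally cross-validated penalties, leave-one-batch-out
evaluation (batch = tissue × study), per-batch age-acceleration residuals
with Kruskal-Wallis group tests and Stouffer meta-analysis, and an
EMMA-lineage linear mixed model with kinship correction for association
mapping across inbred strains. Everything is testable offline: a
synthetic-data module generates RRBS-like binomial counts with age-linear
logit drift, batch offsets, intervention arms, and structured genotype
panels with known truth.

## The model

A clock is a penalized linear regression of chronological age (months) on
CpG methylation levels x ∈ [0, 1]^p:

    min over (β0, β) of  (1/2n) Σᵢ (yᵢ − β0 − xᵢᵀβ)²
                         + λ [ α‖β‖₁ + ((1−α)/2)‖β‖₂² ]

with predictors standardized internally and λ chosen by seeded 10-fold
cross-validation (lambda.min). DNAm age is ŷ = β0 + xᵀβ; age acceleration
is the residual of ŷ on y fitted per batch; and the GWAS model is
y = Xβ + g_s β_s + u + ε with u ~ N(0, σ²_g K) for a standardized-genotype
kinship K. Details, conventions and limitations: `docs/methods.md`.

## Worked example

Simulate a small multi-tissue cohort, build the matrix, and cross-validate
an elastic-net clock — as a library:

```python
from epiclock import evaluate
from epiclock.simulate import SyntheticConfig
from epiclock.workflows import build_from_config

matrix, manifest, truth, conserved = build_from_config(
    SyntheticConfig(n_samples=100, n_sites=1000, n_age_sites=60, seed=3)
)
res = evaluate.crossval(matrix.values, matrix.metadata,
                        alpha=0.5, scheme="kfold10", seed=1)
print(res)
```

which prints

```
CVResult(scheme='kfold10', n=100, R=0.991, mae=0.81 months)
```

R is the Pearson correlation between out-of-fold DNAm age and chronological
age; mae the median absolute error in months. The same pipeline from the
shell:

```sh
epiclock simulate --seed 7 --out data/
epiclock build-matrix --counts data/counts --metadata data/metadata.tsv \
    --min-sites 1000 --out matrix.tsv --manifest manifest.json
epiclock crossval --matrix matrix.tsv --metadata data/metadata.tsv \
    --alpha 0.5 --scheme kfold10 --seed 1 --out cv.tsv
epiclock train --matrix matrix.tsv --metadata data/metadata.tsv \
    --alpha 0 --out clock.tsv
```

`accel` compares treated vs control age acceleration per experiment with a
meta-analysis p-value, and `gwas` runs the kinship-corrected mixed model
with 2-Mbp peak thinning and ±500 kbp gene annotation.

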