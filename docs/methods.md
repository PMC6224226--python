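# Methods

`epiclock` implements a multi-tissue epigenetic-clock analysis for mouse
bisulfite-sequencing data: matrix construction from CpG read counts,
penalized-regression age clocks, cross-validated evaluation, epigenetic age
acceleration with group tests, and a mixed-model GWAS that uses predicted
(DNAm) age as the trait. This note records the models, the defaults and why
they were chosen, the conventions adopted where the underlying procedure is
genuinely open, and what the synthetic-data studies do and do not establish.

## Matrix construction

Per CpG and sample, the methylation level is the raw read frequency k/n
(methylated over total mapped reads). Forward- and reverse-strand cytosines
of one CpG are pooled by summing counts before anything else; a
reverse-strand record at position p belongs to the CpG whose forward C sits
at p−1. Technical replicates are merged the same way, by summing counts.

A measurement is *confident* when the equal-tailed 95% credible interval of
the binomial proportion under a Jeffreys Beta(0.5, 0.5) prior is strictly
narrower than 0.50 (and n > 0). The Bayesian machinery only gates the
measurement; the stored value is always k/n, never the posterior mean. The
width rule has a simple coverage interpretation: at worst-case frequency
0.5 it requires roughly n ≥ 13 reads, while near-0 or near-1 sites pass
with far less.

The pipeline order is fixed:

1. strand pooling and replicate merging;
2. removal of samples measuring fewer than 500,000 CpGs (configurable; a
   "measured" CpG has total count > 0 — exactly at the threshold is kept);
3. Jeffreys confidence calls for every cell;
4. site filter: keep CpGs confident in ≥ 95% of samples (inclusive);
5. set non-confident cells to missing, so "missing" uniformly means
   no-data-or-unconfident;
6. iteratively drop the sample with the most missing cells (ties: first in
   row order) until global missingness ≤ 2% or one sample remains;
7. k-nearest-neighbor imputation with k = 5.

KNN imputation operates over samples: a missing cell (s, j) is filled with
the unweighted mean of the values at j among the k nearest other samples
observed at j, with distance = squared Euclidean over sites observed in
both, normalized by the number of shared sites. The normalization makes
distances comparable across unequal missingness patterns; the neighbor
axis and metric are conventions (the procedure is usually stated without
them) and are implemented via scikit-learn's `KNNImputer`, whose
nan-Euclidean distance is a monotone transform of ours and therefore ranks
neighbors identically. Imputed values are convex combinations of observed
values, hence stay in [0, 1], and observed cells are never modified.

## Penalized-regression clocks

For n training samples and p sites, the clock minimizes the glmnet-style
objective

    (1/(2n)) Σ_i (y_i − β0 − x_i'β)² + λ [ α‖β‖₁ + ((1−α)/2)‖β‖₂² ]

with ages y in months, an unpenalized intercept, and predictors
standardized internally to mean 0 and population SD 1 (coefficients are
reported on the original scale; zero-variance sites get coefficient 0 by
convention). α = 0 is the ridge clock, α = 0.5 the elastic-net clock; the
lasso (α = 1) is deliberately out of scope.

Ridge is solved in closed form through an eigendecomposition of whichever
Gram matrix is smaller (O(n²p) when p ≫ n), so it is exact at any scale.
The elastic net uses coordinate descent (scikit-learn's solver) warm-started
down a log-spaced path from λ_max to the target penalty; on small problems
the solution matches a generic numeric minimization of the stated objective
to better than 1e-6 relative.

The penalty is chosen by internal 10-fold cross-validation with a seeded
shuffle (default seed 1): 100 log-spaced values from λ_max — the smallest
penalty with an all-zero solution; for ridge the conventional α = 0.001
surrogate defines it — down to 1e-4·λ_max when n > p and 1e-2·λ_max
otherwise (the reference glmnet path convention; the short path also keeps
the ill-conditioned n < p tail out of the search). The chosen λ is the
pooled-MSE minimizer ("lambda.min"); "lambda.1se" was not adopted because
the target procedure asks for the automatic optimum. Each CV fold is
re-standardized on its own training part, exactly as a fresh fit would be.

`PenalizedAgeClock` is a scikit-learn estimator (`fit`/`predict`,
`get_params`, trailing-underscore attributes), so it composes with
pipelines and model selection; `fit_penalized`, `select_lambda` and
`predict_age` are thin functional wrappers. Prediction requires every
training site to be present and errors with the missing list — silent
zero-filling would corrupt DNAm ages.

The conserved-CpG clock is the same estimator fitted on the subset of sites
flagged as evolutionarily conserved (BED input, intersected with the
matrix; the intersection size is reported and an empty intersection is an
error).

## Cross-validated evaluation

Three schemes: leave-one-sample-out, seeded 10-fold (remainder samples
dealt one per fold), and leave-one-batch-out, where a batch is the
combination of tissue and study of origin. Samples from longevity
interventions (and their controls) can be excluded from every training fold
while still being predicted; by default they are also excluded from the
pooled metrics, since training-population accuracy is what the scheme
estimates (a `score_excluded` flag scores everyone). Metrics are pooled
over all out-of-fold predictions — one Pearson R and one median absolute
error in months — rather than averaged per fold. All folds share one seed,
so batch-scheme results depend only on the partition, not on batch names or
iteration order.

## Age acceleration and group comparisons

Age acceleration is the residual of predicted age after an ordinary
least-squares fit of predicted on chronological age, computed per batch so
that tissue- and study-level prediction offsets cancel; linear fitting is
the minimal reading of the procedure. Batches with fewer than 3 samples or
fewer than 2 distinct ages fall back to the global fit (logged). Residuals
within a properly fitted batch sum to zero and are invariant to adding a
constant to that batch's predictions.

Treated-vs-control differences are tested per experiment with the
Kruskal-Wallis rank test (mid-ranks and the standard tie correction;
chi-square reference). For combining experiments the per-experiment
one-sided p (the KW p halved and oriented by the sign of the treated-minus
-control median difference) enters an unweighted Stouffer meta-analysis,
z_c = Σ z_i / √m; Fisher's method is available behind a flag. The
meta-analysis method and sidedness are conventions — the combined p is
reported as directional evidence of deceleration.

## Mixed-model GWAS

DNAm age across an inbred panel is regressed on each SNP under
y = Xβ + g_s β_s + u + ε with u ~ N(0, σ²_g K), ε ~ N(0, σ²_e I).
Genotypes are 0/1 (homozygous major/minor); heterozygous or unknown calls
are treated as missing and mean-imputed per SNP. SNPs pass a strict
MAF > 5% filter (missing entries excluded from the frequency). K is the
standardized-genotype cross-product W W'/p rescaled to unit mean diagonal —
the convention of the EMMA/pyLMM lineage. Note that empirical per-SNP
centering leaves a small −1/(n−1) shadow on off-diagonals of an unrelated
panel; it is absorbed by the variance components.

Estimation follows the same lineage: eigendecompose K once, profile the
variance ratio δ = σ²_e/σ²_g by maximum likelihood on the null model
(coarse grid on log δ ∈ [−10, 10] then bounded refinement), hold δ fixed
across SNPs, and test each SNP with a 1-df Wald chi-square from weighted
least squares in the eigenbasis, re-estimating the residual scale per SNP
with an n−q denominator. With K = I this collapses exactly to OLS Wald
tests. Null simulations with structured kinship put the empirical type-I
error at nominal 0.05 within [0.03, 0.07].

Peaks are thinned greedily — best p first, accepting a SNP only if ≥ 2 Mbp
from every accepted SNP on its chromosome (the average LD-block scale in
the panel this models), up to 10 peaks. This formalizes as an algorithm
what is usually stated as a property of the reported SNPs. Genes within a
closed ±500 kbp window are reported nearest-first. No genome-wide threshold
is imposed; the Bonferroni line is carried in the result metadata. A
one-sided Welch t-test compares DNAm ages between the two allelic groups of
a chosen SNP.

## Synthetic data

The generator emulates the statistical regime the pipeline targets, not a
genome. Per site j and sample i the methylated fraction is
μ_ij = logit⁻¹(b_j + s_j·a_i + o_bj), with baseline b_j ~ N(0, 1.5), slope
s_j nonzero at a minority of "age sites" (signed, |s| ~ U(0.02, 0.10)
logit/month, baselines of age sites re-centered so they stay responsive at
mid-life), per-(batch, site) offsets o_bj ~ N(0, 1.0) for the tissue×study
batch, and a_i the *effective* age — chronological age minus the injected
deceleration for intervention-arm samples. Coverage is negative-binomial
per strand (size 5, mean 20, i.e. ~40 pooled reads per CpG — the
post-filter high-quality regime clocks are trained on); methylated counts
are binomial. Strand records with zero sampled reads are simply absent, so
missingness and confidence failures arise mechanistically rather than by
masking at random. Everything is a pure function of the seed.

The logit-linear drift keeps frequencies valid across the full lifespan
(ages default to U(1, 32) months). The batch-offset SD of 1.0 logit was
set during generator validation: per-site offsets much smaller than the
binomial noise floor are averaged away by clocks spanning thousands of
sites and leave leave-one-batch-out no harder than within-sample CV,
contradicting the multi-tissue heterogeneity the generator exists to
emulate; at 1.0 logit (≈ 20-percentage-point shifts at mid-methylation
sites, modest for tissue differences) the batch structure is genuinely
informative. The conserved-site flag marks a random 10% of sites.

The genotype generator draws cluster-structured allele frequencies
(Balding-Nichols divergence, default F = 0.15, 4 clusters, 80 strains) and
inbred 0/1 genotypes; the phenotype is mean 4.2 months plus an optional
causal-SNP effect plus a polygenic term of heritability 0.3 with the
non-causal variance scaled to 1 month².

What the synthetic studies show: that every stage implements its stated
contract and that, when the generative assumptions hold, the pipeline
recovers ages (CV R ≥ 0.9 at the default 300 × 5,000 scale), orders the
conserved-subset clock below the all-site clock, makes held-out batches
measurably harder than held-out samples, detects a −2-month deceleration
at n = 20/20 with a calibrated null, and finds a strong causal SNP under
population structure. What they do not show: performance on real RRBS
data, whose batch effects are not mean-zero per site, whose coverage is
far more heterogeneous, and whose age signal is weaker and confounded with
genetics; the headline accuracies on synthetic data are therefore upper
bounds with no claim of transfer.

## Problem sizes and numerical choices

Simulation studies run at desk scale, chosen as the smallest sizes at which
each effect is comfortably identified: the recovery study at the default
300 samples × 5,000 sites; the batch-vs-sample comparison averaged over 5
seeds at the same scale (ridge clocks, whose closed-form path evaluation
makes repeated CV cheap); intervention detection at 120 training samples ×
1,200 sites with a 20/20 arm over 10 seeds; its null calibration at 50 ×
300 over 200 seeds with the ridge penalty fixed at 1.0 (penalty selection
does not enter the null distribution of the group test); GWAS studies at
60 strains × 300–500 SNPs, with type-I error estimated from 2,000 null
phenotypes on fixed structured genotypes. Coordinate descent runs at
tolerance 1e-6 (dual-gap scale) for final fits and 1e-4 along CV paths;
ridge solutions are exact linear algebra. Degenerate inputs fail loudly:
constant ages, NaN in the design, empty confident-site sets, all-missing
sites, single batches, and undersized allele groups are errors, not
warnings.

## Known limitations

- The KNN distance/axis, the 95%-rule-before-missingness-reduction
  ordering, and the meta-analysis method are documented conventions; other
  readings of the same prose exist.
- The Wald test holds δ fixed across SNPs (the fast approximation); exact
  per-SNP variance-component refits are not implemented.
- The generator's batch offsets are mean-zero and site-independent; real
  batch effects correlate across sites and with coverage.
- Chromosomes are passed through untouched (no whitelist), and Diversity
  Outbred founder-coordinate projection is out of scope.
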