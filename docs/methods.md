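# Methods

`gbspredict` implements a genomic-prediction pipeline for inbred (mostly
doubled-haploid, DH) breeding populations genotyped by sequencing (GBS),
where 40–60% of genotype calls are typically missing at ~1× coverage. It
covers marker editing, haplotype-clustering imputation, relationship-matrix
and kernel construction, Bayesian GBLUP / RKHS kernel-averaging prediction,
and replicated cross-validated evaluation, together with a synthetic-data
generator that reproduces the statistical structure these methods assume.

## Genotype coding and marker editing

Calls are coded 0/2 for the two homozygotes, 1 for heterozygotes, and
missing. Because the material is inbred, residual heterozygous calls are
treated as errors and set missing before any downstream step. Marker
editing then removes markers with more than 80% missing lines, and next
removes markers with minor allele frequency (MAF) ≤ 0.05. MAF is computed
on called genotypes only — the only defensible denominator at 40–60%
missingness — and the filter order (missingness first, MAF second) is fixed
because survivor counts differ under the reverse order. Residual missing
calls entering a marker-based model are replaced by the marker mean 2p̂
("expected-value imputation"), which leaves allele frequencies unchanged.

## Haplotype-clustering imputation

At every marker, lines are partitioned into clusters of individuals that
plausibly share the local haplotype. Two lines may co-cluster only if they
show at most `max_disagreements` (default 4) opposing homozygotes —
loci where one line is 0 and the other 2 — within a window of `flank_size`
markers on each side of the focal marker (defaults: 1000; 50 and 100 are
the short/long-haplotype settings). Missing calls are never evidence of
disagreement. Within a cluster, a missing focal call is *technically*
missing if any member is called — it receives the cluster consensus — and
*biologically* missing (presence–absence variation) if every member is
missing, in which case it stays missing.

Decisions the algorithm statement leaves open, fixed here:

* **Cluster formation** is greedy seed-and-extend in line input order with
  complete linkage: a line joins the first cluster compatible with every
  current member, else founds a new cluster. This is deterministic,
  guarantees the pairwise disagreement bound within clusters, and allows
  singletons. `linkage="seed"` relaxes the check to the founding member.
* **Threshold semantics**: pairs with more than 4 disagreements may not
  co-cluster (≤ 4 tolerated). The strict no-opposing-homozygotes reading is
  available as `max_disagreements=0`.
* **Consensus with internal conflict** (possible when disagreements are
  tolerated): majority vote among called members; an exact tie leaves the
  call missing, and such cells are reported under the biologically-missing
  provenance code.
* **Windows truncate** at chromosome ends; no wrap-around. The focal marker
  itself is not part of its window.

The sweep moves the focal marker one position at a time along each
chromosome. The implementation maintains pairwise disagreement counts
incrementally under the sliding window (rank-one updates per entering/
leaving marker column), compiled with numba, so a 300-line × 4,000-marker
imputation takes seconds rather than hours. A pure-Python per-marker path
(`cluster_at_marker`, `impute_at_marker`) provides the same semantics for
inspection and is tested for exact agreement with the sweep and with an
exhaustive brute-force oracle.

The per-marker clusterings double as *haplotype alleles*: the incidence
matrix with one 0/1 column per (marker, cluster) pair can replace SNP
dosages when building relationship matrices (each line carries exactly one
allele per marker). A `stride` parameter thins the sampled markers, since
every-marker clusterings produce very high-dimensional incidence matrices.

Expected behaviour, verified empirically in the tests: shorter flanks
impute more cells (clusters are larger, so a called member is more often
available), longer flanks impute fewer cells at equal or better accuracy.

## Relationship matrices and kernels

* **Genomic (G)**: VanRaden method 1, G = ZZ′ / (2Σpⱼ(1−pⱼ)) with
  Z = X − 2p. On fully inbred lines diag(G) ≈ 2. With missing dosages
  (nonimputed GBS) the cross-products are computed over pairwise-complete
  markers and rescaled by each pair's share of the denominator; because
  pairwise-complete estimators are not positive semidefinite in general,
  the result is projected to the nearest PSD matrix (negative eigenvalues
  clipped).
* **Haplotype (G_H)**: same centred cross-product on the haplotype-allele
  incidence matrix, scaled by Σqⱼ(1−qⱼ) over haplotype-allele frequencies.
* **Pedigree (A)**: tabular method, a_xy = (a_sy + a_dy)/2,
  a_xx = 1 + a_sd/2, founders 1 on the diagonal. DH lines are fully inbred
  by construction, so their diagonal is forced to 2 while off-diagonals
  follow the standard recursion with the cross parents as the recorded
  parents (two DH full sibs get a = 0.5 under this convention; the
  convention understates the realised DH-sib covariance but keeps the
  matrix a pure pedigree expectation, and prediction is invariant to the
  within-family scale absorbed by the variance component).
* **Gaussian kernels (RKHS)**: K_h(i,i′) = exp(−h·d²(i,i′)/median(d²)),
  with d² the squared Euclidean distance over dosages scaled to [0,1] and
  the median taken over off-diagonal pairs, so the bandwidth grid
  {0.2, 1, 5} (default) is scale-free. Kernel averaging fits all
  bandwidths jointly, one variance each. With missing dosages, distances
  are pairwise-complete rescaled to the full marker count, followed by the
  PSD projection.

## Bayesian multi-kernel model

y = 1μ + Σ_k u_k + ε, u_k ~ N(0, σ²_k K_k), ε ~ N(0, σ²_e I); scaled
inverse-χ² priors (df 5) on all variances. Each kernel's prior scale is set
so that the *trait-scale* genetic variance it implies equals
`prior_scale_fraction` (default 0.5/#kernels) of var(y): the variance a
kernel contributes among lines per unit σ²_k is c_k = tr(PKP)/(n−1) (P the
centring projector), so the prior scale is divided by c_k. Without this
correction, kernels with large diagonals (VanRaden G on DH lines) receive
priors implying roughly twice the intended genetic variance, which biases
heritability summaries upward. The reported `heritability()` uses the same
c_k mapping: h² = Σσ²_k c_k / (Σσ²_k c_k + σ²_e).

Sampling is Gibbs in the eigenbasis of each kernel (eigendecomposition once
per kernel per fit; components with eigenvalue ≤ 1e−10 dropped), so an
iteration costs two matrix–vector products per kernel. Phenotypes of
unobserved (test) lines are latent variables sampled within the chain;
prediction is the posterior mean of μ + Σ u_k at those lines, keeping one
code path for training and prediction. Chains are bit-reproducible given
(seed, config). Defaults 6000/1000/5 (iterations/burn-in/thinning) for
production; tests use short chains (≈1500/500/2) with correspondingly
widened tolerances. A fixed-variance mode clamps variance components for
validation against the mixed-model-equations closed form.

## Evaluation

Plot phenotypes from the replicated incomplete-block trial are pre-adjusted
by OLS (treatment coding) under value ~ env + block(env, rep) + line; only
the environment and block estimates are subtracted, line effects being in
the model solely so the nuisance estimates are unbiased. Line-level values
are means of adjusted plots. Variance components come from the balanced
two-way method-of-moments ANOVA (σ̂²_e = MS_E, σ̂²_ge = (MS_GE−MS_E)/r,
σ̂²_g = (MS_G−MS_GE)/(er), negatives truncated), and broad-sense
heritability on an entry-mean basis is h² = σ²_g/(σ²_g + σ²_ge/e +
σ²_e/(er)).

Predictive ability is evaluated by replicated random 70/30
training/testing partitions (default 50). For each model × partition the
model is fitted to training lines, and the Pearson correlation between
predictions and observed values in the testing set is recorded; tables
report the mean and the SD of the correlations across partitions
(correlations rounded to 3 decimals) and the percent change versus a
baseline model (one decimal), conventionally the pedigree-only model.
Linkage disequilibrium is summarised as squared Pearson correlations of
allele counts between locus pairs within a distance cap, on
pairwise-complete lines, with binned distance medians.

## Synthetic data generator

The generator emulates the study system end to end:

* **Founders**: 8 fully homozygous inbreds; per-marker allele frequencies
  uniform in [0.1, 0.5] by default.
* **Families**: ten full-sib DH families from crosses and backcrosses of
  the founders, family sizes proportional to the reference design (504
  lines at scale 1). Each DH line is a doubled gamete of its F1 (or BC1)
  individual: crossover count per chromosome ~ Poisson(length_cM/100),
  positions uniform, no interference. Maps default to 150 cM chromosomes
  with evenly spaced markers.
* **GBS missingness**: each call masked independently with probability
  exp(−coverage) — the zero-read event of a Poisson read-count model; 1×
  coverage gives the expected 36.8% missing. An optional lognormal
  per-marker coverage multiplier emulates depth variation along the
  genome, and an optional per-cell heterozygote error rate (0.002 scale)
  exercises the heterozygote-masking step; both default off.
* **Phenotypes**: y(line, env, rep) = μ + env + block + g + ge + ε with g
  additive over `n_qtl` (default 100) randomly placed QTL rescaled to
  var(g) = σ²_g, and (σ²_g, σ²_ge, σ²_e) = (1, 1, 2) with e = 4
  environments × r = 2 replicates by default, giving an entry-mean
  broad-sense h² of 0.667 — the scale of a well-heritable agronomic trait
  in this material. Blocks of 25 lines are re-randomised per (env, rep).
* **Panel vs causal loci**: by default the causal QTL are excluded from
  the genotyping panel, so called SNPs tag the trait only through linkage,
  as with real reduced-representation genotyping. True genotypes at all
  loci and true breeding values are returned for oracle tests.

What the generator does **not** emulate: linked QTL effect-size structure
beyond i.i.d. normal, systematic (presence–absence) missingness correlated
across lines, genotyping error beyond the optional i.i.d. heterozygote
flips, selection or assortative mating within families, and multi-trait
correlation. Passing tests on these simulations therefore demonstrate
correctness of the algorithms and the expected qualitative behaviour of the
models under the stated assumptions, not field-data performance.

## Problem sizes used in tests and experiments

Simulation experiments are scaled for a desk machine: masking experiments
use 300 lines × 2 chromosomes × 2,000 markers (windows of ±50/±1000 markers
are meaningful at this density); sampler validation uses 100–400 lines;
the pedigree-vs-markers cross-validation comparison uses 300 lines × 2
chromosomes × 100 markers with 10 partitions and short chains. The small
panel in the last experiment is deliberate: with dense panels the
marker-estimated relationships are nearly noise-free and the pedigree is
redundant, whereas the comparison targets the regime — as in real GBS
programmes with high missingness — where marker and pedigree information
are complementary and combining them is what yields the accuracy gain.

## Known limitations

* The imputation consensus ignores call quality; all called members vote
  equally.
* The pairwise-complete GRM/kernel rescaling assumes missingness is
  independent of genotype; informative missingness (presence–absence
  variation) biases it.
* The A-matrix convention for DH lines (above) is an expectation under the
  recorded two-generation pedigree, not the realised inbred-sib covariance.
* `anova_varcomp` requires a balanced line × environment × replicate
  layout; unbalanced tables must be adjusted or balanced first.
* Kernel averaging uses a fixed bandwidth grid; no bandwidth optimisation.
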