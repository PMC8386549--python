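# Methods

This note documents the models, defaults and numerical choices behind
`icipipe`, and what the synthetic validation does and does not demonstrate.

## Synthetic cohort model

The generator (`icipipe.synthetic_data`) produces one cohort per
`SimulationConfig`; all randomness flows through a single seeded
`numpy.random.Generator`, so identical configs give byte-identical cohorts.

**Reference profiles.** Each of `n_cell_types` cell types shares a
log-normal baseline abundance (ln-mean 3, ln-sd 1) and elevates its own
disjoint block of marker genes 8-fold; per-type multiplicative jitter
(ln-sd 0.25) decorrelates the non-marker portions. Marker blocks are capped
at 30 genes per type, giving a compact marker signature comparable in size
to the reference matrices used for bulk immune deconvolution (a few hundred
genes); deconvolution is run against this marker submatrix.

**Fractions and clusters.** Samples are assigned to `n_clusters` planted
clusters (default 3, uniform proportions). Cell fractions are Dirichlet
draws around cluster-specific archetypes (concentration 0.4 baseline, 8 and
6 on two round-robin favored cell types), so immunophenotypes are
recoverable from fractions alone and the archetypes are roughly symmetric.

**Expression.** Linear-scale expression is `signature @ fractionsᵀ` scaled
to a 10⁶ library size per sample. A fraction `deg_fraction` (default 0.10)
of non-marker genes are cluster-informative: each carries a random sign and
a shift of `deg_log2_effect` (default 2.0) log₂ units scaled by a per-cluster
weight spanning +1…−1 across clusters. Gaussian noise with sd `noise_sd`
(default 0.2) is added on the log₂ scale — multiplicative log-normal noise
on the linear scale, chosen because RNA-seq abundances are heteroskedastic
and must stay non-negative.

**Latent score and survival.** The latent immune score is the mean
z-expression of positive-sign informative genes minus that of negative-sign
ones — deliberately the same type-I-minus-type-II structure as the ICI
score, so recovery tests are meaningful. Survival times are exponential
with hazard `λ₀·exp(−hazard_beta·latent)`, λ₀ = ln2/730 days (2-year median
at score 0). `hazard_beta` is therefore the *protective* log-hazard per unit
latent score: the package's convention is that higher immune infiltration
means better prognosis, matching the phenomenon the score is built to
detect, so positive `hazard_beta` makes the high-ICI group the long
survivor. Censoring replaces the event time with a uniform draw on (0, T)
with probability `censor_rate` (default 0.3), which makes the realized
censoring proportion match the rate.

**Mutations.** Per-sample nonsynonymous counts are Poisson with means drawn
uniformly from `mutation_rate_range` (default 5–80, spanning the wide TMB
range seen in colon tumors). Records receive MAF `Variant_Classification`
strings, ~70% nonsynonymous, and gene symbols drawn with Zipf-like weights
so a handful of genes recur — enough structure to exercise the TMB filter
and frequency tests.

What the generator does **not** emulate: cross-cohort batch effects,
probe-level artifacts, copy-number or methylation layers, biologically
structured mutation co-occurrence, or dependence of mutation burden on the
immune score (TMB and latent score are independent by construction, so the
expected TMB–ICI Spearman correlation is 0). Passing tests therefore show
algorithmic correctness and statistical calibration under a clean
generative model, not robustness to real-data artifacts.

## Deconvolution

Per sample: restrict to shared genes (≥ 50 required), standardize the
signature by its global mean/sd and the mixture column by its own, fit a
linear ν-SVR at ν ∈ {0.25, 0.5, 0.75}, keep the fit whose clamped,
simplex-normalized coefficients reconstruct the standardized mixture with
the smallest RMSE, and report that fit's RMSE and Pearson r. Negative
coefficients are clamped to zero before normalization; the standardization
makes the result invariant to positive rescaling of the mixture column.
Quantile normalization is not applied (standard guidance for RNA-seq
input). The permutation p-value deconvolves gene-permuted copies of the
column and uses the add-one estimator p = (1+#{r_null ≥ r_obs})/(n_perm+1),
so p is never exactly 0; samples with p ≥ 0.05 are flagged rather than
dropped, and the clustering stage excludes flagged samples by default.
The calibration suite uses 200 permutations per column (scaled from the
1000 used at cohort scale) over 200 noise replicates against a 60-gene,
5-type signature — sizes chosen to make a ±3-point check of the 5% flag
rate precise at desk scale.

Enrichment scores are single-sample weighted-ECDF statistics: genes are
ordered by decreasing expression, in-set steps weighted by rank^0.25 (the
published single-sample enrichment default; the weight is the only free
parameter), out-of-set steps uniform, and the score integrates the
difference over the whole list. The combined score is immune + stromal by
definition.

## Consensus clustering

For each K in 2…`k_max` (default 9): `reps`=100 rounds draw 80% of samples
without replacement (`p_item`=0.8, all features kept), run K-means with a
single random start, and accumulate co-assignment/co-sampling ratios into
the consensus matrix. Final labels cut an average-linkage dendrogram of
1 − consensus. The single start per round is deliberate: with a
multi-restart inner K-means, a *wrong* K still produces near-deterministic
partitions of a fixed dataset, so the consensus matrix looks crisp at every
K and K-selection signal vanishes; one start lets basin multiplicity at
wrong K show up as consensus ambiguity.

K is chosen by the delta-area rule on the CDF of consensus entries: the
area A(K) equals 1 − mean(consensus), Δ(2) = A(2), Δ(K) = (A(K) −
A(K−1))/A(K−1) for K ≥ 3, and the chosen K maximizes Δ. Callers can
override K; the cohort-level wrappers default to the three-cluster
immunophenotype (ICI clusters A/B/C) and two gene clusters (A/B). Samples
are internally sorted by id so the partition is invariant to input order.
Cluster letters are anchored to prognosis — "A" has the largest
restricted-mean survival (area under the Kaplan–Meier curve to the last
observed time), which is always defined, unlike the KM median.

## Moderated differential expression

Per gene, a one-way layout across cluster labels: residual variance s²_g on
d = n − k df, shrunk toward a common prior by moment-matching log s² to a
scaled inverse-χ² distribution (prior df d₀ from inverting the trigamma
equation, prior scale s₀² from the mean of log s²; an empirical variance of
log s² at or below trigamma(d/2) indicates no detectable heterogeneity and
gives d₀ = ∞, i.e. complete shrinkage). The moderated F is the
between-group mean square over the posterior variance, referred to
F(k−1, d+d₀) (χ² when d₀ = ∞). Setting `prior_df=0` disables shrinkage and
reproduces the ordinary one-way F exactly — the vague-prior limit used as
an identity check. The moment-matching fit was chosen over iterative ML as
closed-form, testable, and adequate at these scales.

`log2fc` is the largest absolute pairwise group-mean difference (the range
of group means), which keeps the |log₂FC| > 1 filter well defined for three
groups; DEG calls require FDR < 0.05 (Benjamini–Hochberg). The group
comparison helpers use tie-corrected Kruskal–Wallis H plus an exact
rank-sum p for two groups when both sides have ≤ 25 untied observations.

## Signature scores

Gene typing uses Spearman correlation with the gene-cluster-A indicator
(A = better prognosis): strictly positive → type I, otherwise type II;
constant genes fall to type II with a warning (ties-to-II). Characteristic
genes come from a shadow-feature procedure: each iteration appends a
permuted copy of every non-rejected feature, fits a random forest
(200 trees, √p features per split), scores a hit when a real feature's
importance exceeds the best shadow's, and promotes features by two
one-sided binomial tests on the hit count (Bonferroni-corrected α = 0.01
over the initial candidates); the loop stops when nothing is tentative or
at 100 iterations. One calibration choice departs from the usual
formulation: the shadow pool is held at its initial size throughout,
padding with extra permuted copies as features are rejected. With a
shrinking pool, a chance-correlated survivor eventually competes against
only a handful of shadows and outscores their maximum almost surely, so
null data yields false confirmations; a constant-size pool keeps the
best-shadow bar stable and the null hit probability near ½. If one type ends with no confirmed gene, scoring falls
back to all DEGs of that type (with a warning) so the score remains
defined.

Each type's score is the per-sample coordinate on the first principal
component of the z-scored genes × samples submatrix (computed by SVD). PC1
sign is not identifiable, so the orientation is fixed to correlate
positively with the set's mean z-expression: a high type-I score always
means high type-I expression. A single-gene set reduces exactly to that
gene's z-scores. The ICI score is S_PCA I − S_PCA II elementwise.

## Survival

Kaplan–Meier curves (with Greenwood standard errors) and the multi-group
log-rank test delegate to lifelines. The optimal cutpoint re-implements the
maximally selected log-rank statistic: candidates are midpoints between
consecutive distinct score values (midpoints make boundary assignment
unambiguous) whose groups both hold ≥ `minprop` = 0.1 of the cohort (the
conventional default), and the returned cutpoint maximizes |O−E|/√V with
the hypergeometric variance; censored observations at t remain at risk for
events at t. The two-group log-rank χ² equals the square of this
standardized statistic at the same split, a cross-check in the test suite.
Group membership depends only on ranks, so monotone transforms of the score
leave the split unchanged.

Two inferential caveats are inherited from the workflow this implements:
no p-value correction is applied for having optimized the cutpoint, so
downstream log-rank p-values at the chosen split are anti-conservative; and
the argmax of a maximally selected statistic is a changepoint-type
estimator with slow (cube-root) localization, so the cutpoint itself is
variable at moderate effect sizes even when the high/low contrast is
clearly significant. All survival computations exclude follow-up shorter
than 30 days (`filter_min_followup`), applied before cutpoint optimization.

## Mutation burden

TMB is the raw count of records whose `Variant_Classification` is one of
the nine nonsynonymous MAF classes (missense, nonsense, nonstop,
frame-shift ins/del, in-frame ins/del, splice site, translation start
site); no per-megabase scaling is applied because the workflow uses counts
and no capture size is defined. Unknown classification strings are excluded
with a warning. The default high/low TMB rule is the median (high ⇔ tmb >
median), with the maxstat cutpoint available as an option; the combined
subgroups are the four H/L-TMB × H/L-ICI labels. Per-gene contrasts use
two-sided Fisher exact tests on (mutated, unmutated) × (high, low) tables
with BH adjustment across genes — exact tests because per-gene counts are
small — and genes are ranked by overall alteration frequency for the top-k
summary; duplicate gene symbols collapse to one record per gene and sample.

## Problem sizes and determinism

The validation suite runs cohorts of 50–300 samples, 400–1200 genes and
5–8 cell types; calibration studies use 20–200 replicates (20 for the
selection and FDR calibrations, 50 for cutpoint recovery, 200 for the
permutation-flag rate). These sizes were chosen so each study estimates its
quantity with a Monte-Carlo error comfortably below the margin being
asserted. Every stochastic component takes an explicit seed; fixed seeds
make the full pipeline, including subsampled consensus clustering and the
random-forest selection loop, exactly reproducible.
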