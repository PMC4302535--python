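# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limitations of the `riploop` pipeline.

## Count model and paired enrichment test

Counts are modelled as negative binomial with a log link:
K ~ NB(μ, φ) with Var K = μ + φμ², log μ = offset + Xβ, where the offset is
the log library size (column sum), so coefficients live on the
counts-per-million-ratio scale.  For one bait with R replicate pairs the
design has an intercept, R−1 replicate-pair block dummies and an IP-vs-Total
fraction indicator; the fraction coefficient divided by ln 2 is the reported
log2 enrichment.  The pairwise bait contrast uses a joint design over both
baits' libraries with one block dummy per replicate pair, a fraction main
effect and a fraction × bait interaction whose coefficient equals the
difference of the two baits' enrichments (so swapping the baits negates the
estimate and preserves the p-value).

Fitting is by iteratively reweighted least squares with the dispersion held
fixed per gene, batched across genes (all genes share the design matrix, so
the per-gene weighted normal equations are assembled with `einsum` and
solved as a stack of small systems).  Convergence: relative deviance change
below 1e-8 or 50 iterations, with step halving whenever an update increases
the deviance.  Genes that fail to converge are reported with missing
p-values and a logged count, never silently dropped.  All-zero genes are
untested (missing p, never 0).

Inference is a likelihood-ratio chi-square test with 1 df: for fixed φ the
LRT statistic equals the deviance difference between the nested fits.
Quasi-likelihood F-tests and exact NB tests are out of scope.  The fits are
verified in the test suite against statsmodels' independent GLM
implementation.

### Normalization policy

Only CPM scaling is applied — no TMM or other cross-library normalization.
A consequence is that fold changes of null genes are shifted when the
binding mass is unbalanced ("real estate" composition bias); the generator
reproduces this deliberately (see below).  Descriptive statistics
(`median_log2_fc`) use a pseudocount of 0.5 CPM in each ratio; inference
never uses pseudocounts, since the GLM handles zeros natively.

### Dispersion estimation

Per gene, a method-of-moments estimate is formed within each
(bait, fraction) replicate group: counts are rescaled to the group's mean
library size, and the excess of the sample variance over the
depth-corrected mean estimates φμ².  The squared-mean denominator uses the
unbiased estimator m² − v/n of μ² (the naive m² is inflated by Var(m̂)/n and
would bias φ downward by roughly φ/n).  Raw estimates are pooled over
groups and shrunk toward a prior — by default the global mean of the raw
estimates; optionally a running-median trend over gene abundance — with the
empirical-Bayes weight

    φ_shrunk = (w·φ_prior + d·φ_raw) / (w + d),  clipped at 0,

where d is the pooled residual degrees of freedom (4 for three replicates
of IP and Total) and w defaults to 25.  The heavy default shrinkage
reflects how little per-gene information 4 residual df carry: with noisy
per-gene estimates the convexity of the chi-square tail makes the LRT
anti-conservative in exactly the p-value range where FDR thresholds
operate, and stronger shrinkage brings tail calibration close to the
known-dispersion reference.  Users with designs carrying more residual df
(or expecting strong dispersion heterogeneity) should lower `prior_weight`.

### Count filter

The Total-library read filter keeps genes with strictly more than
`threshold` (default 20) reads in *every* pertinent Total library
(`mode="all_above"`).  An alternate reading — excluding only genes below
the threshold in *each* Total library — is available as
`mode="any_above"`; the two are not logically equivalent, and the strict
reading is the default.

## Synthetic data generator

The generator emulates a six-bait closed-loop RIP-seq study: baits
(eIF4E = hub/cap binder, eIF4G1, eIF4G2, Pab1 = poly(A) binder, Caf20 and
Eap1 = repressors), three biological replicates of paired IP and Total
libraries, 6,000 genes, mean library size 5 × 10⁶ reads with a lognormal
spread of CV 0.74 (matching the source dataset's stated depth spread), and
a single global NB dispersion φ = 0.1.

Per-gene relative abundances are lognormal (σ = 1.2 on the log scale),
normalized to proportions.  Genes are assigned to four co-binding groups or
background by a multinomial draw with default proportions
I/II/III/IV = 0.10/0.08/0.10/0.17 (≈45% differential mass, anchored to the
fraction of the transcriptome the motivating study clustered).  Sign
patterns per group: I — negative for every bait except the poly(A) binder
(≈0 there); II — positive for the repressors only; III — positive for the
closed-loop baits, negative for the repressors; IV — positive everywhere.
Magnitudes are `effect_size` (default 1.5 log2 units) jittered ±25%
(uniform) per gene × bait; baits listed together in
`shared_profile_baits` share their jitter stream and therefore carry
literally identical true profiles (used to emulate functionally redundant
isoform pairs; off by default because it makes the hub-relation predictors
singular).

The hub bait's enrichment is not assigned a pattern: it is generated from
the stoichiometric relation e(g, hub) = Σ_f β_f e(g, f) over the four
partner baits (default β = (1.0, 0.4, 0.2, −0.1)) plus Gaussian noise —
either a fixed sd (default 0.3) or calibrated so that the relation explains
a requested signal fraction of the hub profile's variance.  `n_outliers`
genes (default 2) receive an additional `outlier_shift` (default +3 log2)
on top of the relation; they are drawn from planted group II when it is
non-empty (the repressor-bound group, mirroring the autoregulatory biology
of the motivating system) and uniformly otherwise.

Counts: Total ~ NB(N · a_g, φ); IP ~ NB(N · a_g · 2^e / Z, φ), where Z
renormalizes the IP expected proportions to sum to 1.  This renormalization
(on by default; `renormalize_ip=False` disables it) is what induces the
composition bias: when the net planted binding mass is positive, null
genes' apparent log2(IP/Total) shifts below zero.  Note that because CPM
divides by observed column sums, a milder version of the bias arises even
with renormalization off.  Replicate-specific gene effects
(`replicate_effect_sd`, default 0 — the motivating data's replicates are
described as strongly correlated) multiply both members of a pair, which is
exactly the structure the paired design absorbs.

Covariates (ribosome occupancy in (0,1), poly(A)-tail length in
nucleotides) are strictly monotone maps of
strength · z + √(1−strength²) · ε with z the standardized poly(A)-binder
true enrichment (default strength 0.5).  Gene-set terms are drawn without
replacement; planted terms up-weight one truth group's genes by a
configurable odds factor (default 5).

Randomness: one master seed; independent child streams (truth, library
sizes, counts, covariates, gene sets) are spawned deterministically, so a
seed fixes every output byte.

### What the generator does *not* emulate

Real per-gene dispersion heterogeneity (a lognormal per-gene φ is not
modelled; the global-φ default makes the strong dispersion shrinkage
optimal by construction), positional coverage and read-level artifacts,
correlated gene-gene expression structure, annotation hierarchies among
gene sets, and abundance-dependent group membership (in the motivating
study the down-enriched group contains many of the most abundant mRNAs).
Passing recovery tests on this generator therefore demonstrates the
statistics are implemented correctly under the stated model, not that the
model captures every property of real RIP-seq libraries.

## Clustering

The differential set is genes significant at FDR < 0.01 in ≥ 1 bait that
also pass the Total-count filter in every bait.  Profiles are per-replicate
log2((IP_cpm + 0.5)/(Total_cpm + 0.5)) columns (one per bait × replicate,
as in the source study's heatmap; a per-bait median aggregation is
available).  Similarity is the uncentered Pearson coefficient
Σxy/√(Σx²Σy²) — cosine similarity, no mean-centering, so a profile's
overall sign and magnitude matter, not just its shape around its own mean.
The distance transform is d = 1 − s (simple and monotone; the metric
properties of √(2(1−s)) are not needed for average linkage ordering), and
the tree is built by average linkage via scipy's hierarchical clustering,
which the test suite verifies against a brute-force O(n³) re-averaging
oracle on hundreds of random instances.  Under exact distance ties scipy's
deterministic internal order decides the merge; ties have measure zero on
continuous profiles, so no bespoke tie rule is layered on top.  Leaf
ordering follows the standard recursion (subtree containing the smaller
minimum original index first).

Flat groups come from a `k`-cluster or height cut.  Because the four named
binding groups of the motivating study were curated manually from a
heatmap, a programmatic surrogate is provided: cut at k = 7 (the study's
cluster count) and assign each cluster to the archetype — I, II, III or
IV sign patterns over the baits — with the highest uncentered-Pearson
similarity to the cluster's mean per-bait profile.  The archetype table is
exposed (`group_archetypes`) and the matcher is tested on synthetic truth.

Known limitation: with no cross-library normalization and net-positive
binding mass, background transcripts acquire a shared negative apparent
enrichment whose direction is nearly parallel (cosine ≈ 0.95) to the
group-I archetype, so background and group I merge at any cut.  Recovery
of the four planted groups themselves is essentially perfect (adjusted
Rand index ≈ 0.99 restricted to planted genes), while the all-gene index
plateaus near 0.73.  Composition-corrected normalization would separate
them but is deliberately outside this pipeline's scope.

## Stoichiometric decomposition

Ordinary least squares of the hub profile on the partner profiles via a QR
decomposition (numerically stable; explicit rank check on |diag R| with a
`CollinearityError` naming the dependent columns).  An intercept is fitted
by default: the strict linear-combination form has no intercept, but
composition shifts move every profile's baseline, and a free intercept
absorbs that (the no-intercept form is available).  R² = 1 − RSS/TSS (TSS
centred when an intercept is present).  Leverages are hat-matrix diagonals
(row sums of squares of Q); jackknife residuals are externally studentized
residuals computed with the closed-form deletion identity
s²₍ᵢ₎ = (RSS − e²ᵢ/(1−hᵢ))/(n−p−1), t_i = e_i/(s₍ᵢ₎√(1−hᵢ)) — verified in
the tests against literal leave-one-out refits.  When RSS is numerically
zero the jackknife residuals are defined as zero.  Outliers: two-sided t
test Bonferroni-corrected across genes (the motivating analysis flagged
outliers by eye; the full |t| ranking is always returned so any cutoff can
be applied).  The fit records the design condition number and pairwise
predictor correlations, because near-collinear partner pairs (e.g.
redundant scaffold isoforms) make individual coefficients unstable while
their sum remains identified; on count-estimated profiles, measurement
error additionally attenuates and mixes the coefficients, which is why
parameter-recovery benchmarks are run on true profiles and end-to-end runs
are judged on outlier ranking rather than coefficient values.

## Set statistics

Hypergeometric tails (p_over = P(X ≥ k), p_under = P(X ≤ k)) per term
against a user-supplied universe — by default the genes passing the
Total-count filter, not the whole annotation — with BH FDR within each
direction.  The two-sided Fisher exact test (sum of all fixed-margin tables
with probability ≤ observed) compares a cluster against the rest of the
universe; its one-sided variant coincides with the hypergeometric upper
tail, an identity asserted in the tests.  Cross-cluster heterogeneity of a
term is a Pearson chi-square on the groups × (in-term, out-of-term) table
with g−1 df (empty groups dropped with a warning; a warning is logged when
any expected count is below 5).  Note that merging two groups with
identical in-term proportions preserves the statistic but changes the
degrees of freedom, hence the p-value.  Covariates are compared with the
two-sided Wilcoxon rank-sum test — exact enumeration when n_A + n_B ≤ 20
with no ties, otherwise the normal approximation with tie and continuity
corrections.  Box-plot summaries use type-7 (linear interpolation)
quartiles and 1.5 × IQR whiskers.  Multiple-testing correction is
Benjamini–Hochberg step-up throughout, with missing p-values passed
through untouched.

## Pipeline, reproducibility and problem sizes

`run_all` executes enrichment → interactions → clustering → stoichiometry →
set statistics, persisting each stage as TSV, then writes a manifest
(seed, thresholds, per-stage row counts and elapsed times, content hashes
of the enrichment tables) and a markdown report with the heatmap, a
pairwise scatter grid, the residual plot and the top-outlier table.  The
report generator reads only the persisted TSVs, so `riploop report` can
rebuild it without recomputation.  Exit codes: 0 success, 2 configuration
error, 3 data validation error, 4 stage failure.

The evaluation scenarios (`riploop.evaluation`) run at desk scale — 2,000
genes for calibration and clustering scenarios, 3,000 for the
stoichiometric ones, 20–50 replicate simulations where a rate is measured —
sizes chosen so the full evaluation completes in minutes on a single CPU
while keeping Monte-Carlo error well below the decision margins.
Calibration checks report the median over five independent simulations to
damp binomial noise in single-run rates.
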