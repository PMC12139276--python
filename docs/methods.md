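# Methods

## Model

A microbiota sample is modelled as a convex mixture of k latent guilds
(enterosignatures). With X the genus x sample matrix of relative
abundances (every column sums to 1), the factorization X ≈ W H is fitted
under the generalized Kullback–Leibler divergence with multiplicative
updates, optionally with elastic-net penalties on both factors
(`l1_ratio = 1`, i.e. pure L1, is the convention; `alpha_W = alpha_H = 0`
by default so the unregularized optimum is reproducible). Because KL-NMF
has a per-component scale indeterminacy, the reported W is rescaled
column-stochastic with H compensated, leaving W H unchanged; raw factors
are kept alongside.

Multiplicative updates guarantee a non-increasing loss at every step,
which the test suite asserts on full traces. Fits restart from
`n_restarts` seeded random initializations (restart r uses seed
`seed + r`), and the lowest-loss run wins. Restarts are advanced as one
batched tensor so the whole restart loop runs inside numpy. Default
convergence: relative loss change < 1e-6 between checks every 10
iterations, max 2000 iterations; reconstructions are floored at 1e-12
inside updates to avoid division by zero.

## Rank selection

Blocked bi-cross validation (Owen–Perry style): rows and columns are
shuffled and split 3 x 3; each of the nine blocks A is held out once per
repetition. With X = [[A, B], [C, D]], an NMF is fitted on D, activities
for held-out samples are projected from C (W frozen), weights for
held-out genera from B (H frozen, via the transpose symmetry of KL
updates), and A is predicted as W_B H_C. Held-out KL error, explained
variance and total cosine are recorded; the same blocks are scored at
every k so curves are paired across ranks. The selected rank is the
smallest k whose median held-out cosine lies within `plateau_tol = 0.01`
of the best median among all larger k; a curve still rising at the
largest k returns that k with a "no plateau" warning.

Numerical choices inside bi-cross validation: fits and projections use
single precision, 5 restarts, at most 200 iterations and tolerance 1e-4.
Held-out medians are compared at the 1e-2 scale, and these settings
reproduce the float64/tol 1e-6 curves to three decimals at roughly a
quarter of the cost; the final full-data fit always runs in float64 at
tol 1e-6. Default scan: k = 2..8 with 20 repetitions on desk scale
(9 x 20 = 180 scored blocks per k); both the k range and the repetition
count are configurable up to the 2..30 x 200 schedule used for real
studies.

## Preprocessing

The QC chain, in order: (1) remove features present in fewer than 2
samples AND carrying less than 1e-6 of total counts — the conjunction as
conventionally stated; a flag switches to the OR rule. The abundance
clause uses the total counts before sample exclusion (a flag reverses
the order). (2) drop samples with fewer than 10,000 reads (strict).
(3) collapse ASVs to genus using the taxonomy map; unresolved features
are pooled into a labelled `unclassified:<highest-resolved-rank>` bucket
rather than dropped, so column totals still reflect the whole community
(flag to drop instead). (4) keep genera present (count > 0) in strictly
more than 20% of samples — genus collapse precedes the prevalence rule.
(5) divide each column by its sum. Presence means count > 0 throughout.

## Characterization

Contributions are columns of W normalized to 1; assignment probabilities
are rows of W normalized to 1 (all-zero rows are flagged, not
normalized). The driver of an ES is the genus with the largest
contribution, ties broken lexicographically with a warning; ES names are
"ES-" plus the driver's first four letters, with numeric suffixes on
collision. Per-sample ES fractions are normalized H columns — times 100
they read as the percentage of a sample's community each ES explains.
Group summaries rank ES by mean per-sample fraction (mean chosen over
median for additivity of the cumulative rule) and report the shortest
prefix covering 90% of the community, the primary ES, and each ES's
frequency of membership in those minimal sets. Profiles from different
fits (ages, ranks, or simulation truth) are compared by Hungarian
assignment maximizing summed cosine similarity on the shared genus set.

## Association

Each trait is regressed on one ES fraction at a time (OLS with
intercept, two-sided t test on the slope; missing traits dropped
pairwise; constant fractions flagged degenerate). Body weight is first
residualized on age; other traits are used raw and unadjusted by
default, with covariates available as an option. Raw p values are
primary — no multiple-testing correction is applied across ES–trait
pairs — with a Benjamini–Hochberg column emitted alongside. The
stress-vs-control composition contrast reports per-ES group means and
differences with a descriptive two-sample t test.

## Heritability

Per ES, the animal model y = Xβ + u + e with u ~ N(0, G σ²ₐ) and the
VanRaden G = ZZ′/(2Σpⱼ(1−pⱼ)), Z the allele-frequency-centred dosage
matrix. SNP QC: drop MAF < 0.05 or missingness > 0.10 (both strict on
the stated side), optional keep-list for mapped markers, then mean
imputation (2pⱼ) of remaining missing dosages. Allele frequencies are
computed from the post-QC data by default; external frequencies can be
supplied (and make G stable under duplicating individuals).

Variance components are Gibbs-sampled with a flat prior on β and
scaled-inverse-chi-square priors on both variances (default df = 5 with
the prior mode of each variance at half the phenotypic variance,
mirroring the defaults of standard Bayesian GBLUP software; both
configurable). The sampler rotates into the eigenbasis G = U D U′ where
genetic values decorrelate, so each round is O(n) after one
eigendecomposition; eigenvalues at numerical zero pin their components
to zero. A direct (naive) sampler that solves an n x n system per round
is included purely as an independent cross-check and agrees with the
eigen sampler on small problems. h² = σ²ₐ/(σ²ₐ+σ²ₑ) is recorded per
draw; summaries report the posterior mean, SD and the shortest-window
(highest posterior density) 95% interval, which is deterministic given
the draws. Chains retain draws after burn-in at the thinning interval;
the desk-scale default is 20,000 iterations (burn-in 500, thin 5), and
the 100,000/500/5 schedule used on real data is available — a warning is
emitted whenever burn-in is below 1% of the chain, since such short
burn-ins are unusual.

Age enters the fixed effects as a centred covariate, batch and sex as
factor dummies (first level dropped). ES fractions are analysed
untransformed by default; a transform hook exists for e.g. logit scales.

## Synthetic data

The generator emulates the study conditions end to end:

* **Guilds.** W has one driver genus per guild with weight drawn in
  [driver_weight, 1.2·driver_weight] (default 0.5) and the remaining
  mass Dirichlet-spread over a random subset of other genera (default
  sparsity 0.5, i.e. half the non-driver genera at zero); non-driver
  weights are kept strictly below the driver's so the driver is always
  the unique argmax, while still allowing near-co-dominant pairs.
* **Samples.** Guild activities are symmetric Dirichlet(1,…,1) mixtures;
  counts are multinomial draws from W H at a log-normal depth (median
  20,000 reads, log-sd 0.35) so the depth filter is exercised by the
  lower tail. Multinomial-on-low-rank-mean is the minimal noise model
  consistent with 16S count data; it deliberately omits overdispersion
  beyond mixing variation, contamination, and taxonomic misassignment.
  The stress contrast shifts the Dirichlet *mean* of designated guilds
  for the stressed group (renormalized at constant total concentration),
  so group mean activities differ by the stated shift in expectation.
* **Genotypes.** Independent HWE SNPs with Uniform(0.05, 0.5) allele
  frequencies and optional missingness; no linkage or population
  structure.
* **Heritable phenotypes.** A random causal subset (default 100 SNPs)
  with Gaussian effects on standardized dosages, rescaled so
  var(u)/(var(u)+var(e)) equals the target h² with unit total random
  variance; batch/sex/age effects are added on top when a design is
  supplied. Traits are linear in guild activities plus Gaussian noise;
  slopes are free parameters (the source analyses report p values, not
  effect sizes, so no calibration target exists).

What passing tests show — and do not show. Rank and guild recovery on
this generator demonstrate that the estimator chain is correct under its
own assumptions (low-rank mixing + multinomial sampling); real 16S data
add overdispersion and taxonomic noise that can flatten the bi-cross
validation plateau. Likewise, heritability recovery uses structure-free
genotypes, for which the h² likelihood is intrinsically flat: the
sampling SD of ĥ² is ≈ √(2m)/n (≈ 0.16 at n = 400, m = 2,000), so
posterior means carry prior influence of the same order, a null
phenotype cannot be distinguished sharply from moderate heritability,
and per-seed point-estimate errors of ±0.15–0.2 are expected even though
HPD intervals remain calibrated. Real SNP panels with linkage and family
structure identify h² far more strongly (the posterior SDs of ~0.06–0.09
reported for real pig data are unreachable in this synthetic regime).
This limitation is a property of the simulation design (structure-free
genotypes are a stated non-goal to keep the generator simple), not of
the sampler, which matches a direct multivariate sampler draw-for-draw
in distribution on small problems.

## Pipeline

`enteroguild run --config run.yaml` executes
simulate → preprocess → rank → fit → characterize → assoc → h2. Every
stage writes its outputs plus a provenance JSON (parameters, seed,
SHA-256 of inputs); reruns skip stages whose provenance matches and
recompute everything downstream of any changed file. All stage defaults
above are overridable from the YAML; config errors exit with status 2
naming the offending key, stage failures with status 1.

## Problem sizes

Defaults are chosen for a single desk CPU: bi-cross validation at
k = 2..8 with 20 repetitions on an 80 x 400 table (~1 minute), full fits
with 20–100 restarts (seconds), Gibbs chains of 20,000 (seconds after
the one-time eigendecomposition). The study-scale schedules (k to 30,
200 repetitions, 100,000-iteration chains) are plain configuration
changes.
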