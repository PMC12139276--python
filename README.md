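# enteroguild

Enterosignature inference for gut microbiota count tables: decompose a
genus-level abundance matrix into co-occurring bacterial guilds, choose the
number of guilds by bi-cross validation, relate guild fractions to host
traits, and estimate the SNP-based heritability of guild abundance.

## The problem

16S rRNA surveys of the pig (or any mammalian) gut yield a table of counts
per taxon per animal. Discrete "enterotype" clustering hides the fact that
most communities are mixtures. *Enterosignatures* (ES) instead model each
sample as a convex combination of a small number of microbial guilds —
groups of genera that rise and fall together. Given a column-stochastic
genus x sample matrix **X**, the package fits

    X ≈ W H,   W ≥ 0 (genus weights per ES),  H ≥ 0 (ES activity per sample)

by multiplicative updates under the generalized Kullback–Leibler divergence

    D(X‖WH) = Σᵢⱼ [ xᵢⱼ log(xᵢⱼ/(WH)ᵢⱼ) − xᵢⱼ + (WH)ᵢⱼ ],

with many seeded restarts. The rank k is selected by blocked 3×3
bi-cross validation: shuffle rows and columns, hold out each of the nine
row-block × column-block submatrices A in turn, train on the complement,
predict A from projections of the flanking blocks, and pick the smallest k
whose median held-out cosine similarity reaches a plateau.

Each ES is summarized by its *driver* genus (largest column weight), the
genera contributing > 4%, and per-sample ES fractions (normalized columns
of H). Guild fractions are then regressed on host traits (growth, feed
efficiency, hair cortisol) one ES at a time, and their heritability is
estimated with the animal-model GBLUP

    y = Xβ + u + e,  u ~ N(0, G σ²ₐ),  e ~ N(0, I σ²ₑ),
    G = ZZ′ / (2 Σⱼ pⱼ(1−pⱼ))   (VanRaden),
    h² = σ²ₐ / (σ²ₐ + σ²ₑ),

sampled by a Gibbs chain that works in the eigenbasis of G, and reported as
posterior mean, SD and the 95% highest-posterior-density interval.

A synthetic-data module generates guild-structured count tables, HWE SNP
genotypes and linearly coupled traits with known ground truth, so the whole
pipeline is testable end to end without any external download.

## Worked example

```python
import numpy as np
from enteroguild import synthetic, preprocess, rank, nmf, characterize

truth = synthetic.simulate_guilds(n_genera=80, k=5, driver_weight=0.5,
                                  sparsity=0.5, seed=1)
table, samples = synthetic.simulate_samples(truth, n_samples=400, seed=2)
X, qc = preprocess.make_nmf_input(table)      # QC chain -> 75 genera x 392 samples

res = rank.bicv_curve(X.X, k_range=range(2, 9), n_repetitions=20, seed=1)
print(np.round(res.medians("cosine_total"), 3))
print("selected k =", rank.select_rank(res))

dec = nmf.fit_nmf(X, k=5, n_restarts=20, seed=1)
print("explained variance:", round(dec.metrics["explained_variance"], 3))
prof = characterize.make_profile(dec)
print("drivers:", prof.driver_genus)
```

prints (seed 1):

```
[0.742 0.758 0.888 0.999 0.999 0.999 0.999]
selected k = 5
explained variance: 1.0
drivers: ['g002', 'g035', 'g075', 'g039', 'g058']
```

The held-out cosine medians rise steeply until k = 5 and plateau there, so
the first-plateau rule recovers the simulated number of guilds; the k = 5
full fit explains essentially all variance of this (deeply sequenced,
noise-dominated-only-by-sampling) synthetic table, and the five fitted
drivers are exactly the five simulated driver genera
(`truth.driver_ids`).

The same steps are available from the shell:

```bash
enteroguild simulate --out demo --seed 1
enteroguild preprocess --counts demo/simulate/counts.tsv --no-collapse --out demo/pre
enteroguild rank --table demo/pre/relabund.tsv --kmin 2 --kmax 8 --reps 20 --out demo/rank
enteroguild fit  --table demo/pre/relabund.tsv --k 5 --out demo/fit
enteroguild run  --config run.yaml           # full pipeline with caching
```

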