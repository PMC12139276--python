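"""Guild-structured synthetic data with known ground truth.

Every downstream stage of the pipeline (preprocessing, NMF, rank
selection, characterization, association, heritability) is validated by
recovery tests against data generated here.  The generative model:

* A genus x k weight matrix ``W_true`` with one dominant "driver" genus
  per guild and the remaining mass spread over a sparse subset of genera
  (mirroring real enterosignatures, where one genus dominates but several
  co-occur).
* Per-sample guild activities ``H_true`` drawn from a Dirichlet, so each
  sample is a convex mixture of guilds; expected genus relative
  abundances are ``W_true @ H_true``.
* Integer counts drawn multinomially at a log-normal read depth — the
  minimal noise model consistent with 16S amplicon count data.
* SNP genotypes under Hardy-Weinberg equilibrium with uniform allele
  frequencies, no linkage; additive genetic values from a random causal
  subset give a phenotype with prescribed narrow-sense heritability.
* Host traits linearly coupled to guild activities, with an optional
  stress contrast implemented as a shift of the Dirichlet mean for the
  stressed group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import CountTable, GenotypeMatrix

__all__ = [
    "GuildTruth",
    "SampleTruth",
    "GeneticTruth",
    "simulate_guilds",
    "simulate_samples",
    "simulate_genotypes",
    "simulate_heritable_es",
    "simulate_traits",
]


@dataclass
class GuildTruth:
    """Ground-truth guild weights: each column is one guild, sums to 1,
    and has a unique argmax (its driver genus)."""

    W_true: np.ndarray  # genera x k
    driver_ids: list
    k_true: int
    genus_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.W_true = np.asarray(self.W_true, dtype=float)
        if np.any(self.W_true < 0):
            raise ValueError("W_true must be nonnegative")
        if not np.allclose(self.W_true.sum(axis=0), 1.0):
            raise ValueError("W_true columns must sum to 1")
        if not self.genus_ids:
            self.genus_ids = [f"g{i:03d}" for i in range(self.W_true.shape[0])]
        # unique argmax per column, and it must be the declared driver
        for j in range(self.k_true):
            col = self.W_true[:, j]
            top = np.argmax(col)
            if (col == col[top]).sum() > 1:
                raise ValueError(f"guild {j} has a tied argmax")
            if self.genus_ids[top] != self.driver_ids[j]:
                raise ValueError(f"guild {j} driver mismatch")
        if len(set(self.driver_ids)) != self.k_true:
            raise ValueError("drivers must be distinct")

    @property
    def guild_names(self) -> list:
        return list(self.driver_ids)


@dataclass
class SampleTruth:
    """Ground-truth per-sample guild activities and design labels."""

    H_true: np.ndarray  # k x samples, columns sum to 1
    group_labels: pd.DataFrame  # per-sample batch / sex / group
    depth: np.ndarray
    guild_names: list

    def __post_init__(self):
        self.H_true = np.asarray(self.H_true, dtype=float)
        if not np.allclose(self.H_true.sum(axis=0), 1.0):
            raise ValueError("H_true columns must sum to 1")
        self.depth = np.asarray(self.depth)
        if np.any(self.depth < 1):
            raise ValueError("depth must be >= 1")


@dataclass
class GeneticTruth:
    """Ground truth for the heritability simulation."""

    u_true: np.ndarray
    h2_true: float
    causal_effects: np.ndarray  # per-SNP, zero for non-causal markers


def simulate_guilds(
    n_genera: int,
    k: int,
    driver_weight: float = 0.5,
    sparsity: float = 0.5,
    seed: int = 0,
) -> GuildTruth:
    """Draw a guild weight matrix with one driver genus per guild.

    Each column gives its driver a weight drawn uniformly in
    ``[driver_weight, min(1, 1.2 * driver_weight)]``; the remaining mass is
    spread (Dirichlet) over a random subset of the other genera, where
    ``sparsity`` is the expected fraction of non-driver genera left at
    zero.  Non-driver weights are kept strictly below the driver's so the
    driver is always the unique argmax.
    """
    if k < 2 or n_genera < k:
        raise ValueError(f"need n_genera >= k >= 2, got n_genera={n_genera}, k={k}")
    if not (0 < driver_weight < 1):
        raise ValueError("driver_weight must be in (0, 1)")
    if not (0 <= sparsity < 1):
        raise ValueError("sparsity must be in [0, 1)")
    rng = np.random.default_rng(seed)
    genus_ids = [f"g{i:03d}" for i in range(n_genera)]
    drivers = rng.choice(n_genera, size=k, replace=False)
    W = np.zeros((n_genera, k))
    n_support = max(1, int(round((1 - sparsity) * (n_genera - 1))))
    for j in range(k):
        dw = float(rng.uniform(driver_weight, min(1.0, 1.2 * driver_weight)))
        dw = min(dw, 1.0 - 1e-6)
        others = np.setdiff1d(np.arange(n_genera), drivers[j : j + 1])
        rest = 1.0 - dw
        cap = 0.99 * dw
        # support must be large enough that non-driver mass can stay below the driver
        size = min(others.size, max(n_support, int(np.ceil(rest / cap)) + 1))
        support = rng.choice(others, size=size, replace=False)
        weights = rng.dirichlet(np.ones(size)) * rest
        if weights.max() >= cap:
            # blend toward the uniform allocation until every entry is capped
            uniform = np.full(size, rest / size)
            t = 0.9 * (cap - uniform[0]) / (weights.max() - uniform[0])
            weights = t * weights + (1 - t) * uniform
        W[support, j] = weights
        W[drivers[j], j] = dw
        W[:, j] /= W[:, j].sum()
    return GuildTruth(
        W_true=W,
        driver_ids=[genus_ids[d] for d in drivers],
        k_true=k,
        genus_ids=genus_ids,
    )


def _assign_groups(n_samples: int, n_batches: int, rng) -> pd.DataFrame:
    batch = np.array([f"batch{i % n_batches + 1}" for i in range(n_samples)])
    rng.shuffle(batch)
    sex = rng.choice(["M", "F"], size=n_samples)
    group = np.array(["control"] * (n_samples - n_samples // 2) + ["stress"] * (n_samples // 2))
    rng.shuffle(group)
    age = np.round(rng.normal(60.0, 8.0, size=n_samples)).astype(int)
    return pd.DataFrame(
        {
            "sample_id": [f"s{j:04d}" for j in range(n_samples)],
            "batch": batch,
            "sex": sex,
            "group": group,
            "age": age,
        }
    )


def simulate_samples(
    truth: GuildTruth,
    n_samples: int,
    dirichlet_concentration=None,
    depth_log_mean: float = float(np.log(20_000)),
    depth_log_sd: float = 0.35,
    seed: int = 0,
    stress_shift: dict | None = None,
    n_batches: int = 6,
) -> tuple[CountTable, SampleTruth]:
    """Draw guild mixtures and multinomial counts at log-normal depth.

    Per sample j, ``H[:, j] ~ Dirichlet(concentration)`` and counts are
    multinomial with probability vector ``W_true @ H[:, j]`` at a depth
    drawn log-normally (median ``exp(depth_log_mean)``, by default 20,000
    reads so the tail exercises the 10,000-read sample filter).

    ``stress_shift`` maps guild name -> additive shift applied to the
    Dirichlet *mean* for samples in the stress group (renormalized,
    keeping the same total concentration), so group mean activities
    differ by the stated shift in expectation.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    k = truth.k_true
    conc = (
        np.ones(k)
        if dirichlet_concentration is None
        else np.asarray(dirichlet_concentration, dtype=float)
    )
    if conc.shape != (k,) or np.any(conc <= 0):
        raise ValueError("concentration must be length k with positive entries")
    rng = np.random.default_rng(seed)
    labels = _assign_groups(n_samples, n_batches, rng)

    conc_stress = conc
    if stress_shift:
        names = truth.guild_names
        unknown = [g for g in stress_shift if g not in names]
        if unknown:
            raise ValueError(f"unknown guild name(s) in stress_shift: {unknown}")
        mean = conc / conc.sum()
        shift = np.zeros(k)
        for g, d in stress_shift.items():
            shift[names.index(g)] = d
        mean_s = np.maximum(mean + shift, 1e-9)
        mean_s /= mean_s.sum()
        conc_stress = mean_s * conc.sum()

    H = np.empty((k, n_samples))
    stressed = labels["group"].to_numpy() == "stress"
    for j in range(n_samples):
        c = conc_stress if (stress_shift and stressed[j]) else conc
        H[:, j] = rng.dirichlet(c)

    P = truth.W_true @ H  # expected relative abundances, columns sum to 1
    depth = np.maximum(1, np.round(rng.lognormal(depth_log_mean, depth_log_sd, n_samples))).astype(
        np.int64
    )
    counts = np.empty((truth.W_true.shape[0], n_samples), dtype=np.int64)
    for j in range(n_samples):
        counts[:, j] = rng.multinomial(depth[j], P[:, j])

    table = CountTable(
        counts=counts,
        feature_ids=truth.genus_ids,
        sample_ids=list(labels["sample_id"]),
        taxonomy={g: g for g in truth.genus_ids},
    )
    sample_truth = SampleTruth(
        H_true=H,
        group_labels=labels,
        depth=depth,
        guild_names=truth.guild_names,
    )
    return table, sample_truth


def simulate_genotypes(
    n_ind: int,
    n_snp: int,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Independent HWE genotypes with Uniform(maf_low, maf_high) frequencies.

    The drawn per-SNP frequencies are attached to the returned object as
    ``true_freqs`` for recovery tests.  No linkage or population
    structure is simulated.
    """
    if not (0 <= maf_low <= maf_high <= 0.5):
        raise ValueError("need 0 <= maf_low <= maf_high <= 0.5")
    if not (0 <= missing_rate < 1):
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    p = rng.uniform(maf_low, maf_high, size=n_snp)
    dos = rng.binomial(2, p[None, :], size=(n_ind, n_snp)).astype(float)
    if missing_rate > 0:
        mask = rng.random((n_ind, n_snp)) < missing_rate
        dos[mask] = np.nan
    geno = GenotypeMatrix(
        dosages=dos,
        snp_ids=[f"snp{j:05d}" for j in range(n_snp)],
        individual_ids=[f"s{j:04d}" for j in range(n_ind)],
    )
    geno.true_freqs = p
    return geno


def simulate_heritable_es(
    genotypes: GenotypeMatrix,
    h2: float,
    n_causal: int = 100,
    fixed_design: pd.DataFrame | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, GeneticTruth]:
    """Phenotype y = X beta + u + e with prescribed heritability.

    ``u`` is built from ``n_causal`` randomly chosen SNPs with Gaussian
    effects on centered/scaled dosages, rescaled so that
    ``var(u) / (var(u) + var(e)) = h2`` in expectation with total random
    variance 1.  ``fixed_design`` (columns among batch, sex, age) adds
    systematic effects on top.
    """
    if not (0 <= h2 < 1):
        raise ValueError("h2 must be in [0, 1)")
    if n_causal > genotypes.n_snps:
        raise ValueError("n_causal exceeds number of SNPs")
    rng = np.random.default_rng(seed)
    n = genotypes.n_individuals
    causal_effects = np.zeros(genotypes.n_snps)

    if h2 > 0:
        if n_causal < 1:
            raise ValueError("n_causal must be >= 1 when h2 > 0")
        idx = rng.choice(genotypes.n_snps, size=n_causal, replace=False)
        M = genotypes.dosages[:, idx]
        M = np.where(np.isfinite(M), M, np.nanmean(M, axis=0))
        p = M.mean(axis=0) / 2.0
        sd = np.sqrt(2 * p * (1 - p))
        sd[sd == 0] = 1.0
        Z = (M - 2 * p) / sd
        b = rng.normal(size=n_causal)
        u = Z @ b
        scale = np.sqrt(h2 / max(u.var(), 1e-12))
        u *= scale
        causal_effects[idx] = b * scale
    else:
        u = np.zeros(n)

    e = rng.normal(scale=np.sqrt(1 - h2), size=n)
    y = u + e

    if fixed_design is not None:
        for col in fixed_design.columns:
            if col == "sample_id":
                continue
            vals = fixed_design[col]
            if vals.dtype.kind in "ifu" and vals.nunique() > 8:
                # covariate (e.g. age): modest standardized slope
                x = (vals - vals.mean()) / max(vals.std(), 1e-12)
                y = y + 0.3 * x.to_numpy()
            else:
                levels = {lv: eff for lv, eff in zip(vals.unique(), rng.normal(0, 0.3, vals.nunique()))}
                y = y + vals.map(levels).to_numpy()

    return y, GeneticTruth(u_true=u, h2_true=h2, causal_effects=causal_effects)


def simulate_traits(
    sample_truth: SampleTruth,
    effect_spec: list,
    noise_sd: float = 0.1,
    seed: int = 0,
    intercept: float = 0.0,
) -> pd.DataFrame:
    """Traits linearly coupled to guild activities.

    ``effect_spec`` is a list of ``(guild_name, trait_name, slope)``; each
    trait is ``intercept + sum(slope * H[guild]) + N(0, noise_sd)``.
    Returns a table indexed like the sample labels, one column per trait.
    """
    rng = np.random.default_rng(seed)
    names = sample_truth.guild_names
    n = sample_truth.H_true.shape[1]
    traits: dict = {}
    for guild, trait, slope in effect_spec:
        if guild not in names:
            raise ValueError(f"unknown guild name: {guild!r}")
        if not np.isfinite(slope):
            raise ValueError("slopes must be finite")
        traits.setdefault(trait, np.full(n, float(intercept)))
        traits[trait] = traits[trait] + slope * sample_truth.H_true[names.index(guild)]
    out = pd.DataFrame({"sample_id": sample_truth.group_labels["sample_id"]})
    for trait, vals in traits.items():
        out[trait] = vals + rng.normal(scale=noise_sd, size=n)
    return out
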