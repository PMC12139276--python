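"""Core data containers shared across the pipeline.

The pipeline moves through a small number of well-defined states: an
integer feature-by-sample count table, a column-stochastic genus
relative-abundance matrix, a nonnegative factor pair (W, H) describing
enterosignatures, genotype dosages, and posterior draws from the
heritability sampler.  Each state is a lightweight dataclass wrapping
numpy arrays plus identifier lists, with validation at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "RelAbundanceMatrix",
    "ESDecomposition",
    "BicvResult",
    "ESProfile",
    "SampleESFractions",
    "GenotypeMatrix",
    "GRM",
    "HeritabilityPosterior",
]


def _check_unique(ids, what: str) -> list:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")
    return ids


@dataclass
class CountTable:
    """Feature x sample table of nonnegative integer counts.

    ``taxonomy`` optionally maps each feature id to a genus name; it is
    required for :func:`enteroguild.preprocess.collapse_to_genus`.
    """

    counts: np.ndarray
    feature_ids: list
    sample_ids: list
    taxonomy: dict | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix (features x samples)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        self.feature_ids = _check_unique(self.feature_ids, "feature")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_depths(self) -> np.ndarray:
        """Total counts per sample (column sums)."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, taxonomy: dict | None = None) -> "CountTable":
        return cls(
            counts=df.to_numpy(),
            feature_ids=list(df.index),
            sample_ids=list(df.columns),
            taxonomy=taxonomy,
        )


@dataclass
class RelAbundanceMatrix:
    """Genus x sample relative abundances; every column sums to one."""

    X: np.ndarray
    genus_ids: list
    sample_ids: list

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if np.any(self.X < 0):
            raise ValueError("relative abundances must be nonnegative")
        colsums = self.X.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            bad = np.flatnonzero(np.abs(colsums - 1.0) > 1e-9)
            raise ValueError(f"columns do not sum to 1 (first offenders: {bad[:5]})")
        self.genus_ids = _check_unique(self.genus_ids, "genus")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        if self.X.shape != (len(self.genus_ids), len(self.sample_ids)):
            raise ValueError("X shape does not match identifier lists")

    @property
    def n_genera(self) -> int:
        return self.X.shape[0]

    @property
    def n_samples(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.genus_ids, columns=self.sample_ids)


@dataclass
class ESDecomposition:
    """Fitted NMF factor pair X ~ W @ H with fit diagnostics.

    W holds per-genus weights of each enterosignature (genera x k), H the
    per-sample enterosignature activities (k x samples).  ``loss`` is the
    final generalized Kullback-Leibler divergence of the best restart.
    """

    W: np.ndarray
    H: np.ndarray
    k: int
    loss: float
    n_iter: int
    seed: int
    genus_ids: list
    sample_ids: list
    metrics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        if np.any(self.W < 0) or np.any(self.H < 0):
            raise ValueError("factors must be nonnegative")
        if self.W.shape[1] != self.k or self.H.shape[0] != self.k:
            raise ValueError("factor shapes inconsistent with rank k")
        if self.loss < -1e-12:
            raise ValueError("loss must be nonnegative")

    def reconstruction(self) -> np.ndarray:
        return self.W @ self.H


@dataclass
class BicvResult:
    """Held-out metric distributions from blocked bi-cross validation.

    ``per_k[k]`` maps each metric name to an array of length
    ``n_repetitions * row_folds * col_folds`` (one entry per held-out
    block per repetition).
    """

    k_values: list
    per_k: dict
    row_folds: int
    col_folds: int
    n_repetitions: int

    def __post_init__(self):
        expected = self.n_repetitions * self.row_folds * self.col_folds
        for k in self.k_values:
            for metric, arr in self.per_k[k].items():
                arr = np.asarray(arr, dtype=float)
                if arr.size != expected:
                    raise ValueError(
                        f"k={k} metric {metric}: {arr.size} values, expected {expected}"
                    )
                if not np.all(np.isfinite(arr)):
                    raise ValueError(f"non-finite bicv metric for k={k}, {metric}")
                self.per_k[k][metric] = arr

    def medians(self, metric: str) -> np.ndarray:
        return np.array([np.median(self.per_k[k][metric]) for k in self.k_values])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (k, repetition, fold, metric, value)."""
        rows = []
        n_blocks = self.row_folds * self.col_folds
        for k in self.k_values:
            for metric, arr in self.per_k[k].items():
                for i, v in enumerate(arr):
                    rows.append(
                        {
                            "k": k,
                            "repetition": i // n_blocks,
                            "fold": i % n_blocks,
                            "metric": metric,
                            "value": v,
                        }
                    )
        return pd.DataFrame(rows)


@dataclass
class ESProfile:
    """Interpretable view of W: drivers, contributions, assignment probabilities."""

    es_names: list
    driver_genus: list
    contributions: np.ndarray  # genus x k, columns sum to 1
    assignment_prob: np.ndarray  # genus x k, rows sum to 1 (zero rows flagged)
    genus_ids: list
    zero_weight_genera: list = field(default_factory=list)

    def contributions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.contributions, index=self.genus_ids, columns=self.es_names)

    def assignment_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.assignment_prob, index=self.genus_ids, columns=self.es_names)


@dataclass
class SampleESFractions:
    """Per-sample enterosignature fractions (columns of normalized H)."""

    fractions: np.ndarray  # k x samples
    sample_ids: list
    es_names: list

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        if np.any(self.fractions < -1e-12) or np.any(self.fractions > 1 + 1e-12):
            raise ValueError("fractions must lie in [0, 1]")
        if not np.allclose(self.fractions.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("fraction columns must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fractions, index=self.es_names, columns=self.sample_ids)


@dataclass
class GenotypeMatrix:
    """SNP dosages (individuals x SNPs), 0/1/2 with NaN for missing."""

    dosages: np.ndarray
    snp_ids: list
    individual_ids: list

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x SNPs)")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must be in {0, 1, 2} or missing")
        self.snp_ids = _check_unique(self.snp_ids, "SNP")
        self.individual_ids = _check_unique(self.individual_ids, "individual")
        if self.dosages.shape != (len(self.individual_ids), len(self.snp_ids)):
            raise ValueError("dosage shape does not match identifier lists")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_freqs(self) -> np.ndarray:
        """Frequency of the counted allele per SNP, from non-missing dosages."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def minor_allele_freqs(self) -> np.ndarray:
        p = self.allele_freqs()
        return np.minimum(p, 1.0 - p)

    def missing_rates(self) -> np.ndarray:
        return np.mean(~np.isfinite(self.dosages), axis=0)


@dataclass
class GRM:
    """VanRaden genomic relationship matrix with its scaling constant."""

    G: np.ndarray
    individual_ids: list
    scaling: float  # 2 * sum_j p_j (1 - p_j)

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=float)
        n = self.G.shape[0]
        if self.G.shape != (n, n):
            raise ValueError("G must be square")
        if not np.allclose(self.G, self.G.T, atol=1e-10):
            raise ValueError("G must be symmetric")

    def eigendecompose(self, tol: float = -1e-8):
        """Eigenvalues/vectors; raises if G is indefinite beyond tolerance."""
        vals, vecs = np.linalg.eigh(self.G)
        if vals.min() < tol * max(1.0, vals.max()):
            raise ValueError(
                "G is not positive semidefinite beyond tolerance; "
                "consider adding a small diagonal jitter"
            )
        return vals, vecs


@dataclass
class HeritabilityPosterior:
    """Retained Gibbs draws for one enterosignature's variance components.

    The per-draw identity h2 = sigma2_a / (sigma2_a + sigma2_e) holds
    exactly for every stored draw.
    """

    sigma2_a: np.ndarray
    sigma2_e: np.ndarray
    h2: np.ndarray
    beta: np.ndarray  # draws x n_fixed
    u: np.ndarray | None  # draws x n_individuals, optional storage
    chain: dict  # n_iter, burn_in, thin, seed, prior settings

    def __post_init__(self):
        self.sigma2_a = np.asarray(self.sigma2_a, dtype=float)
        self.sigma2_e = np.asarray(self.sigma2_e, dtype=float)
        self.h2 = np.asarray(self.h2, dtype=float)
        if np.any(self.sigma2_a <= 0) or np.any(self.sigma2_e <= 0):
            raise ValueError("variance draws must be positive")
        if np.any((self.h2 <= 0) | (self.h2 >= 1)):
            raise ValueError("h2 draws must lie strictly in (0, 1)")
        ratio = self.sigma2_a / (self.sigma2_a + self.sigma2_e)
        if not np.array_equal(ratio, self.h2):
            raise ValueError("h2 draws must equal sigma2_a/(sigma2_a+sigma2_e) exactly")

    @property
    def n_draws(self) -> int:
        return self.h2.size
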