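"""Rank selection for the enterosignature decomposition.

The number of signatures k is chosen by blocked bi-cross validation
(Owen & Perry style): rows and columns are randomly shuffled and split
into a grid of row-folds x column-folds blocks (3 x 3 = nine folds by
default).  Each block A is held out in turn; with the matrix arranged as

    X = [[A, B],
         [C, D]]

an NMF is fitted on D, activities for the held-out samples are projected
from C against the fitted genus weights, genus weights for the held-out
genera are projected from B against the fitted activities, and the
held-out block is predicted as ``A_hat = W_B @ H_C``.  None of A's
entries enter training or projection.  Repetitions reshuffle the matrix;
the same blocks are scored for every k so per-k curves are paired.

The selected rank is the smallest k whose median held-out cosine
similarity has reached a plateau (is within ``plateau_tol`` of the best
median among all larger k).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .nmf import cosine_metrics, explained_variance, fit_nmf, kl_divergence, project_H
from .types import BicvResult, RelAbundanceMatrix

__all__ = [
    "BicvBlock",
    "bicv_blocks",
    "bicv_score_one",
    "bicv_curve",
    "select_rank",
    "full_fit_curve",
    "DEFAULT_BICV_NMF_PARAMS",
]

# desk-scale fitting budget inside bicv: held-out scoring is compared at
# the 1e-2 scale, so single precision and a shallow convergence tolerance
# are plenty (the final full-data fit uses float64 and tol 1e-6)
DEFAULT_BICV_NMF_PARAMS = dict(
    n_restarts=5,
    max_iter=200,
    tol=1e-4,
    dtype=np.float32,
    proj_max_iter=200,
    proj_tol=1e-4,
)


@dataclass
class BicvBlock:
    """Index sets defining one held-out block of a shuffled matrix."""

    hold_rows: np.ndarray
    hold_cols: np.ndarray
    train_rows: np.ndarray
    train_cols: np.ndarray


def bicv_blocks(X, row_folds: int = 3, col_folds: int = 3, seed: int = 0) -> list:
    """Shuffle rows/columns and partition into row_folds x col_folds blocks.

    Every cell of X belongs to exactly one held-out block; fold sizes
    differ by at most one row/column.
    """
    Xm = X.X if isinstance(X, RelAbundanceMatrix) else np.asarray(X)
    m, n = Xm.shape
    if row_folds * col_folds < 2:
        raise ValueError("need at least two blocks")
    if row_folds > m or col_folds > n:
        raise ValueError(f"folds ({row_folds}x{col_folds}) exceed matrix shape {m}x{n}")
    rng = np.random.default_rng(seed)
    row_perm = rng.permutation(m)
    col_perm = rng.permutation(n)
    row_groups = np.array_split(row_perm, row_folds)
    col_groups = np.array_split(col_perm, col_folds)
    blocks = []
    for rg in row_groups:
        other_rows = np.concatenate([g for g in row_groups if g is not rg])
        for cg in col_groups:
            other_cols = np.concatenate([g for g in col_groups if g is not cg])
            blocks.append(
                BicvBlock(
                    hold_rows=rg.copy(),
                    hold_cols=cg.copy(),
                    train_rows=other_rows,
                    train_cols=other_cols,
                )
            )
    return blocks


def bicv_score_one(X, k: int, block: BicvBlock, nmf_params: dict | None = None) -> dict:
    """Score one held-out block at rank k.

    Returns the generalized KL reconstruction error, explained variance,
    and total cosine similarity between the held-out block A and its
    prediction W_B @ H_C.
    """
    Xm = X.X if isinstance(X, RelAbundanceMatrix) else np.asarray(X, dtype=float)
    params = dict(DEFAULT_BICV_NMF_PARAMS)
    if nmf_params:
        params.update(nmf_params)
    proj_iter = params.pop("proj_max_iter", 500)
    proj_tol = params.pop("proj_tol", 1e-6)
    seed = params.pop("seed", 0)
    dtype = params.get("dtype", np.float64)

    A = Xm[np.ix_(block.hold_rows, block.hold_cols)]
    B = Xm[np.ix_(block.hold_rows, block.train_cols)]
    C = Xm[np.ix_(block.train_rows, block.hold_cols)]
    D = Xm[np.ix_(block.train_rows, block.train_cols)]
    if min(D.shape) <= k:
        raise ValueError(f"training block {D.shape} too small for k={k}")
    if D.sum() == 0:
        raise ValueError("degenerate training block (all zeros)")

    dec = fit_nmf(D, k=k, seed=seed, **params)
    W_D = dec.metrics["raw_W"]
    H_D = dec.metrics["raw_H"]
    # held-out samples projected onto the trained genus weights
    H_C = project_H(C, W_D, max_iter=proj_iter, tol=proj_tol, seed=seed, dtype=dtype)
    # held-out genera projected onto the trained activities (transpose trick:
    # B ~ W_B @ H_D  <=>  B.T ~ H_D.T @ W_B.T)
    W_B = project_H(B.T, H_D.T, max_iter=proj_iter, tol=proj_tol, seed=seed, dtype=dtype).T
    A_hat = W_B @ H_C

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if A.sum() > 0 and np.all(np.linalg.norm(A, axis=0) > 0):
            cos_total = cosine_metrics(A, W_B, H_C)["total"]
        else:
            na, nb = np.linalg.norm(A), np.linalg.norm(A_hat)
            cos_total = float((A * A_hat).sum() / (na * nb)) if na * nb > 0 else 0.0
    return {
        "reconstruction_error": kl_divergence(A, W_B, H_C),
        "explained_variance": explained_variance(A, W_B, H_C) if A.any() else 0.0,
        "cosine_total": cos_total,
    }


def bicv_curve(
    X,
    k_range=range(2, 31),
    n_repetitions: int = 200,
    nmf_params: dict | None = None,
    seed: int = 0,
    row_folds: int = 3,
    col_folds: int = 3,
) -> BicvResult:
    """Held-out metric distributions over a range of ranks.

    Each repetition reshuffles the matrix and scores all nine blocks at
    every k (the same blocks across k, so curves are paired).
    """
    k_values = list(k_range)
    Xm = X.X if isinstance(X, RelAbundanceMatrix) else np.asarray(X, dtype=float)
    min_train = (
        Xm.shape[0] - int(np.ceil(Xm.shape[0] / row_folds)),
        Xm.shape[1] - int(np.ceil(Xm.shape[1] / col_folds)),
    )
    if max(k_values) >= min(min_train):
        raise ValueError(f"k up to {max(k_values)} too large for training blocks {min_train}")
    metrics = ("reconstruction_error", "explained_variance", "cosine_total")
    per_k = {k: {m: [] for m in metrics} for k in k_values}
    base = dict(nmf_params or {})
    for rep in range(n_repetitions):
        blocks = bicv_blocks(Xm, row_folds, col_folds, seed=seed + 1000 * rep)
        for b_idx, block in enumerate(blocks):
            fit_seed = seed + 1000 * rep + b_idx
            for k in k_values:
                scores = bicv_score_one(Xm, k, block, {**base, "seed": fit_seed})
                for m in metrics:
                    per_k[k][m].append(scores[m])
    per_k = {k: {m: np.asarray(v) for m, v in d.items()} for k, d in per_k.items()}
    return BicvResult(
        k_values=k_values,
        per_k=per_k,
        row_folds=row_folds,
        col_folds=col_folds,
        n_repetitions=n_repetitions,
    )


def select_rank(result: BicvResult, metric: str = "cosine_total", plateau_tol: float = 0.01) -> int:
    """First-plateau rule on the per-k median of a held-out metric.

    Returns the smallest k whose median is within ``plateau_tol`` of the
    best median among all strictly larger k.  If only the largest k
    satisfies the rule vacuously (curve still rising), that k is returned
    with a "no plateau detected" warning.
    """
    if len(result.k_values) < 3:
        raise ValueError("need at least 3 k values to detect a plateau")
    medians = result.medians(metric)
    k_values = result.k_values
    for i, k in enumerate(k_values[:-1]):
        later_max = medians[i + 1 :].max()
        if medians[i] >= later_max - plateau_tol:
            return k
    warnings.warn("no plateau detected; returning largest k", RuntimeWarning, stacklevel=2)
    return k_values[-1]


def full_fit_curve(X, k_range=range(2, 11), nmf_params: dict | None = None, seed: int = 0) -> dict:
    """Fit the full matrix at each k and record the fit metrics."""
    params = dict(nmf_params or {})
    params.pop("seed", None)
    out = {}
    for k in k_range:
        dec = fit_nmf(X, k=k, seed=seed, **params)
        out[k] = {
            "explained_variance": dec.metrics["explained_variance"],
            "cosine_total": dec.metrics["cosine_similarity_total"],
            "reconstruction_error": dec.metrics["reconstruction_error"],
        }
    return out
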