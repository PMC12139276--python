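"""Interpretation of a fitted enterosignature decomposition.

From the factor pair (W, H) this module derives:

* per-signature genus *contributions* (columns of W normalized to 1) and
  the *driver* genus of each signature (largest contribution);
* per-genus *assignment probabilities* (rows of W normalized to 1);
* per-sample signature *fractions* (columns of H normalized to 1; x100
  they read as the percentage each signature explains within a sample);
* the genera contributing more than a threshold (4% by default) to at
  least one signature, with the remainder pooled as "others";
* per-group minimal signature sets: how many signatures, in descending
  order of mean fraction, are needed to cover 90% of a group's community;
* optimal one-to-one matching of two signature profiles by cosine
  similarity (Hungarian assignment), used to compare fits across ages,
  ranks, or against simulation ground truth.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .types import ESDecomposition, ESProfile, SampleESFractions

__all__ = [
    "make_profile",
    "sample_fractions",
    "top_contributors",
    "minimal_es_set",
    "match_es",
]


def _es_name(driver: str, taken: set) -> str:
    base = "ES-" + str(driver)[:4]
    name, i = base, 2
    while name in taken:
        name = f"{base}{i}"
        i += 1
    return name


def make_profile(dec: ESDecomposition) -> ESProfile:
    """Column- and row-normalized views of W with driver-based names."""
    W = dec.W
    colsums = W.sum(axis=0)
    if np.any(colsums == 0):
        raise ValueError("degenerate enterosignature: W has an all-zero column")
    contributions = W / colsums

    rowsums = W.sum(axis=1)
    zero_rows = rowsums == 0
    assignment = np.zeros_like(W)
    assignment[~zero_rows] = W[~zero_rows] / rowsums[~zero_rows, None]
    zero_weight = [g for g, z in zip(dec.genus_ids, zero_rows) if z]

    drivers, names = [], []
    taken: set = set()
    for j in range(dec.k):
        col = contributions[:, j]
        top = col.max()
        ties = [dec.genus_ids[i] for i in np.flatnonzero(col == top)]
        if len(ties) > 1:
            warnings.warn(
                f"driver tie in signature {j}: {ties}; breaking lexicographically",
                RuntimeWarning,
                stacklevel=2,
            )
        driver = min(ties)
        drivers.append(driver)
        name = _es_name(driver, taken)
        taken.add(name)
        names.append(name)

    return ESProfile(
        es_names=names,
        driver_genus=drivers,
        contributions=contributions,
        assignment_prob=assignment,
        genus_ids=list(dec.genus_ids),
        zero_weight_genera=zero_weight,
    )


def sample_fractions(dec: ESDecomposition, es_names: list | None = None) -> SampleESFractions:
    """Normalize H columns to per-sample signature fractions."""
    H = dec.H
    sums = H.sum(axis=0)
    if np.any(sums == 0):
        bad = [dec.sample_ids[j] for j in np.flatnonzero(sums == 0)[:10]]
        raise ValueError(f"zero-activity sample column(s): {bad}")
    if es_names is None:
        es_names = make_profile(dec).es_names
    return SampleESFractions(
        fractions=H / sums,
        sample_ids=list(dec.sample_ids),
        es_names=list(es_names),
    )


def top_contributors(profile: ESProfile, threshold: float = 0.04) -> pd.DataFrame:
    """Genera exceeding ``threshold`` contribution in at least one signature.

    Returns a genus x signature table of contributions restricted to those
    genera, plus an ``others`` row pooling everything below threshold, so
    each signature column still sums to 1.
    """
    if not (0 <= threshold <= 1):
        raise ValueError("threshold must be in [0, 1]")
    listed = (profile.contributions > threshold).any(axis=1)
    frame = profile.contributions_frame()
    top = frame.loc[listed]
    others = frame.loc[~listed].sum(axis=0)
    out = pd.concat([top, others.to_frame("others").T])
    return out


def minimal_es_set(
    fractions: SampleESFractions,
    group_labels,
    coverage: float = 0.90,
) -> dict:
    """Per-group minimal signature sets covering a fraction of the community.

    For each group level, signatures are ranked by their mean per-sample
    fraction (descending); ``n_min`` is the length of the shortest prefix
    whose cumulative mean reaches ``coverage``.  Also reports each
    signature's frequency of membership in the minimal sets across groups.
    """
    if not (0 < coverage <= 1):
        raise ValueError("coverage must be in (0, 1]")
    labels = np.asarray(group_labels)
    if labels.shape[0] != len(fractions.sample_ids):
        raise ValueError("group_labels length must match number of samples")
    out: dict = {"groups": {}, "es_frequency": {}}
    membership: dict = {name: 0 for name in fractions.es_names}
    for level in pd.unique(labels):
        mask = labels == level
        means = fractions.fractions[:, mask].mean(axis=1)
        order = np.argsort(-means, kind="stable")
        cum = np.cumsum(means[order])
        n_min = int(np.searchsorted(cum, coverage - 1e-12) + 1)
        n_min = min(n_min, len(order))
        ranked = [fractions.es_names[i] for i in order]
        out["groups"][str(level)] = {
            "n_min": n_min,
            "es_rank_order": ranked,
            "primary_es": ranked[0],
            "mean_fractions": {fractions.es_names[i]: float(means[i]) for i in order},
        }
        for name in ranked[:n_min]:
            membership[name] += 1
    n_groups = len(out["groups"])
    out["es_frequency"] = {name: c / n_groups for name, c in membership.items()}
    return out


def match_es(profile_a: ESProfile, profile_b: ESProfile) -> dict:
    """Optimal one-to-one signature matching between two profiles.

    Contribution columns are restricted to the shared genus universe and
    re-normalized; the Hungarian assignment maximizes summed cosine
    similarity.  When ranks differ, surplus signatures of the larger
    profile are left unpaired.
    """
    shared = [g for g in profile_a.genus_ids if g in set(profile_b.genus_ids)]
    if not shared:
        raise ValueError("profiles share no genera")
    idx_a = [profile_a.genus_ids.index(g) for g in shared]
    idx_b = [profile_b.genus_ids.index(g) for g in shared]
    A = profile_a.contributions[idx_a]
    B = profile_b.contributions[idx_b]

    def _unit(M):
        norms = np.linalg.norm(M, axis=0)
        norms[norms == 0] = 1.0
        return M / norms

    cos = _unit(A).T @ _unit(B)  # ka x kb
    rows, cols = linear_sum_assignment(-cos)
    pairs = [
        {
            "es_a": profile_a.es_names[i],
            "es_b": profile_b.es_names[j],
            "cosine": float(cos[i, j]),
        }
        for i, j in zip(rows, cols)
    ]
    matched_a = {p["es_a"] for p in pairs}
    matched_b = {p["es_b"] for p in pairs}
    return {
        "pairs": pairs,
        "mean_cosine": float(np.mean([p["cosine"] for p in pairs])),
        "unmatched_a": [n for n in profile_a.es_names if n not in matched_a],
        "unmatched_b": [n for n in profile_b.es_names if n not in matched_b],
    }
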