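"""Count-table QC and construction of the NMF input matrix.

The pipeline starts from a feature (ASV or genus) count table plus a
taxonomy map and produces a column-stochastic genus relative-abundance
matrix:

1. drop rare features (present in fewer than 2 samples AND below 1e-6 of
   total counts — both clauses must hold, matching the conventional
   conjunction),
2. drop shallow samples (fewer than 10,000 reads),
3. collapse ASVs to genus level,
4. keep genera present in strictly more than 20% of samples,
5. divide each sample column by its sum.

All thresholds are arguments; defaults follow the study design this
package reproduces.
"""

from __future__ import annotations

import warnings

import numpy as np

from .types import CountTable, RelAbundanceMatrix

__all__ = [
    "filter_features",
    "filter_samples",
    "collapse_to_genus",
    "prevalence_filter",
    "normalize_columns",
    "make_nmf_input",
]


def filter_features(
    table: CountTable,
    min_sample_presence: int = 2,
    min_total_fraction: float = 1e-6,
    conjunction: bool = True,
) -> CountTable:
    """Remove features that are both rare across samples and low-abundance.

    A feature is removed when it is present (count > 0) in fewer than
    ``min_sample_presence`` samples AND represents less than
    ``min_total_fraction`` of the table's total counts.  Set
    ``conjunction=False`` for the OR rule used by some pipelines.
    Feature order is preserved.
    """
    if min_sample_presence < 0 or min_total_fraction < 0:
        raise ValueError("thresholds must be nonnegative")
    presence = (table.counts > 0).sum(axis=1)
    total = table.counts.sum()
    frac = table.counts.sum(axis=1) / total if total > 0 else np.zeros(table.n_features)
    rare = presence < min_sample_presence
    low = frac < min_total_fraction
    drop = (rare & low) if conjunction else (rare | low)
    keep = ~drop
    if not keep.any():
        warnings.warn("feature filter removed every feature", RuntimeWarning, stacklevel=2)
    return _subset(table, feature_mask=keep)


def filter_samples(table: CountTable, min_depth: int = 10_000) -> CountTable:
    """Drop samples with total counts strictly below ``min_depth``."""
    if min_depth < 0:
        raise ValueError("min_depth must be nonnegative")
    keep = table.sample_depths() >= min_depth
    if not keep.any():
        raise ValueError("no samples pass depth filter")
    return _subset(table, sample_mask=keep)


def collapse_to_genus(table: CountTable) -> CountTable:
    """Sum feature rows within genus using the table's taxonomy map.

    Features whose genus is unresolved (empty string or None in the map)
    are pooled into a labeled ``unclassified`` bucket rather than dropped,
    so column totals still reflect the whole community.  Genus order
    follows first appearance among features.
    """
    if table.taxonomy is None:
        raise ValueError("collapse_to_genus requires a taxonomy map")
    missing = [f for f in table.feature_ids if f not in table.taxonomy]
    if missing:
        raise ValueError(f"taxonomy missing for features: {missing[:10]}")
    genus_order: list = []
    rows: dict = {}
    for i, f in enumerate(table.feature_ids):
        genus = table.taxonomy[f]
        if not genus:
            genus = "unclassified"
        if genus not in rows:
            rows[genus] = np.zeros(table.n_samples, dtype=table.counts.dtype)
            genus_order.append(genus)
        rows[genus] += table.counts[i]
    return CountTable(
        counts=np.vstack([rows[g] for g in genus_order]),
        feature_ids=genus_order,
        sample_ids=list(table.sample_ids),
        taxonomy={g: g for g in genus_order},
    )


def prevalence_filter(table: CountTable, min_prevalence: float = 0.20) -> CountTable:
    """Keep features with nonzero counts in strictly more than
    ``min_prevalence`` of the samples."""
    if not (0 <= min_prevalence <= 1):
        raise ValueError("min_prevalence must be in [0, 1]")
    prevalence = (table.counts > 0).mean(axis=1)
    keep = prevalence > min_prevalence
    if not keep.any():
        warnings.warn("prevalence filter removed every feature", RuntimeWarning, stacklevel=2)
    return _subset(table, feature_mask=keep)


def normalize_columns(table: CountTable) -> RelAbundanceMatrix:
    """Divide each sample column by its sum (total-sum scaling)."""
    sums = table.sample_depths().astype(float)
    zero = sums == 0
    if zero.any():
        bad = [table.sample_ids[j] for j in np.flatnonzero(zero)[:10]]
        raise ValueError(f"zero-sum sample column(s): {bad}")
    return RelAbundanceMatrix(
        X=table.counts / sums,
        genus_ids=list(table.feature_ids),
        sample_ids=list(table.sample_ids),
    )


def make_nmf_input(
    table: CountTable,
    min_sample_presence: int = 2,
    min_total_fraction: float = 1e-6,
    min_depth: int = 10_000,
    min_prevalence: float = 0.20,
    collapse: bool = True,
) -> tuple[RelAbundanceMatrix, dict]:
    """Run the full QC chain and return the NMF input plus a QC report.

    The report records which features/samples each step dropped and why,
    suitable for JSON serialization.
    """
    report: dict = {"steps": []}

    def _log(step, before, after, axis):
        ids_before = before.feature_ids if axis == "features" else before.sample_ids
        ids_after = set(after.feature_ids if axis == "features" else after.sample_ids)
        dropped = [i for i in ids_before if i not in ids_after]
        report["steps"].append({"step": step, "dropped": dropped, "n_dropped": len(dropped)})

    t1 = filter_features(table, min_sample_presence, min_total_fraction)
    _log("filter_features", table, t1, "features")
    t2 = filter_samples(t1, min_depth)
    _log("filter_samples", t1, t2, "samples")
    t3 = collapse_to_genus(t2) if collapse else t2
    if collapse:
        report["steps"].append(
            {"step": "collapse_to_genus", "n_features_in": t2.n_features, "n_genera_out": t3.n_features}
        )
    t4 = prevalence_filter(t3, min_prevalence)
    _log("prevalence_filter", t3, t4, "features")
    X = normalize_columns(t4)
    report["n_genera"] = X.n_genera
    report["n_samples"] = X.n_samples
    return X, report


def _subset(
    table: CountTable,
    feature_mask: np.ndarray | None = None,
    sample_mask: np.ndarray | None = None,
) -> CountTable:
    counts = table.counts
    feature_ids = list(table.feature_ids)
    sample_ids = list(table.sample_ids)
    if feature_mask is not None:
        counts = counts[feature_mask]
        feature_ids = [f for f, k in zip(feature_ids, feature_mask) if k]
    if sample_mask is not None:
        counts = counts[:, sample_mask]
        sample_ids = [s for s, k in zip(sample_ids, sample_mask) if k]
    taxonomy = None
    if table.taxonomy is not None:
        taxonomy = {f: table.taxonomy[f] for f in feature_ids if f in table.taxonomy}
    return CountTable(counts=counts, feature_ids=feature_ids, sample_ids=sample_ids, taxonomy=taxonomy)
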