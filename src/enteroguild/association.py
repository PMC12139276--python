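"""Univariate enterosignature-trait association.

Traits (body weight, average daily gain, feed conversion ratio, residual
feed intake, hair cortisol) are regressed on one signature fraction at a
time by ordinary least squares; body weight is first residualized on age.
Group composition contrasts (stress vs control) compare per-signature
mean fractions with a descriptive two-sample t test.  Raw p values are
reported alongside a Benjamini-Hochberg column for convenience; the
primary analysis applies no multiple-testing correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import SampleESFractions

__all__ = ["residualize", "es_trait_regression", "group_contrast"]


def residualize(trait, covariates) -> np.ndarray:
    """OLS residuals of a trait on intercept + covariates.

    ``covariates`` may be a vector, 2-D array, or DataFrame of numeric
    columns.  Raises on a rank-deficient design.
    """
    y = np.asarray(trait, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    n = y.shape[0]
    if C.shape[0] != n:
        raise ValueError("trait and covariates must have matching length")
    X = np.column_stack([np.ones(n), C])
    if n <= X.shape[1]:
        raise ValueError("need more observations than covariates")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate design")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def es_trait_regression(
    fractions: SampleESFractions,
    trait,
    trait_name: str = "trait",
) -> pd.DataFrame:
    """Per-signature univariate OLS: trait ~ intercept + fraction.

    Missing trait values are dropped pairwise.  Signatures with constant
    fraction over the complete pairs are flagged degenerate (no p value).
    Returns a tidy table (es, trait, n, slope, se, t, p, p_bh).
    """
    if isinstance(trait, pd.Series):
        trait = trait.to_numpy()
    y_all = np.asarray(trait, dtype=float)
    if y_all.shape[0] != len(fractions.sample_ids):
        raise ValueError("trait length must match number of samples")
    ok = np.isfinite(y_all)
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete trait observations")
    rows = []
    for i, name in enumerate(fractions.es_names):
        x = fractions.fractions[i, ok]
        y = y_all[ok]
        if np.ptp(x) == 0:
            rows.append(
                dict(es=name, trait=trait_name, n=int(ok.sum()), slope=np.nan,
                     se=np.nan, t=np.nan, p=np.nan, degenerate=True)
            )
            continue
        res = stats.linregress(x, y)
        rows.append(
            dict(
                es=name,
                trait=trait_name,
                n=int(ok.sum()),
                slope=res.slope,
                se=res.stderr,
                t=res.slope / res.stderr,
                p=res.pvalue,
                degenerate=False,
            )
        )
    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    out["p_bh"] = np.nan
    if valid.any():
        out.loc[valid, "p_bh"] = multipletests(out.loc[valid, "p"], method="fdr_bh")[1]
    return out


def group_contrast(fractions: SampleESFractions, group) -> pd.DataFrame:
    """Per-signature mean fractions by group with a descriptive t test.

    Requires exactly two group levels with at least two samples each.
    The difference is level2 - level1 in sorted level order.  The t-test
    p value is descriptive (no design adjustment), matching how the
    stress-vs-control composition shift is reported.
    """
    g = np.asarray(group)
    if g.shape[0] != len(fractions.sample_ids):
        raise ValueError("group length must match number of samples")
    levels = sorted(pd.unique(g).tolist())
    if len(levels) < 2:
        raise ValueError("group factor must have at least two levels")
    if len(levels) > 2:
        raise ValueError(f"expected two group levels, got {levels}")
    m1, m2 = g == levels[0], g == levels[1]
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("each group level needs at least two samples")
    rows = []
    for i, name in enumerate(fractions.es_names):
        a = fractions.fractions[i, m1]
        b = fractions.fractions[i, m2]
        t, p = stats.ttest_ind(b, a)
        rows.append(
            {
                "es": name,
                f"mean_{levels[0]}": a.mean(),
                f"mean_{levels[1]}": b.mean(),
                "difference": b.mean() - a.mean(),
                "t": t,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
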