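"""Empirical-Bayes moderated two-group differential expression.

Per gene, the ordinary two-sample statistics (mean difference on the log2
scale and pooled residual variance s² with d degrees of freedom) are
moderated by shrinking s² toward a cross-gene prior: the prior degrees of
freedom d0 and prior variance s0² are estimated by moment matching on
log s² (digamma/trigamma inversion), the posterior variance is
s̃² = (d0·s0² + d·s²)/(d0 + d), and the moderated t statistic
t̃ = Δ / (s̃·√(1/n1 + 1/n2)) is referred to a t distribution with d0 + d
degrees of freedom. p-values are BH-adjusted across genes.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import norm, t as t_dist
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix


def _trigamma(x):
    return polygamma(1, x)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = _trigamma(y)
        step = tri * (1.0 - tri / x) / polygamma(2, y)
        y += step
        if abs(step) < 1e-10 * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching estimate of (d0, s0²) from gene-wise variances.

    Works on z = log s², whose mean and excess variance relative to the
    trigamma(df/2) sampling component identify the scaled-inverse-chi²
    prior. Returns (inf, geometric-mean variance) when the observed spread
    is no larger than the sampling spread.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(_trigamma(df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s02 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


def moderated_t(matrix, group_labels, groups=None,
                prior_df: float | None = None) -> pd.DataFrame:
    """Moderated-t differential expression between exactly two groups.

    Parameters
    ----------
    matrix : ExpressionMatrix or DataFrame
        Genes × samples, log2 scale.
    group_labels : Series or array
        Per-sample group labels with exactly two levels.
    groups : tuple, optional
        (group1, group2); log2FC is group1 mean − group2 mean. Defaults to
        the sorted unique labels.
    prior_df : float, optional
        Override the estimated prior degrees of freedom; 0 gives the
        ordinary pooled two-sample t, numpy.inf a common-variance z-like
        statistic.

    Returns
    -------
    DataFrame indexed by gene: log2fc, t, p, adj_p, s2, df, plus the
    hyperparameters d0 and s0_2 as attrs.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    labels = pd.Series(np.asarray(group_labels), index=values.columns)
    levels = sorted(labels.unique()) if groups is None else list(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    idx1 = labels.index[labels == levels[0]]
    idx2 = labels.index[labels == levels[1]]
    n1, n2 = len(idx1), len(idx2)
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least 2 samples")

    x1 = values[idx1].to_numpy(dtype=float)
    x2 = values[idx2].to_numpy(dtype=float)
    delta = x1.mean(axis=1) - x2.mean(axis=1)
    df = n1 + n2 - 2
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) \
        + ((x2 - x2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / df

    if prior_df is None:
        d0, s02 = estimate_prior(s2, df)
    else:
        d0 = float(prior_df)
        _, s02 = estimate_prior(s2, df)
        if d0 == 0.0:
            s02 = 0.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        total_df = np.inf
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
        total_df = d0 + df

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, delta / np.where(se > 0, se, 1.0), 0.0)
    if np.isinf(total_df):
        p = 2.0 * norm.sf(np.abs(t))
    else:
        p = 2.0 * t_dist.sf(np.abs(t), total_df)
    # zero-variance genes with zero difference: t = 0, p = 1
    degenerate = (se == 0) & (delta == 0)
    p = np.where(degenerate, 1.0, p)

    out = pd.DataFrame({
        "log2fc": delta, "t": t, "p": p,
        "adj_p": multipletests(p, method="fdr_bh")[1],
        "s2": s2, "df": float(df),
    }, index=values.index)
    out.attrs["d0"] = d0
    out.attrs["s0_2"] = s02
    out.attrs["groups"] = tuple(levels)
    return out


def pattern_degs(matrix, assignment, lfc_cut: float = 0.7,
                 p_cut: float = 0.05):
    """All pairwise moderated-t comparisons between cluster patterns.

    Returns (per-pair tables, union gene list) where the union collects
    genes passing |log2FC| > lfc_cut and p < p_cut in at least one pair.
    Pairs involving a cluster of fewer than 2 samples are skipped with a
    warning.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    assignment = pd.Series(assignment)
    labels = sorted(assignment.unique())
    if len(labels) < 2:
        raise ValueError("need at least 2 clusters")
    sizes = assignment.value_counts()
    tables: dict[tuple, pd.DataFrame] = {}
    union: set = set()
    for a, b in combinations(labels, 2):
        if sizes[a] < 2 or sizes[b] < 2:
            warnings.warn(f"pair ({a}, {b}) skipped: cluster with <2 samples",
                          stacklevel=2)
            continue
        keep = assignment[assignment.isin([a, b])]
        tab = moderated_t(values[keep.index], keep, groups=(a, b))
        tables[(a, b)] = tab
        passing = tab[(tab["log2fc"].abs() > lfc_cut) & (tab["p"] < p_cut)]
        union.update(passing.index)
    if not tables:
        raise ValueError("no cluster pair had enough samples")
    return tables, sorted(union)


def overlap_degs(per_pair_tables: dict, adj_p_cut: float = 0.001,
                 mode: str = "intersection") -> list[str]:
    """Genes significant (BH-adjusted p < cut) across pairwise comparisons.

    ``mode='intersection'`` (default) keeps genes significant in *every*
    pair; ``'union'`` keeps genes significant in at least one. The list is
    sorted by worst (largest) adjusted p ascending, then gene id.
    """
    if mode not in ("intersection", "union"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(per_pair_tables) < 2:
        raise ValueError("need at least 2 pairwise tables")
    sig = [set(tab.index[tab["adj_p"] < adj_p_cut])
           for tab in per_pair_tables.values()]
    genes = set.intersection(*sig) if mode == "intersection" \
        else set.union(*sig)
    if not genes:
        warnings.warn("no overlap genes at the requested threshold",
                      stacklevel=2)
        return []
    worst = pd.concat([tab.loc[sorted(genes), "adj_p"]
                       for tab in per_pair_tables.values()], axis=1)
    worst = worst.max(axis=1) if mode == "intersection" else worst.min(axis=1)
    return worst.sort_values(kind="stable").index.tolist()
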