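"""Single-sample gene-set enrichment (ssGSEA), composite TME scores and
hypergeometric over-representation analysis.

ssGSEA scores one sample at a time: genes are ranked by expression
(descending, ties broken by gene id), and the raw enrichment score is the
sum over all ranked positions of the gap between the weighted in-set
cumulative distribution and the unweighted out-of-set one. Raw scores are
then min–max rescaled to [0, 1] per set across samples ("unity
normalisation"), which makes scores comparable across sets of different
sizes. Composite immune/stromal scores are means of normalised scores over
user-supplied signature groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, GeneSetCollection


@dataclass
class EnrichmentMatrix:
    """Raw and unity-normalised enrichment scores (sets × samples)."""

    raw: pd.DataFrame
    normalized: pd.DataFrame

    def composite(self, set_group) -> pd.Series:
        return composite_score(self, set_group)


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, ExpressionMatrix):
        return matrix.values
    return matrix


def _sample_es(expr: np.ndarray, order: np.ndarray, in_set: np.ndarray,
               alpha: float) -> float:
    """Raw ssGSEA enrichment score for one sample.

    ``order`` indexes genes from highest to lowest expression; ``in_set``
    is a boolean membership mask aligned to the original gene order.
    """
    n = expr.size
    mask = in_set[order]
    # absolute rank from the bottom: top gene has rank n
    r = np.arange(n, 0, -1, dtype=float)
    w = np.where(mask, r ** alpha, 0.0)
    p_in = np.cumsum(w)
    p_in /= p_in[-1]
    n_out = n - int(mask.sum())
    p_out = np.cumsum(~mask) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea(matrix, gene_sets: GeneSetCollection, alpha: float = 0.25
           ) -> EnrichmentMatrix:
    """ssGSEA over a genes × samples matrix.

    Sets intersecting the matrix in fewer than 2 genes are skipped with a
    warning; a set covering the entire gene universe is rejected (its
    out-of-set walk is undefined). Normalised scores are per-set min–max
    across samples; a constant raw score maps to 0.5 by convention.
    """
    values = _as_frame(matrix)
    if len(gene_sets) == 0:
        raise ValueError("empty gene-set collection")
    genes = values.index
    gene_pos = {g: i for i, g in enumerate(genes)}
    n = len(genes)

    masks = {}
    for name, members in gene_sets.sets.items():
        hit = sorted({g for g in members if g in gene_pos})
        if len(hit) < 2:
            warnings.warn(f"set {name!r} intersects <2 matrix genes; skipped",
                          stacklevel=2)
            continue
        if len(hit) == n:
            raise ValueError(
                f"set {name!r} covers the whole gene universe; its "
                "enrichment score is undefined"
            )
        mask = np.zeros(n, dtype=bool)
        mask[[gene_pos[g] for g in hit]] = True
        masks[name] = mask
    if not masks:
        raise ValueError("all gene sets were skipped")

    X = values.to_numpy(dtype=float)
    # stable tie-break by gene id: pre-sort rows by gene id, then stable
    # argsort on descending expression
    id_order = np.argsort(genes.to_numpy().astype(str), kind="stable")
    raw = pd.DataFrame(index=list(masks), columns=values.columns, dtype=float)
    for s, sample in enumerate(values.columns):
        expr = X[:, s]
        order = id_order[np.argsort(-expr[id_order], kind="stable")]
        for name, mask in masks.items():
            raw.loc[name, sample] = _sample_es(expr, order, mask, alpha)

    rng = raw.max(axis=1) - raw.min(axis=1)
    with np.errstate(invalid="ignore"):
        normalized = raw.sub(raw.min(axis=1), axis=0).div(rng, axis=0)
    normalized[rng == 0] = 0.5
    return EnrichmentMatrix(raw=raw, normalized=normalized)


class SSGSEA(BaseEstimator, TransformerMixin):
    """Transformer wrapper: samples × genes in, samples × sets out.

    ``transform`` applies unity normalisation within the batch it is given,
    so scores are cohort-relative by construction.
    """

    def __init__(self, gene_sets: GeneSetCollection | None = None,
                 alpha: float = 0.25):
        self.gene_sets = gene_sets
        self.alpha = alpha

    def fit(self, X, y=None):
        if self.gene_sets is None or len(self.gene_sets) == 0:
            raise ValueError("gene_sets must be provided")
        return self

    def transform(self, X) -> pd.DataFrame:
        self.fit(X)
        frame = X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
        result = ssgsea(frame.T, self.gene_sets, alpha=self.alpha)
        return result.normalized.T


def composite_score(enrichment: EnrichmentMatrix, set_group) -> pd.Series:
    """Per-sample mean of normalised scores over a group of sets."""
    group = list(set_group)
    if not group:
        raise ValueError("empty set group")
    missing = [s for s in group if s not in enrichment.normalized.index]
    if missing:
        raise KeyError(f"sets absent from enrichment matrix: {missing}")
    return enrichment.normalized.loc[group].mean(axis=0)


def ora(query_genes, gene_sets: GeneSetCollection, universe) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list against sets.

    Query genes outside the universe are dropped with a warning. For each
    set (intersected with the universe) the upper-tail hypergeometric
    probability P[X >= overlap] is computed, then BH-adjusted across sets.
    """
    universe = list(dict.fromkeys(universe))
    uni = set(universe)
    query = list(dict.fromkeys(query_genes))
    outside = [g for g in query if g not in uni]
    if outside:
        warnings.warn(f"{len(outside)} query gene(s) outside universe dropped",
                      stacklevel=2)
        query = [g for g in query if g in uni]
    m, q = len(universe), len(query)

    rows = []
    for name, members in gene_sets.sets.items():
        inset = {g for g in members if g in uni}
        if not inset:
            continue
        overlap = len(inset.intersection(query))
        p = float(hypergeom.sf(overlap - 1, m, len(inset), q))
        rows.append((name, overlap, len(inset), m, min(p, 1.0)))
    if not rows:
        raise ValueError("no gene set overlaps the universe")
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size",
                                      "universe_size", "p"]).set_index("set")
    out["adj_p"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values("p")
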