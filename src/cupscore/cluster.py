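"""Resampling-based consensus clustering with PAC-driven model selection.

For each candidate k, samples are repeatedly subsampled without replacement
and clustered (agglomerative, average linkage on 1 − Pearson correlation
between sample profiles by default); the consensus matrix entry (i, j) is
the fraction of co-clustered draws among draws in which both samples
appeared. k is chosen by minimising the proportion of ambiguous clustering
(PAC) — the mass of the consensus-entry CDF between 0.1 and 0.9 — with a
tie tolerance favouring the largest near-minimal k, since merging two
internally stable clusters is itself stable (PAC ties at ~0 below the true
k) while over-splitting is not. The final
partition is an agglomerative cut of 1 − consensus at the chosen k, with
clusters relabelled by ascending mean panel expression so the *last* label
("C" for k = 3) is the pattern with the highest regulator expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .containers import ExpressionMatrix
from .synth import cluster_letters

PAC_LOWER = 0.1
PAC_UPPER = 0.9


def _correlation_distance(X: np.ndarray) -> np.ndarray:
    """1 − Pearson correlation between rows, NaNs (constant rows) -> 1."""
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr = np.nan_to_num(corr, nan=0.0)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    # clip tiny negative round-off and symmetrise for squareform
    return np.clip((d + d.T) / 2.0, 0.0, 2.0)


def _cut_tree(dist: np.ndarray, k: int) -> np.ndarray:
    Z = linkage(squareform(dist, checks=False), method="average")
    return fcluster(Z, t=k, criterion="maxclust")


class ConsensusCluster(BaseEstimator, ClusterMixin):
    """Consensus clustering estimator (scikit-learn API).

    Parameters
    ----------
    k_range : tuple of int
        Inclusive (k_min, k_max) candidate range.
    n_resamples : int
        Subsampling iterations per k (>= 2).
    subsample_frac : float
        Fraction of samples drawn without replacement each iteration,
        strictly between 0 and 1.
    base_clusterer : {"hierarchical", "kmeans"}
        Clusterer applied to each subsample. Hierarchical uses average
        linkage on 1 − Pearson distance; k-means runs on the raw profiles.
    random_state : int or None
        Seed for the subsampling (and k-means) stream.

    Attributes
    ----------
    consensus_ : dict[int, ndarray]
        Per-k samples × samples consensus matrices.
    cosampled_ : dict[int, ndarray]
        Per-k co-sampling count matrices.
    pac_ : pandas.Series
        PAC statistic per k.
    delta_area_ : pandas.Series
        Relative change of the area under the consensus CDF per k.
    best_k_ : int
        argmin-PAC candidate.
    labels_ : ndarray of int
        Final assignment at ``best_k_``; codes 0..k−1 ordered by ascending
        cluster-mean feature value.
    """

    def __init__(self, k_range=(2, 6), n_resamples: int = 1000,
                 subsample_frac: float = 0.8,
                 base_clusterer: str = "hierarchical",
                 center_genes: bool = True,
                 pac_tolerance: float = 0.01,
                 min_cluster_frac: float = 0.05,
                 random_state: int | None = None):
        self.k_range = k_range
        self.n_resamples = n_resamples
        self.subsample_frac = subsample_frac
        self.base_clusterer = base_clusterer
        self.center_genes = center_genes
        self.pac_tolerance = pac_tolerance
        self.min_cluster_frac = min_cluster_frac
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        k_min, k_max = self.k_range
        if X.shape[1] < 2:
            raise ValueError("need at least 2 panel genes to cluster on")
        if not 2 <= k_min <= k_max:
            raise ValueError("k_range must satisfy 2 <= k_min <= k_max")
        if k_max >= n:
            raise ValueError(f"k_max={k_max} must be < n_samples={n}")
        if self.n_resamples < 2:
            raise ValueError("n_resamples must be >= 2")
        if not 0.0 < self.subsample_frac < 1.0:
            raise ValueError("subsample_frac must be in (0, 1)")
        if self.base_clusterer not in ("hierarchical", "kmeans"):
            raise ValueError(f"unknown base clusterer {self.base_clusterer!r}")

        rng = np.random.default_rng(self.random_state)
        m = int(np.ceil(self.subsample_frac * n))
        ks = list(range(k_min, k_max + 1))

        raw_X = X
        if self.center_genes:
            # sweep gene medians so sample-sample correlations reflect the
            # expression *pattern*, not the shared per-gene baseline level
            X = X - np.median(X, axis=0, keepdims=True)

        self.consensus_ = {}
        self.cosampled_ = {}
        for k in ks:
            together = np.zeros((n, n))
            cosampled = np.zeros((n, n))
            for _ in range(self.n_resamples):
                idx = np.sort(rng.choice(n, size=m, replace=False))
                sub = X[idx]
                if self.base_clusterer == "hierarchical":
                    labels = _cut_tree(_correlation_distance(sub), k)
                else:
                    seed = int(rng.integers(0, 2**31 - 1))
                    labels = KMeans(n_clusters=k, n_init=10,
                                    random_state=seed).fit_predict(sub)
                cosampled[np.ix_(idx, idx)] += 1.0
                same = labels[:, None] == labels[None, :]
                together[np.ix_(idx, idx)] += same
            with np.errstate(invalid="ignore"):
                cm = np.where(cosampled > 0, together / cosampled, 0.0)
            self.consensus_[k] = cm
            self.cosampled_[k] = cosampled

        iu = np.triu_indices(n, k=1)
        pac, area = {}, {}
        for k in ks:
            entries = self.consensus_[k][iu]
            pac[k] = float(np.mean((entries > PAC_LOWER)
                                   & (entries <= PAC_UPPER)))
            grid = np.linspace(0.0, 1.0, 101)
            cdf = np.searchsorted(np.sort(entries), grid,
                                  side="right") / entries.size
            area[k] = float(np.trapezoid(cdf, grid))
        self.pac_ = pd.Series(pac, name="pac")
        areas = pd.Series(area, name="auc_cdf")
        delta = {ks[0]: areas.iloc[0]}
        for prev, k in zip(ks, ks[1:]):
            delta[k] = (areas[k] - areas[prev]) / areas[prev]
        self.delta_area_ = pd.Series(delta, name="delta_area")

        # k values whose partition contains a trivial cluster (outlier
        # peeling) do not represent new structure and are not eligible
        min_size = max(1, int(np.ceil(self.min_cluster_frac * n)))
        eligible = [k for k in ks
                    if np.bincount(self.assign(k, raw_X)).min() >= min_size]
        pac_eligible = self.pac_[eligible] if eligible else self.pac_
        # tie-tolerant argmin: a merge of two internally stable clusters is
        # itself perfectly stable, so PAC can tie at ~0 for k below the
        # truth; among near-minimal k keep the finest unambiguous partition.
        near_min = pac_eligible[pac_eligible <= pac_eligible.min()
                                + self.pac_tolerance]
        self.best_k_ = int(near_min.index.max())
        self.labels_ = self.assign(self.best_k_, raw_X)
        return self

    def assign(self, k: int, X) -> np.ndarray:
        """Final partition at a given k, relabelled by ascending mean profile."""
        raw = _cut_tree(1.0 - self.consensus_[k], k)
        X = np.asarray(X, dtype=float)
        sample_mean = X.mean(axis=1)
        # a maxclust cut can yield fewer than k groups on degenerate ties;
        # empty labels sort last
        means = [sample_mean[raw == c].mean() if (raw == c).any() else np.inf
                 for c in range(1, k + 1)]
        order = np.argsort(means, kind="stable")
        remap = np.empty(k, dtype=int)
        remap[order] = np.arange(k)
        return remap[raw - 1]


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, diagnostics and the chosen partition."""

    consensus: dict[int, pd.DataFrame]
    cosampled: dict[int, pd.DataFrame]
    pac: pd.Series
    delta_area: pd.Series
    chosen_k: int
    assignment: pd.Series  # sample -> cluster letter


def consensus_cluster(matrix: ExpressionMatrix, panel_genes,
                      k_range=(2, 6), n_resamples: int = 1000,
                      subsample_frac: float = 0.8, seed: int | None = None,
                      base_clusterer: str = "hierarchical") -> ConsensusResult:
    """Cluster samples on a gene panel and pick k by minimum PAC.

    ``panel_genes`` must all be present in the matrix (missing names raise a
    KeyError listing them). Labels are letters ordered by ascending mean
    panel expression, so the last letter is the highest-expression pattern.
    """
    panel = list(panel_genes)
    if len(panel) < 2:
        raise ValueError("panel must contain at least 2 genes")
    sub = matrix.subset_genes(panel)
    X = sub.to_samples_by_genes().to_numpy()
    est = ConsensusCluster(k_range=k_range, n_resamples=n_resamples,
                           subsample_frac=subsample_frac,
                           base_clusterer=base_clusterer,
                           random_state=seed).fit(X)
    letters = cluster_letters(est.best_k_)
    samples = matrix.samples
    assignment = pd.Series([letters[c] for c in est.labels_], index=samples,
                           name="cluster")
    consensus = {k: pd.DataFrame(cm, index=samples, columns=samples)
                 for k, cm in est.consensus_.items()}
    cosampled = {k: pd.DataFrame(cs, index=samples, columns=samples)
                 for k, cs in est.cosampled_.items()}
    return ConsensusResult(consensus=consensus, cosampled=cosampled,
                           pac=est.pac_, delta_area=est.delta_area_,
                           chosen_k=est.best_k_, assignment=assignment)


def cluster_survival_table(assignment: pd.Series, clinical: pd.DataFrame):
    """Per-cluster sizes plus per-cluster (time, event) tables.

    Samples in the assignment but absent from the clinical table are dropped
    with a warning reporting the count; sizes always sum to the number of
    samples retained (partition conservation).
    """
    clin = clinical.set_index("sample_id")
    present = assignment.index.intersection(clin.index)
    dropped = len(assignment) - len(present)
    if dropped:
        warnings.warn(f"{dropped} sample(s) dropped: missing clinical data",
                      stacklevel=2)
    kept = assignment.loc[present]
    sizes = kept.value_counts().sort_index()
    groups = {
        label: clin.loc[kept.index[kept == label], ["time", "event"]].copy()
        for label in sizes.index
    }
    assert int(sizes.sum()) == len(kept)
    return sizes, groups
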