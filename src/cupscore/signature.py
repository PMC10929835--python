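"""The CupScore: a per-sample cuproptosis-pattern signature score.

The score is GGI-like: genes in the prognostic pattern-DEG pool are
z-scored on the training cohort, the first two principal axes of the
standardised samples × genes array are extracted by SVD, and a sample's
score is the sum of its projections on those two axes,

    score_s = Σ_i (w1_i + w2_i) · z_si,

summing over pool genes i. Axis signs are fixed deterministically (largest
absolute loading positive), and optionally both axes are flipped together
so that high score tracks high regulator-panel expression. An optional
L1-penalised Cox stage sparsifies the gene pool before the PCA. New
cohorts are scored with the training centering/scaling, making the fitted
model portable.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .containers import ExpressionMatrix
from .survival import best_cutpoint, efron_loglik


class CupScoreSignature(BaseEstimator, TransformerMixin):
    """PCA-based signature score (scikit-learn transformer).

    Parameters
    ----------
    genes : list of str, optional
        Gene pool; defaults to every column of the training frame.
    orient_panel : list of str, optional
        Regulator panel used to orient the score: if the training scores
        correlate negatively with mean panel expression, both axes are
        flipped together so high score ⇔ high regulator expression.
    standardize : bool
        z-score genes on the training cohort before the SVD.

    Attributes
    ----------
    genes_ : list of str
        Genes retained after dropping constant ones.
    mean_, scale_ : ndarray
        Training centering and scaling per gene.
    loadings1_, loadings2_ : ndarray
        First two principal-axis loadings (unit norm, orthogonal).
    flipped_ : bool
        Whether the panel-orientation flip was applied.
    training_scores_ : pandas.Series
        Scores of the training samples.
    """

    def __init__(self, genes=None, orient_panel=None, standardize: bool = True):
        self.genes = genes
        self.orient_panel = orient_panel
        self.standardize = standardize

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(X)
        pool = list(self.genes) if self.genes is not None else list(X.columns)
        missing = [g for g in pool if g not in X.columns]
        if missing:
            raise KeyError(f"pool genes absent from matrix: {missing}")
        if len(pool) < 2:
            raise ValueError("gene pool must contain at least 2 genes")
        if len(X) < 3:
            raise ValueError("need at least 3 training samples")

        # contiguous copy: keeps reductions/SVD bit-reproducible regardless
        # of the caller's memory layout
        x = np.ascontiguousarray(X[pool].to_numpy(dtype=float))
        sd = x.std(axis=0, ddof=1)
        constant = sd == 0
        if constant.any():
            dropped = [g for g, c in zip(pool, constant) if c]
            warnings.warn(f"constant gene(s) dropped from pool: {dropped}",
                          stacklevel=2)
            pool = [g for g, c in zip(pool, constant) if not c]
            if len(pool) < 2:
                raise ValueError("gene pool collapsed below 2 genes")
            x = np.ascontiguousarray(X[pool].to_numpy(dtype=float))
            sd = x.std(axis=0, ddof=1)

        mean = x.mean(axis=0)
        if not self.standardize:
            sd = np.ones_like(sd)
        z = (x - mean) / sd

        _, _, vt = np.linalg.svd(z, full_matrices=False)
        w1, w2 = vt[0].copy(), vt[1].copy()
        # deterministic orientation: largest-|loading| positive
        for w in (w1, w2):
            if w[np.argmax(np.abs(w))] < 0:
                w *= -1.0

        scores = z @ (w1 + w2)
        flipped = False
        if self.orient_panel is not None:
            panel = [g for g in self.orient_panel if g in X.columns]
            if panel:
                panel_mean = X[panel].mean(axis=1).to_numpy(dtype=float)
                r = np.corrcoef(scores, panel_mean)[0, 1]
                if np.isfinite(r) and r < 0:
                    w1, w2, scores, flipped = -w1, -w2, -scores, True

        self.genes_ = pool
        self.mean_ = mean
        self.scale_ = sd
        self.loadings1_ = w1
        self.loadings2_ = w2
        self.flipped_ = flipped
        self.training_scores_ = pd.Series(scores, index=X.index,
                                          name="cupscore")
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "genes_")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(X)
        missing = [g for g in self.genes_ if g not in X.columns]
        if missing:
            raise KeyError(f"model genes absent from matrix: {missing}")
        z = (X[self.genes_].to_numpy(dtype=float) - self.mean_) / self.scale_
        return z @ (self.loadings1_ + self.loadings2_)

    def score_series(self, X: pd.DataFrame) -> pd.Series:
        return pd.Series(self.transform(X), index=X.index, name="cupscore")

    def to_dict(self) -> dict:
        check_is_fitted(self, "genes_")
        return {
            "genes": list(self.genes_),
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "loadings1": self.loadings1_.tolist(),
            "loadings2": self.loadings2_.tolist(),
            "flipped": bool(self.flipped_),
            "standardize": bool(self.standardize),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "CupScoreSignature":
        model = cls(genes=payload["genes"],
                    standardize=payload.get("standardize", True))
        model.genes_ = list(payload["genes"])
        model.mean_ = np.asarray(payload["mean"], dtype=float)
        model.scale_ = np.asarray(payload["scale"], dtype=float)
        model.loadings1_ = np.asarray(payload["loadings1"], dtype=float)
        model.loadings2_ = np.asarray(payload["loadings2"], dtype=float)
        model.flipped_ = bool(payload["flipped"])
        model.training_scores_ = pd.Series(dtype=float)
        return model

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "CupScoreSignature":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_cupscore(matrix, gene_pool, orient_panel=None) -> CupScoreSignature:
    """Fit the signature on a genes × samples matrix restricted to a pool."""
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    return CupScoreSignature(genes=list(gene_pool),
                             orient_panel=orient_panel).fit(values.T)


def score_samples(model: CupScoreSignature, matrix) -> pd.Series:
    """Score samples of a genes × samples matrix with a fitted model."""
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    return model.score_series(values.T)


def assign_groups(scores: pd.Series, cutoff, clinical: pd.DataFrame = None,
                  n_perm: int = 1000, seed: int | None = None):
    """Split samples into low/high score groups at a cutoff.

    ``cutoff='auto'`` selects the maximally selected log-rank cutpoint,
    which requires a clinical table aligned with the scores. Returns a
    DataFrame (score, group) plus the cutoff used; high ⇔ score > cutoff.
    """
    scores = pd.Series(scores)
    if isinstance(cutoff, str):
        if cutoff != "auto":
            raise ValueError(f"unknown cutoff {cutoff!r}")
        if clinical is None:
            raise ValueError("cutoff='auto' needs a clinical table")
        clin = clinical.set_index("sample_id").loc[scores.index,
                                                   ["time", "event"]]
        cp = best_cutpoint(scores, clin, n_perm=n_perm, seed=seed)
        cutoff = cp.cutoff
    cutoff = float(cutoff)
    group = np.where(scores.to_numpy() > cutoff, "high", "low")
    out = pd.DataFrame({"score": scores, "group": group}, index=scores.index)
    sizes = out["group"].value_counts()
    assert int(sizes.sum()) == len(scores)
    return out, cutoff


def lasso_select(matrix, clinical: pd.DataFrame, n_folds: int = 10,
                 seed: int | None = None, alphas=None) -> list[str]:
    """L1-penalised Cox gene sparsification with CV deviance + 1-SE rule.

    The regularisation path is fitted by coordinate descent on the
    penalised Cox partial likelihood (glmnet-style); the penalty is chosen
    by K-fold cross-validated partial-likelihood deviance with the 1-SE
    rule, and genes with non-zero coefficients at that penalty are
    returned. If no penalty yields non-empty support the full input set is
    returned with a warning (stage skipped).
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    genes = list(values.index)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    clin = clinical.set_index("sample_id")[["time", "event"]]
    common = values.columns.intersection(clin.index)
    clin = clin.loc[common]
    n_events = int(clin["event"].sum())
    if n_events < n_folds:
        raise ValueError(f"{n_events} events cannot support {n_folds} folds")

    X = values[common].T.to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    y = Surv.from_arrays(event=clin["event"].astype(bool).to_numpy(),
                         time=clin["time"].to_numpy(dtype=float))
    time = clin["time"].to_numpy(dtype=float)
    event = clin["event"].to_numpy(dtype=int)

    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas,
                                  fit_baseline_model=False)
    path.fit(X, y)
    alphas_path = np.asarray(path.alphas_)

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    deviance = np.full((n_folds, alphas_path.size), np.nan)
    for f, (tr, _te) in enumerate(kf.split(X)):
        fold = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas_path,
                                      fit_baseline_model=False)
        fold.fit(X[tr], y[tr])
        # the path solver may stop early; align on the alphas it kept
        kept = {round(float(a), 12): i
                for i, a in enumerate(np.asarray(fold.alphas_))}
        for a, alpha in enumerate(alphas_path):
            i = kept.get(round(float(alpha), 12))
            if i is None:
                continue
            beta = fold.coef_[:, i]
            # Verweij & van Houwelingen CV partial-likelihood deviance
            ll_all = efron_loglik(time, event, X, beta)
            ll_tr = efron_loglik(time[tr], event[tr], X[tr], beta)
            deviance[f, a] = -2.0 * (ll_all - ll_tr)
    complete = ~np.isnan(deviance).any(axis=0)
    if not complete.any():
        warnings.warn("cross-validation path empty; returning the full "
                      "gene pool", stacklevel=2)
        return genes
    deviance = deviance[:, complete]
    alphas_path = alphas_path[complete]
    coef_path = path.coef_[:, complete]
    cvm = deviance.mean(axis=0)
    cvse = deviance.std(axis=0, ddof=1) / np.sqrt(n_folds)
    best = int(np.argmin(cvm))
    # 1-SE rule: sparsest model within one SE of the minimum
    threshold = cvm[best] + cvse[best]
    candidates = np.flatnonzero(cvm <= threshold)
    chosen = int(candidates[np.argmax(alphas_path[candidates])])

    coefs = coef_path[:, chosen]
    support = [g for g, b in zip(genes, coefs) if b != 0.0]
    if not support:
        warnings.warn("LASSO support empty at the chosen penalty; "
                      "returning the full gene pool", stacklevel=2)
        return genes
    return support
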