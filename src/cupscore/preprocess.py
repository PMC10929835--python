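"""Expression preprocessing: FPKM→TPM conversion and ComBat batch correction.

ComBat is the parametric empirical-Bayes location/scale model: per-gene
standardisation against a batch-design fit, per-batch additive (gamma) and
multiplicative (delta²) effect estimates shrunk toward cross-gene parametric
priors (normal for gamma, inverse-gamma for delta²) by the standard iterative
EB updates, then back-transformation. No model covariates are used.

Note the EB shrinkage intentionally leaves a small residual batch effect of
the order of the batch-mean estimation noise; that is the price paid for not
over-fitting gene-level effects, and it means re-applying the correction to
already-corrected data nudges values slightly rather than leaving them
bit-identical.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import ExpressionMatrix


def fpkm_to_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Convert raw FPKM to log2(TPM+1).

    TPM_gs = FPKM_gs / sum_g FPKM_gs * 1e6, so each sample's pre-log TPM
    column sums to exactly 1e6; output is log2(TPM+1).
    """
    if matrix.log_scale:
        raise ValueError("input flagged as log-scale; expected raw FPKM")
    fpkm = matrix.values
    if (fpkm.to_numpy() < 0).any():
        raise ValueError("negative FPKM values present")
    colsum = fpkm.sum(axis=0)
    zero = colsum.index[colsum == 0].tolist()
    if zero:
        raise ValueError(f"all-zero FPKM columns for samples: {zero}")
    tpm = fpkm.div(colsum, axis=1) * 1e6
    return ExpressionMatrix(np.log2(tpm + 1.0), batch=matrix.batch)


class ComBat(BaseEstimator, TransformerMixin):
    """Parametric empirical-Bayes batch correction (location + scale).

    scikit-learn style transformer operating on samples × genes arrays;
    the batch label vector is passed to :meth:`fit` / :meth:`fit_transform`.

    Parameters
    ----------
    max_iter : int
        Iteration cap for the EB fixed-point updates.
    tol : float
        Convergence tolerance on the per-batch EB estimates.

    Attributes
    ----------
    grand_mean_ : ndarray of shape (n_genes,)
        Batch-size-weighted gene-wise mean (the standardisation target).
    pooled_var_ : ndarray of shape (n_genes,)
        Gene-wise residual variance after removing batch means.
    constant_genes_ : ndarray of bool
        Genes with zero pooled variance, passed through unadjusted.
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-8):
        self.max_iter = max_iter
        self.tol = tol

    def fit_transform(self, X, y=None, *, batch):
        X = np.asarray(X, dtype=float)
        batch = np.asarray(batch)
        if X.shape[0] != batch.shape[0]:
            raise ValueError("batch length must match number of samples")
        levels, codes = np.unique(batch, return_inverse=True)
        counts = np.bincount(codes)
        if len(levels) < 2:
            # single batch: identity pass-through
            self.grand_mean_ = X.mean(axis=0)
            self.pooled_var_ = X.var(axis=0)
            self.constant_genes_ = np.zeros(X.shape[1], dtype=bool)
            return X.copy()
        singletons = levels[counts < 2]
        if len(singletons):
            raise ValueError(
                f"batches with a single sample cannot be corrected: "
                f"{singletons.tolist()}"
            )
        n, n_genes = X.shape
        n_batches = len(levels)

        batch_means = np.vstack([X[codes == b].mean(axis=0)
                                 for b in range(n_batches)])
        w = counts / n
        grand_mean = w @ batch_means
        resid = X - batch_means[codes]
        pooled_var = (resid ** 2).sum(axis=0) / n

        constant = pooled_var <= 0
        if constant.any():
            warnings.warn(
                f"{int(constant.sum())} constant gene(s) passed through "
                "unadjusted", stacklevel=2,
            )
        safe_var = np.where(constant, 1.0, pooled_var)
        sd = np.sqrt(safe_var)

        Z = (X - grand_mean) / sd

        out = Z.copy()
        for b in range(n_batches):
            idx = codes == b
            nb = counts[b]
            zb = Z[idx]
            gamma_hat = zb.mean(axis=0)
            delta_hat = zb.var(axis=0, ddof=1)

            gamma_bar = gamma_hat.mean()
            tau2 = gamma_hat.var(ddof=1)
            m, v = delta_hat.mean(), delta_hat.var(ddof=1)
            if n_genes < 2 or tau2 <= 0 or v <= 0:
                # too few genes to estimate priors: no shrinkage
                out[idx] = (zb - gamma_hat) / np.sqrt(
                    np.where(delta_hat > 0, delta_hat, 1.0))
                continue
            # inverse-gamma prior shape/scale by moment matching
            lam = (2 * v + m**2) / v
            theta = (m * v + m**3) / v

            gamma_star = gamma_hat.copy()
            delta_star = delta_hat.copy()
            sse0 = ((zb - gamma_hat) ** 2).sum(axis=0)
            for _ in range(self.max_iter):
                g_new = ((nb * tau2 * gamma_hat + delta_star * gamma_bar)
                         / (nb * tau2 + delta_star))
                sse = sse0 + nb * (gamma_hat - g_new) ** 2
                d_new = (theta + 0.5 * sse) / (nb / 2 + lam - 1)
                change = max(np.abs(g_new - gamma_star).max(),
                             np.abs(d_new - delta_star).max())
                gamma_star, delta_star = g_new, d_new
                if change < self.tol:
                    break
            out[idx] = (zb - gamma_star) / np.sqrt(delta_star)

        result = out * sd + grand_mean
        result[:, constant] = X[:, constant]
        self.grand_mean_ = grand_mean
        self.pooled_var_ = pooled_var
        self.constant_genes_ = constant
        return result

    def fit(self, X, y=None, *, batch):
        self.fit_transform(X, batch=batch)
        return self


def batch_correct(matrix: ExpressionMatrix,
                  batch: pd.Series | None = None) -> ExpressionMatrix:
    """Apply ComBat to a genes × samples :class:`ExpressionMatrix`.

    ``batch`` defaults to the matrix's own batch labels. A single batch is an
    identity pass-through; batches of one sample are an error; constant genes
    pass through unadjusted with a warning.
    """
    if batch is None:
        batch = matrix.batch
    if batch is None:
        raise ValueError("no batch labels supplied")
    batch = batch.reindex(matrix.samples)
    corrected = ComBat().fit_transform(
        matrix.to_samples_by_genes().to_numpy(), batch=batch.to_numpy()
    )
    values = pd.DataFrame(corrected.T, index=matrix.genes,
                          columns=matrix.samples)
    return ExpressionMatrix(values, batch=matrix.batch,
                            log_scale=matrix.log_scale)
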