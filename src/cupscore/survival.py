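"""Survival machinery: Kaplan–Meier, log-rank, Cox proportional hazards,
univariate prognostic filtering, maximally selected cutpoints and
time-dependent ROC.

Cox models are fitted with the Efron tie correction (lifelines); the
package also carries its own Efron partial-likelihood evaluator, used for
cross-validated deviance in the LASSO stage and as an independent oracle in
tests. The maximally selected cutpoint scans admissible score thresholds
for the largest absolute standardized two-group log-rank statistic and
calibrates it by label permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.exceptions import ConvergenceError
from scipy.stats import kruskal, mannwhitneyu
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

MAX_ABS_BETA = 15.0


def _check_survival(data: pd.DataFrame) -> pd.DataFrame:
    if not {"time", "event"}.issubset(data.columns):
        raise ValueError("survival data needs 'time' and 'event' columns")
    if len(data) == 0:
        raise ValueError("empty survival data")
    if (data["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not data["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0 or 1")
    return data


@dataclass
class KmCurve:
    """Product-limit estimate: step times, survival, numbers at risk."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p: float


@dataclass
class CoxFit:
    """Per-covariate Cox summary plus model-level diagnostics.

    ``summary`` columns: coef, hr, se, z, p, ci_low, ci_high with
    hr = exp(coef) and ci = exp(coef ± 1.96·se).
    """

    summary: pd.DataFrame
    log_likelihood: float
    converged: bool


@dataclass
class CutpointResult:
    cutoff: float
    statistic: float
    p: float
    n_low: int
    n_high: int


@dataclass
class TdRocResult:
    horizons: np.ndarray
    auc: np.ndarray


def km_estimate(data: pd.DataFrame) -> KmCurve:
    """Kaplan–Meier product-limit estimator with right censoring."""
    data = _check_survival(data)
    km = KaplanMeierFitter()
    km.fit(data["time"], event_observed=data["event"])
    times = km.survival_function_.index.to_numpy(dtype=float)
    surv = km.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = km.event_table["at_risk"].reindex(km.survival_function_.index
                                                ).to_numpy(dtype=float)
    return KmCurve(times=times, survival=surv, at_risk=at_risk)


def logrank(groups) -> LogRankResult:
    """k-sample log-rank test; ``groups`` is a dict or list of survival
    tables (time, event)."""
    if isinstance(groups, dict):
        items = list(groups.items())
    else:
        items = list(enumerate(groups))
    if len(items) < 2:
        raise ValueError("need at least 2 groups")
    frames = []
    for label, df in items:
        df = _check_survival(df)
        frames.append(pd.DataFrame({
            "time": df["time"].to_numpy(),
            "event": df["event"].to_numpy(),
            "group": label,
        }))
    merged = pd.concat(frames, ignore_index=True)
    if merged["event"].sum() == 0:
        raise ValueError("no events in any group")
    res = multivariate_logrank_test(merged["time"], merged["group"],
                                    merged["event"])
    return LogRankResult(statistic=float(res.test_statistic),
                         df=len(items) - 1, p=float(res.p_value))


def cox_fit(data: pd.DataFrame, covariates) -> CoxFit:
    """Cox proportional-hazards fit (Efron ties, Newton–Raphson).

    Monotone-likelihood / separation problems are reported through the
    ``converged`` flag with coefficients capped at |beta| <= 15.
    """
    covariates = list(covariates)
    data = _check_survival(data)
    n_events = int(data["event"].sum())
    if n_events < len(covariates) + 1:
        raise ValueError(
            f"{n_events} events cannot support {len(covariates)} covariates"
        )
    frame = data[["time", "event", *covariates]].dropna()
    constant = [c for c in covariates if frame[c].nunique() <= 1]
    active = [c for c in covariates if c not in constant]
    if not active:
        # all covariates carry no information: beta = 0 by definition
        ll = efron_loglik(frame["time"], frame["event"],
                          np.zeros((len(frame), 1)), [0.0])
        summary = pd.DataFrame({
            "coef": 0.0, "hr": 1.0, "se": np.inf, "z": 0.0, "p": 1.0,
            "ci_low": 0.0, "ci_high": np.inf,
        }, index=covariates)
        return CoxFit(summary=summary, log_likelihood=ll, converged=True)
    covariates = active
    frame = frame[["time", "event", *active]]
    converged = True
    cph = CoxPHFitter()
    try:
        import warnings as _w

        with _w.catch_warnings(record=True) as caught:
            _w.simplefilter("always")
            cph.fit(frame, duration_col="time", event_col="event")
        if any("convergence" in str(c.message).lower()
               or "collinear" in str(c.message).lower() for c in caught):
            converged = False
    except ConvergenceError:
        # retry with a ridge penalty to obtain finite, capped estimates
        converged = False
        cph = CoxPHFitter(penalizer=0.1)
        cph.fit(frame, duration_col="time", event_col="event")

    coef = cph.params_.to_numpy(dtype=float)
    if np.abs(coef).max(initial=0.0) > MAX_ABS_BETA:
        converged = False
        coef = np.clip(coef, -MAX_ABS_BETA, MAX_ABS_BETA)
    se = cph.standard_errors_.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, coef / np.where(se > 0, se, 1.0), 0.0)
    from scipy.stats import norm

    p = 2.0 * norm.sf(np.abs(z))
    p = np.where(coef == 0.0, 1.0, p)
    summary = pd.DataFrame({
        "coef": coef,
        "hr": np.exp(coef),
        "se": se,
        "z": z,
        "p": p,
        "ci_low": np.exp(coef - 1.96 * se),
        "ci_high": np.exp(coef + 1.96 * se),
    }, index=covariates)
    if constant:
        const = pd.DataFrame({
            "coef": 0.0, "hr": 1.0, "se": np.inf, "z": 0.0, "p": 1.0,
            "ci_low": 0.0, "ci_high": np.inf,
        }, index=constant)
        summary = pd.concat([summary, const])
    return CoxFit(summary=summary,
                  log_likelihood=float(cph.log_likelihood_),
                  converged=converged)


def efron_loglik(time, event, X, beta) -> float:
    """Efron-tie Cox log partial likelihood at a given coefficient vector.

    Independent of the lifelines fitting path; used as a brute-force oracle
    and for cross-validated deviance in the LASSO stage.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != time.size:
        X = X.T
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    eta = X @ beta
    # guard overflow for capped/huge betas
    eta = np.clip(eta, -500, 500)
    theta = np.exp(eta)

    order = np.argsort(time, kind="stable")
    time, event, eta, theta = time[order], event[order], eta[order], theta[order]

    ll = 0.0
    n = time.size
    i = 0
    # iterate unique times ascending; risk set = samples with time >= t
    suffix = np.concatenate([np.cumsum(theta[::-1])[::-1], [0.0]])
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        d_idx = [k for k in range(i, j) if event[k] == 1]
        d = len(d_idx)
        if d > 0:
            risk_sum = suffix[i]
            tie_sum = theta[d_idx].sum()
            ll += eta[d_idx].sum()
            for r in range(d):
                ll -= np.log(risk_sum - (r / d) * tie_sum)
        i = j
    return float(ll)


def prognostic_filter(matrix, clinical: pd.DataFrame,
                      p_cut: float = 0.05):
    """Univariate Cox per gene on z-scored expression; keep Wald p < p_cut.

    Returns (retained gene list, per-gene summary DataFrame with coef, hr,
    se, z, p). Hazard ratios are per standard deviation of expression.
    """
    from .containers import ExpressionMatrix

    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    clin = clinical.set_index("sample_id")[["time", "event"]]
    common = values.columns.intersection(clin.index)
    clin = clin.loc[common]
    _check_survival(clin)
    rows = []
    for gene in values.index:
        x = values.loc[gene, common].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0:
            continue
        frame = clin.copy()
        frame["x"] = (x - x.mean()) / sd
        fit = cox_fit(frame, ["x"])
        s = fit.summary.loc["x"]
        rows.append((gene, s["coef"], s["hr"], s["se"], s["z"], s["p"]))
    table = pd.DataFrame(rows, columns=["gene", "coef", "hr", "se", "z", "p"]
                         ).set_index("gene")
    retained = table.index[table["p"] < p_cut].tolist()
    return retained, table


def _logrank_scan(time, event, score_rank, splits):
    """Standardized two-group log-rank statistics for nested score splits.

    ``splits`` are rank thresholds j; the high group at split j consists of
    samples with score rank > j. Returns the z statistic per split.
    """
    n = time.size
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    e_sorted = event[order]
    r_sorted = score_rank[order]

    high = r_sorted[:, None] > splits[None, :]          # n × n_splits
    # suffix sums over the time ordering = at-risk counts
    y1 = np.cumsum(high[::-1], axis=0)[::-1].astype(float)
    y = np.arange(n, 0, -1, dtype=float)

    starts = np.flatnonzero(np.r_[True, t_sorted[1:] != t_sorted[:-1]])
    d = np.add.reduceat(e_sorted.astype(float), starts)
    o1 = np.add.reduceat(e_sorted[:, None] * high, starts, axis=0)
    y1_t = y1[starts]
    y_t = y[starts]

    frac = y1_t / y_t[:, None]
    e1 = d[:, None] * frac
    with np.errstate(invalid="ignore", divide="ignore"):
        v = (d[:, None] * frac * (1.0 - frac)
             * ((y_t - d) / np.maximum(y_t - 1.0, 1.0))[:, None])
    u = (o1 - e1).sum(axis=0)
    var = v.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(var > 0, u / np.sqrt(var), 0.0)


def best_cutpoint(scores, data: pd.DataFrame, min_prop: float = 0.1,
                  n_perm: int = 1000, seed: int | None = None
                  ) -> CutpointResult:
    """Maximally selected log-rank cutpoint with permutation p-value.

    Scans unique score values keeping both groups at least
    ``min_prop``·n large, maximises |standardized log-rank| and assesses
    significance by permuting the score–outcome pairing.
    """
    scores = pd.Series(scores)
    data = _check_survival(data)
    if len(scores) != len(data):
        raise ValueError("scores and survival data differ in length")
    n = len(scores)
    if n < 20:
        raise ValueError("need at least 20 samples for cutpoint selection")

    s = scores.to_numpy(dtype=float)
    time = data["time"].to_numpy(dtype=float)
    event = data["event"].to_numpy(dtype=int)

    order = np.argsort(s, kind="stable")
    sorted_s = s[order]
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)

    min_n = max(1, int(np.ceil(min_prop * n)))
    # split after rank j (0-based): low group = ranks <= j has j+1 members;
    # admissible when both sides large enough and the threshold separates
    # distinct score values
    js = np.array([j for j in range(min_n - 1, n - min_n)
                   if sorted_s[j] < sorted_s[j + 1]], dtype=int)
    if js.size == 0:
        raise ValueError("no admissible cutpoint (scores too concentrated)")

    z = _logrank_scan(time, event, rank, js)
    best = int(np.argmax(np.abs(z)))
    stat = float(np.abs(z[best]))
    cutoff = float(sorted_s[js[best]])

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        zp = _logrank_scan(time, event, rank[perm], js)
        if np.max(np.abs(zp)) >= stat:
            exceed += 1
    p = (exceed + 1.0) / (n_perm + 1.0)
    n_low = int(js[best] + 1)
    return CutpointResult(cutoff=cutoff, statistic=stat, p=p,
                          n_low=n_low, n_high=n - n_low)


def td_roc(scores, data: pd.DataFrame, horizons) -> TdRocResult:
    """Cumulative-case / dynamic-control AUC(t) with IPCW weighting."""
    scores = np.asarray(scores, dtype=float)
    data = _check_survival(data)
    horizons = np.atleast_1d(np.asarray(horizons, dtype=float))
    times = data["time"].to_numpy(dtype=float)
    events = data["event"].to_numpy(dtype=bool)
    event_times = times[events]
    if event_times.size == 0:
        raise ValueError("no events observed; AUC(t) undefined")
    lo, hi = event_times.min(), times.max()
    bad = (horizons < lo) | (horizons >= hi)
    if bad.any():
        raise ValueError(
            f"horizons {horizons[bad].tolist()} outside the evaluable "
            f"range [{lo}, {hi})"
        )
    y = Surv.from_arrays(event=events, time=times)
    auc, _ = cumulative_dynamic_auc(y, y, scores, horizons)
    return TdRocResult(horizons=horizons, auc=np.atleast_1d(auc))


def group_compare(values, groups, test: str = "wilcoxon"):
    """Rank-based comparison of a numeric variable across groups.

    ``wilcoxon`` (exactly 2 groups) uses the exact rank-sum distribution
    when the combined n <= 10 and there are no ties, the normal
    approximation otherwise; ``kruskal`` handles >= 2 groups.
    Returns (statistic, p).
    """
    values = pd.Series(values).to_numpy(dtype=float)
    groups = pd.Series(groups)
    levels = sorted(groups.unique())
    samples = [values[(groups == g).to_numpy()] for g in levels]
    if test == "wilcoxon":
        if len(levels) != 2:
            raise ValueError("wilcoxon requires exactly 2 groups")
        n_total = values.size
        has_ties = pd.Series(values).duplicated().any()
        method = "exact" if (n_total <= 10 and not has_ties) else "asymptotic"
        res = mannwhitneyu(samples[0], samples[1], alternative="two-sided",
                           method=method)
        return float(res.statistic), float(res.pvalue)
    if test == "kruskal":
        if all(np.array_equal(samples[0], s) for s in samples[1:]):
            return 0.0, 1.0
        res = kruskal(*samples)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")
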