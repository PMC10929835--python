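import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from cupscore.survival import (best_cutpoint, cox_fit, efron_loglik,
                               group_compare, km_estimate, logrank,
                               prognostic_filter, td_roc, _logrank_scan)


def _surv(times, events):
    return pd.DataFrame({"time": np.asarray(times, dtype=float),
                         "event": np.asarray(events, dtype=int)})


class TestKaplanMeier:
    def test_no_censoring_is_empirical_survival(self):
        km = km_estimate(_surv([1, 2, 3], [1, 1, 1]))
        np.testing.assert_allclose(km.survival[1:], [2 / 3, 1 / 3, 0.0])

    def test_all_censored_stays_at_one(self):
        km = km_estimate(_surv([1, 2, 3], [0, 0, 0]))
        np.testing.assert_array_equal(km.survival, 1.0)

    def test_hand_product_limit_with_censoring(self):
        # events at 1, 3, 5; censored at 2, 4, 6:
        # S(1) = 5/6, S(3) = 5/6 * 3/4 = 5/8, S(5) = 5/8 * 1/2 = 5/16
        km = km_estimate(_surv([1, 2, 3, 4, 5, 6], [1, 0, 1, 0, 1, 0]))
        lookup = dict(zip(km.times, km.survival))
        assert lookup[1.0] == pytest.approx(5 / 6)
        assert lookup[3.0] == pytest.approx(5 / 8)
        assert lookup[5.0] == pytest.approx(5 / 16)

    def test_monotone_from_one(self):
        rng = np.random.default_rng(0)
        km = km_estimate(_surv(rng.exponential(10, 50),
                               rng.integers(0, 2, 50)))
        assert km.survival[0] == 1.0
        assert (np.diff(km.survival) <= 1e-12).all()

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(5, 40)
        km = km_estimate(_surv(times, np.ones(40)))
        for t, s in zip(km.times, km.survival):
            assert s == pytest.approx(1.0 - np.mean(times <= t))


class TestLogrank:
    def test_identical_groups_null(self):
        g = _surv([1, 2, 3, 4], [1, 1, 0, 1])
        res = logrank({"a": g, "b": g.copy()})
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_enumerated_risk_sets(self):
        # g1 events at 1, 2; g2 events at 3, 4:
        # U = 2 - (1/2 + 1/3) = 7/6, V = 1/4 + 2/9 = 17/36,
        # chi-square = U^2 / V = 49/17
        res = logrank({"a": _surv([1, 2], [1, 1]),
                       "b": _surv([3, 4], [1, 1])})
        assert res.statistic == pytest.approx(49 / 17)
        assert res.df == 1

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(2)
        rejections = 0
        reps = 400
        for _ in range(reps):
            t1, t2 = rng.exponential(10, 100), rng.exponential(10, 100)
            res = logrank({"a": _surv(t1, np.ones(100)),
                           "b": _surv(t2, np.ones(100))})
            rejections += res.p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_matches_cutpoint_scan_statistic(self):
        rng = np.random.default_rng(3)
        n = 60
        times = rng.exponential(10, n)
        events = rng.integers(0, 2, n)
        group = np.arange(n) >= 30
        chi2 = logrank({"a": _surv(times[~group], events[~group]),
                        "b": _surv(times[group], events[group])}).statistic
        z = _logrank_scan(times, events, np.arange(n), np.array([29]))
        assert z[0] ** 2 == pytest.approx(chi2, rel=1e-9)


class TestCox:
    def test_constant_covariate_is_null(self):
        data = _surv([1, 2, 3, 4, 5, 6], [1, 1, 1, 0, 1, 0])
        data["x"] = 0.0
        fit = cox_fit(data, ["x"])
        assert fit.summary.loc["x", "coef"] == 0.0
        assert fit.summary.loc["x", "p"] == 1.0

    def test_parameter_recovery(self):
        rng = np.random.default_rng(4)
        n, beta = 500, 0.5
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.01 * np.exp(beta * x)))
        c = rng.exponential(np.quantile(t, 0.9), size=n)
        data = _surv(np.minimum(t, c), (t <= c).astype(int))
        data["x"] = x
        fit = cox_fit(data, ["x"])
        assert abs(fit.summary.loc["x", "coef"] - beta) < 0.15
        assert fit.converged

    def test_tiny_fit_matches_grid_oracle(self):
        data = _surv([2.0, 5.0, 1.0, 7.0, 3.0], [1, 1, 1, 0, 1])
        data["x"] = [0.5, -1.0, 1.5, 0.3, -0.7]
        fit = cox_fit(data, ["x"])
        beta_hat = fit.summary.loc["x", "coef"]
        x = data["x"].to_numpy()[:, None]
        ll = lambda b: efron_loglik(data["time"], data["event"], x, [b])
        res = minimize_scalar(lambda b: -ll(b), bounds=(-10, 10),
                              method="bounded")
        assert abs(beta_hat - res.x) < 1e-3
        assert abs(fit.log_likelihood - ll(beta_hat)) < 1e-6
        # dominance over a grid of alternatives
        for b in np.linspace(-5, 5, 101):
            assert ll(beta_hat) >= ll(b) - 1e-8

    def test_hazard_ratio_and_ci_identities(self):
        rng = np.random.default_rng(5)
        n = 120
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.02 * np.exp(0.6 * x)))
        data = _surv(t, np.ones(n))
        data["x"] = x
        s = cox_fit(data, ["x"]).summary.loc["x"]
        assert s["hr"] == pytest.approx(np.exp(s["coef"]), rel=1e-12)
        assert s["ci_low"] == pytest.approx(
            np.exp(s["coef"] - 1.96 * s["se"]), rel=1e-12)


class TestPrognosticFilter:
    def test_null_retention_near_alpha(self):
        rng = np.random.default_rng(6)
        n, g = 450, 500
        df = pd.DataFrame(rng.normal(size=(g, n)),
                          index=[f"g{i}" for i in range(g)],
                          columns=[f"s{j}" for j in range(n)])
        clinical = pd.DataFrame({
            "sample_id": df.columns,
            "time": rng.exponential(100, n),
            "event": rng.integers(0, 2, n),
        })
        retained, table = prognostic_filter(df, clinical)
        assert 0.03 <= len(retained) / g <= 0.07

    def test_planted_risk_gene_retained_with_positive_sign(self):
        rng = np.random.default_rng(7)
        n = 300
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.01 * np.exp(0.8 * x)))
        clinical = pd.DataFrame({
            "sample_id": [f"s{j}" for j in range(n)],
            "time": t, "event": np.ones(n, dtype=int),
        })
        df = pd.DataFrame({f"s{j}": [x[j], rng.normal()]
                           for j in range(n)}, index=["risk", "noise"])
        retained, table = prognostic_filter(df, clinical)
        assert "risk" in retained
        assert table.loc["risk", "coef"] > 0

    def test_zero_pcut_keeps_nothing(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(3, 40)),
                          index=list("abc"),
                          columns=[f"s{j}" for j in range(40)])
        clinical = pd.DataFrame({"sample_id": df.columns,
                                 "time": rng.exponential(10, 40),
                                 "event": 1})
        retained, _ = prognostic_filter(df, clinical, p_cut=0.0)
        assert retained == []


class TestBestCutpoint:
    def test_constant_scores_rejected(self):
        data = _surv(np.arange(1, 31), np.ones(30))
        with pytest.raises(ValueError, match="admissible"):
            best_cutpoint(np.ones(30), data, n_perm=10, seed=0)

    def test_monotone_hazard_detected(self):
        n = 60
        times = np.arange(1, n + 1, dtype=float)
        data = _surv(times, np.ones(n))
        scores = -times  # higher score = shorter survival, exact ranking
        res = best_cutpoint(scores, data, n_perm=400, seed=0)
        assert res.p < 0.01
        # the high group is the short-survival side of the split
        high = scores > res.cutoff
        assert times[high].mean() < times[~high].mean()
        # chosen split dominates the median split by construction
        rank = np.empty(n, dtype=int)
        rank[np.argsort(scores, kind="stable")] = np.arange(n)
        z_med = _logrank_scan(times, np.ones(n, dtype=int), rank,
                              np.array([n // 2]))
        assert res.statistic >= abs(z_med[0]) - 1e-9

    def test_null_scores_rejection_rate(self):
        rng = np.random.default_rng(9)
        n = 80
        rejections = 0
        reps = 200
        for r in range(reps):
            data = _surv(rng.exponential(10, n), np.ones(n))
            scores = rng.normal(size=n)
            res = best_cutpoint(scores, data, n_perm=100, seed=r)
            rejections += res.p < 0.05
        # 0.05 nominal level plus ~2.6 binomial standard errors at 200 reps
        assert rejections / reps <= 0.09

    def test_group_sizes_respect_min_prop(self):
        rng = np.random.default_rng(10)
        n = 100
        data = _surv(rng.exponential(10, n), np.ones(n))
        res = best_cutpoint(rng.normal(size=n), data, min_prop=0.2,
                            n_perm=20, seed=0)
        assert res.n_low >= 20 and res.n_high >= 20
        assert res.n_low + res.n_high == n


class TestTdRoc:
    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(11)
        n = 450
        data = _surv(rng.exponential(100, n), np.ones(n))
        res = td_roc(rng.normal(size=n), data, horizons=[80.0])
        assert abs(res.auc[0] - 0.5) < 0.05

    def test_perfect_ranking_auc_one(self):
        times = np.arange(1.0, 41.0)
        data = _surv(times, np.ones(40))
        res = td_roc(-times, data, horizons=[20.5])
        assert res.auc[0] == pytest.approx(1.0)

    def test_sign_reversal_flips_auc(self):
        rng = np.random.default_rng(12)
        n = 200
        scores = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.05 * np.exp(0.5 * scores)))
        data = _surv(t, np.ones(n))
        h = [float(np.quantile(t, 0.4))]
        a = td_roc(scores, data, horizons=h).auc[0]
        b = td_roc(-scores, data, horizons=h).auc[0]
        assert a + b == pytest.approx(1.0, abs=1e-9)

    def test_horizon_beyond_events_is_error(self):
        data = _surv([1.0, 2.0, 3.0], [1, 1, 1])
        with pytest.raises(ValueError, match="outside"):
            td_roc([3.0, 2.0, 1.0], data, horizons=[10.0])


class TestGroupCompare:
    def test_exact_wilcoxon_separated_triplets(self):
        stat, p = group_compare([1, 2, 3, 4, 5, 6],
                                ["a"] * 3 + ["b"] * 3, "wilcoxon")
        assert p == pytest.approx(0.1)  # 2 of the 20 assignments as extreme

    def test_identical_groups_boundary(self):
        _, p = group_compare([1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                             ["a"] * 3 + ["b"] * 3, "wilcoxon")
        assert p >= 0.99

    def test_three_identical_groups_kruskal(self):
        stat, p = group_compare([1, 2, 3] * 3,
                                ["a"] * 3 + ["b"] * 3 + ["c"] * 3, "kruskal")
        assert stat == 0.0 and p == 1.0
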