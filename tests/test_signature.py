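import numpy as np
import pandas as pd
import pytest

from cupscore.signature import (CupScoreSignature, assign_groups,
                                fit_cupscore, lasso_select, score_samples)
from cupscore.survival import cox_fit


def _frame(X, genes=None):
    X = np.asarray(X, dtype=float)
    genes = genes or [f"g{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=genes,
                        index=[f"s{j}" for j in range(X.shape[0])])


class TestFit:
    def test_two_correlated_genes_rank_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=30)
        X = _frame(np.column_stack([a, 2.0 * a + 1.0]))
        model = CupScoreSignature().fit(X)
        np.testing.assert_allclose(np.abs(model.loadings1_),
                                   [1 / np.sqrt(2)] * 2, atol=1e-10)
        assert model.loadings1_[np.argmax(np.abs(model.loadings1_))] > 0
        # second axis carries no variance
        z = (X.to_numpy() - model.mean_) / model.scale_
        np.testing.assert_allclose(z @ model.loadings2_, 0.0, atol=1e-8)

    def test_axes_unit_norm_and_orthogonal(self):
        rng = np.random.default_rng(1)
        model = CupScoreSignature().fit(_frame(rng.normal(size=(40, 8))))
        assert np.linalg.norm(model.loadings1_) == pytest.approx(1.0)
        assert np.linalg.norm(model.loadings2_) == pytest.approx(1.0)
        assert abs(model.loadings1_ @ model.loadings2_) < 1e-8

    def test_gene_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        X = _frame(rng.normal(size=(25, 6)))
        model = CupScoreSignature().fit(X)
        perm = [3, 0, 5, 1, 4, 2]
        Xp = X.iloc[:, perm]
        model_p = CupScoreSignature().fit(Xp)
        np.testing.assert_allclose(model_p.loadings1_,
                                   model.loadings1_[perm], atol=1e-10)
        np.testing.assert_allclose(model_p.training_scores_,
                                   model.training_scores_, atol=1e-10)

    def test_loadings_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        X = _frame(rng.normal(size=(4, 3)))
        model = CupScoreSignature().fit(X)
        z = (X.to_numpy() - model.mean_) / model.scale_
        evals, evecs = np.linalg.eigh(z.T @ z)
        for w, col in ((model.loadings1_, -1), (model.loadings2_, -2)):
            v = evecs[:, col]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            np.testing.assert_allclose(w, v, atol=1e-8)

    def test_training_scores_equal_svd_projection(self):
        rng = np.random.default_rng(4)
        X = _frame(rng.normal(size=(20, 7)))
        model = CupScoreSignature().fit(X)
        z = (X.to_numpy() - model.mean_) / model.scale_
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        proj = u[:, :2] * s[:2]
        signs = [1.0 if vt[i][np.argmax(np.abs(vt[i]))] > 0 else -1.0
                 for i in range(2)]
        expected = signs[0] * proj[:, 0] + signs[1] * proj[:, 1]
        np.testing.assert_allclose(model.training_scores_, expected,
                                   atol=1e-8)

    def test_constant_gene_dropped(self):
        rng = np.random.default_rng(5)
        X = _frame(rng.normal(size=(15, 3)))
        X["g1"] = 4.0
        with pytest.warns(UserWarning, match="constant"):
            model = CupScoreSignature().fit(X)
        assert "g1" not in model.genes_

    def test_pool_collapse_is_error(self):
        X = _frame(np.ones((10, 2)))
        X["g0"] = np.arange(10.0)
        with pytest.warns(UserWarning, match="constant"):
            with pytest.raises(ValueError, match="collapsed"):
                CupScoreSignature().fit(X)

    def test_deterministic_refit(self):
        rng = np.random.default_rng(6)
        X = _frame(rng.normal(size=(30, 10)))
        a = CupScoreSignature().fit(X)
        b = CupScoreSignature().fit(X.copy())
        assert a.to_dict() == b.to_dict()


class TestScoring:
    def test_training_mean_sample_scores_zero(self):
        rng = np.random.default_rng(7)
        X = _frame(rng.normal(size=(20, 5)))
        model = CupScoreSignature().fit(X)
        centre = pd.DataFrame([model.mean_], columns=model.genes_,
                              index=["centre"])
        assert model.transform(centre)[0] == pytest.approx(0.0, abs=1e-12)

    def test_linearity_in_z_profile(self):
        rng = np.random.default_rng(8)
        X = _frame(rng.normal(size=(20, 5)))
        model = CupScoreSignature().fit(X)
        z = rng.normal(size=5)
        one = pd.DataFrame([model.mean_ + model.scale_ * z],
                           columns=model.genes_)
        two = pd.DataFrame([model.mean_ + model.scale_ * 2 * z],
                           columns=model.genes_)
        assert model.transform(two)[0] == pytest.approx(
            2.0 * model.transform(one)[0])

    def test_invariant_to_non_pool_genes(self):
        rng = np.random.default_rng(9)
        X = _frame(rng.normal(size=(20, 6)))
        pool = ["g0", "g2", "g4"]
        model = CupScoreSignature(genes=pool).fit(X)
        scores = model.transform(X)
        wider = X.copy()
        wider["extra"] = rng.normal(size=20)
        np.testing.assert_allclose(model.transform(wider), scores)

    def test_missing_model_genes_listed(self):
        rng = np.random.default_rng(10)
        X = _frame(rng.normal(size=(10, 4)))
        model = CupScoreSignature().fit(X)
        with pytest.raises(KeyError, match="g3"):
            model.transform(X.drop(columns=["g3"]))

    def test_matrix_wrappers_and_serialisation(self, tmp_path):
        rng = np.random.default_rng(11)
        values = pd.DataFrame(rng.normal(size=(6, 15)),
                              index=[f"g{i}" for i in range(6)],
                              columns=[f"s{j}" for j in range(15)])
        model = fit_cupscore(values, ["g0", "g1", "g2"])
        scores = score_samples(model, values)
        assert list(scores.index) == list(values.columns)
        path = tmp_path / "model.json"
        model.save(path)
        back = CupScoreSignature.load(path)
        np.testing.assert_allclose(back.score_series(values.T), scores)

    def test_panel_orientation_flip(self):
        rng = np.random.default_rng(12)
        risk = rng.normal(size=40)
        X = _frame(np.column_stack([risk + 0.1 * rng.normal(size=40),
                                    risk + 0.1 * rng.normal(size=40),
                                    -risk + 0.1 * rng.normal(size=40)]),
                   genes=["p1", "p2", "q"])
        # orientation panel = p1, p2: score must correlate positively with
        # their mean regardless of the SVD's arbitrary sign
        model = CupScoreSignature(genes=["p1", "p2", "q"],
                                  orient_panel=["p1", "p2"]).fit(X)
        r = np.corrcoef(model.training_scores_,
                        X[["p1", "p2"]].mean(axis=1))[0, 1]
        assert r > 0


class TestAssignGroups:
    def test_cutoff_below_minimum_all_high(self):
        scores = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        out, cutoff = assign_groups(scores, 0.0)
        assert (out["group"] == "high").all()

    def test_sizes_sum_to_total(self):
        rng = np.random.default_rng(13)
        scores = pd.Series(rng.normal(size=383),
                           index=[f"s{j}" for j in range(383)])
        out, _ = assign_groups(scores, float(np.median(scores)))
        sizes = out["group"].value_counts()
        assert int(sizes.sum()) == 383

    def test_high_iff_above_cutoff(self):
        scores = pd.Series([0.1, 0.3054, 0.4], index=list("abc"))
        out, _ = assign_groups(scores, 0.3054)
        assert out.loc["a", "group"] == "low"
        assert out.loc["b", "group"] == "low"   # strictly greater only
        assert out.loc["c", "group"] == "high"


class TestLassoSelect:
    def _cohort(self, seed=0, n=450, n_noise=50, beta=0.8):
        rng = np.random.default_rng(seed)
        planted = rng.normal(size=(2, n))
        noise = rng.normal(size=(n_noise, n))
        risk = beta * planted.sum(axis=0)
        t = rng.exponential(1.0 / (0.01 * np.exp(risk)))
        c = rng.exponential(np.quantile(t, 0.85), size=n)
        genes = ["p1", "p2"] + [f"n{i}" for i in range(n_noise)]
        values = pd.DataFrame(np.vstack([planted, noise]), index=genes,
                              columns=[f"s{j}" for j in range(n)])
        clinical = pd.DataFrame({
            "sample_id": values.columns,
            "time": np.minimum(t, c),
            "event": (t <= c).astype(int),
        })
        return values, clinical

    def test_planted_genes_recovered(self):
        values, clinical = self._cohort()
        support = lasso_select(values, clinical, seed=0)
        assert {"p1", "p2"}.issubset(support)
        assert len(support) < values.shape[0]

    def test_full_shrinkage_returns_pool_with_warning(self):
        values, clinical = self._cohort(n=120, n_noise=5)
        with pytest.warns(UserWarning, match="empty"):
            support = lasso_select(values, clinical, seed=0,
                                   alphas=[1e4])
        assert support == list(values.index)

    def test_vanishing_penalty_matches_unpenalised_cox(self):
        values, clinical = self._cohort(n=200, n_noise=1)
        frame = clinical.set_index("sample_id")
        z = values.T
        z = (z - z.mean()) / z.std()
        data = pd.concat([frame[["time", "event"]], z], axis=1)
        full = cox_fit(data, list(values.index))
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.util import Surv

        net = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[1e-8])
        net.fit(z.to_numpy(),
                Surv.from_arrays(event=frame["event"].astype(bool),
                                 time=frame["time"]))
        np.testing.assert_allclose(net.coef_[:, 0],
                                   full.summary["coef"].to_numpy(),
                                   atol=1e-3)
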