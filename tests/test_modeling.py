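"""Potency models: LASSO/RF contracts, grouped LOOCV, data-usage grid."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import lasso_path

import morphoclone as mc
from morphoclone.modeling import build_dataset, make_model
from morphoclone.profiling import CohortDataset, MorphologicalProfile


def _toy_dataset(n=12, p=3, seed=0, names=None):
    """Profiles whose first parameter IS the potency (plus tiny noise)."""
    rng = np.random.default_rng(seed)
    names = names or [f"param{i}" for i in range(p)]
    profiles, labels = [], {}
    for i in range(n):
        pot = 7 + i % 7
        vals = rng.normal(0, 1, p)
        vals[0] = pot
        cid = f"c{i:02d}"
        profiles.append(MorphologicalProfile(
            clone_id=cid, names=list(names), values=vals,
            window_end_h=6, fov_count=1, fov_ids=(0,)))
        labels[cid] = mc.CloneLabel(cid, pot)
    return CohortDataset(profiles=profiles, labels=labels)


class _FunctionModel:
    """Test double: predicts a fixed function of X, ignores training."""

    def __init__(self, fn):
        self.fn = fn

    def get_params(self, deep=True):
        return {"fn": self.fn}

    def fit(self, X, y, groups=None):
        return self

    def predict(self, X):
        X = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X)
        return self.fn(X)


class TestLasso:
    def test_ols_equivalence_at_zero_penalty(self):
        """Near-zero penalty with n > p matches the normal-equation OLS fit."""
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(0, 1, (40, 3)), columns=list("abc"))
        beta = np.array([2.0, -1.0, 0.5])
        y = X.to_numpy() @ beta + 5.0
        est = mc.LassoPotencyModel(alphas=[1e-10]).fit(X, y)
        # oracle: closed-form OLS on the z-scored design
        Z = (X - X.mean()) / X.std(ddof=0)
        A = np.column_stack([np.ones(40), Z])
        coef = np.linalg.solve(A.T @ A, A.T @ y)
        np.testing.assert_allclose(est.coef_, coef[1:], rtol=1e-3)
        np.testing.assert_allclose(est.intercept_, coef[0], rtol=1e-3)

    def test_huge_penalty_predicts_mean(self):
        ds = _toy_dataset()
        X, y, g = ds.to_matrices()
        est = mc.LassoPotencyModel(alphas=[1e6]).fit(X, y, groups=g)
        assert np.count_nonzero(est.coef_) == 0
        np.testing.assert_allclose(est.predict(X), np.full(len(y), y.mean()))

    def test_support_recovery_on_noiseless_cohort(self):
        """With exactly two coupled parameters and no clone noise, LASSO
        places all its weight on the true support."""
        coupling = {("Length", "SD", 6): -0.7, ("Correlation", "SD", 6): 0.007}
        spec = mc.SyntheticCohortSpec(
            n_clones=15, seed=9, noise_sd=0.0, coupling=coupling,
            cells_per_well_range=(300, 600), n_fovs=8, time_points=(6, 12))
        clones = mc.generate_cohort(spec)
        ds = build_dataset(mc.cohort_cells(clones), mc.cohort_labels(clones), 12)
        fit = mc.fit_lasso(ds)
        true_support = {"Length_SD (6 h)", "Correlation_SD (6 h)"}
        w = fit.weights.abs()
        assert w[w.index.isin(true_support)].sum() / w.sum() > 0.95
        cv = mc.loocv(ds, "lasso")
        assert cv.rmse < 0.1  # noiseless limit: RMSE -> 0

    def test_nonzero_count_bounded_by_samples(self, small_cells, small_labels):
        ds = build_dataset(small_cells, small_labels, 90)
        fit = mc.fit_lasso(ds)
        assert len(fit.selected()) <= len(ds.profiles)

    def test_path_monotone_support(self):
        """Nonzero-coefficient count is non-increasing in the penalty."""
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (30, 10))
        y = X[:, 0] * 3 + X[:, 1] - X[:, 2] * 0.5 + rng.normal(0, 0.1, 30)
        alphas, coefs, _ = lasso_path(X, y, alphas=np.logspace(-3, 1, 30))
        order = np.argsort(-alphas)  # strongest penalty first
        counts = (np.abs(coefs) > 1e-12).sum(axis=0)[order]
        assert (np.diff(counts) >= 0).all()

    def test_degenerate_target_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(ValueError, match="degenerate"):
            mc.LassoPotencyModel().fit(X, np.full(5, 9.0))


class TestForest:
    def test_no_signal_bound(self):
        """On a pure-noise target RF cannot beat predicting the mean."""
        rng = np.random.default_rng(5)
        n = 24
        profiles, labels = [], {}
        for i in range(n):
            cid = f"c{i:02d}"
            profiles.append(MorphologicalProfile(
                clone_id=cid, names=["a", "b"], values=rng.normal(0, 1, 2),
                window_end_h=6, fov_count=1, fov_ids=(0,)))
            labels[cid] = mc.CloneLabel(cid, int(rng.integers(7, 14)))
        ds = CohortDataset(profiles=profiles, labels=labels)
        cv = mc.loocv(ds, "rf", seed=0)
        _, y, _ = ds.to_matrices()
        # LOO mean predictor baseline
        base = np.sqrt(np.mean([(y[i] - np.delete(y, i).mean()) ** 2
                                for i in range(n)]))
        assert cv.rmse >= base - 0.5  # Monte-Carlo tolerance

    def test_dominant_predictor_top_importance(self):
        ds = _toy_dataset(n=20, p=5, seed=1)
        fit = mc.fit_rf(ds, seed=0)
        assert fit.weights.idxmax() == "param0"

    def test_seed_reproducible(self):
        ds = _toy_dataset(n=15, p=4, seed=2)
        X, y, g = ds.to_matrices()
        p1 = mc.ForestPotencyModel(random_state=3).fit(X, y).predict(X)
        p2 = mc.ForestPotencyModel(random_state=3).fit(X, y).predict(X)
        np.testing.assert_array_equal(p1, p2)


class TestLoocv:
    def test_oracle_predictor_zero_rmse(self):
        ds = _toy_dataset()
        cv = mc.loocv(ds, _FunctionModel(lambda X: X[:, 0]))
        assert cv.rmse == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_rmse_one(self):
        ds = _toy_dataset()
        cv = mc.loocv(ds, _FunctionModel(lambda X: X[:, 0] + 1.0))
        assert cv.rmse == pytest.approx(1.0)

    def test_fold_count_equals_clone_count(self, small_cells, small_labels):
        ds = build_dataset(small_cells, small_labels, 6)
        cv = mc.loocv(ds, _FunctionModel(lambda X: np.zeros(len(X))))
        assert cv.n_folds == 15
        assert len(cv.predictions) == 15

    def test_grouped_bootstrap_replicates_leave_together(self, small_cells,
                                                         small_labels):
        """Each fold predicts all B replicates of exactly one clone, and the
        model never trains on any replicate of that clone."""
        seen = []

        class SpyModel(_FunctionModel):
            def __init__(self):
                super().__init__(lambda X: np.zeros(len(X)))

            def get_params(self, deep=True):
                return {}

            def fit(self, X, y, groups=None):
                seen.append(set(np.asarray(groups).tolist()))
                return self

        ds = build_dataset(small_cells, small_labels, 6, B=5, k=4, seed=1)
        cv = mc.loocv(ds, SpyModel())
        clones = set(ds.clone_ids())
        assert cv.n_folds == 15
        assert len(cv.predictions) == 15 * 5
        for train_groups in seen:
            held = clones - train_groups
            assert len(held) == 1  # exactly one clone fully held out

    def test_too_few_clones(self):
        ds = _toy_dataset(n=2)
        with pytest.raises(ValueError, match="3 clones"):
            mc.loocv(ds, "lasso")


class TestDataUsageGrid:
    def test_shape_contract_and_finiteness(self, small_cells, small_labels):
        g = mc.data_usage_grid(small_cells, small_labels, [6, 30], [4, 16],
                               "lasso", seed=5)
        assert len(g.table) == 4
        assert g.table["ok"].all()
        assert np.isfinite(g.table["rmse"]).all()
        assert g.rmse_matrix().shape == (2, 2)

    def test_more_data_no_worse(self, small_cells, small_labels):
        g = mc.data_usage_grid(small_cells, small_labels, [6, 90], [1, 16],
                               "lasso", seed=5)
        m = g.rmse_matrix()
        assert m.loc[16, 90] <= m.loc[1, 6] + 0.1

    def test_full_condition_beats_threshold(self, small_cells, small_labels):
        g = mc.data_usage_grid(small_cells, small_labels, [90], [16],
                               "lasso", seed=5)
        assert bool(g.pass_matrix().loc[16, 90])

    def test_failures_recorded_not_raised(self, small_cells, small_labels):
        # FOV count beyond availability: recorded as a failed cell
        g = mc.data_usage_grid(small_cells, small_labels, [6], [999],
                               "lasso", seed=0)
        assert not g.table["ok"].iloc[0]
        assert g.table["error"].iloc[0] != ""


class TestStructureCorrelation:
    def _fit(self, weights, name):
        return mc.ModelFit(kind="lasso",
                           weights=pd.Series(weights),
                           condition={"name": name})

    def test_self_correlation_one(self):
        f = self._fit({"a": 1.0, "b": -2.0, "c": 0.0}, "f")
        C = mc.model_structure_correlation([f, f])
        assert C.iloc[0, 1] == pytest.approx(1.0)

    def test_negated_fit_minus_one(self):
        f = self._fit({"a": 1.0, "b": -2.0, "c": 0.5}, "f")
        g = self._fit({"a": -1.0, "b": 2.0, "c": -0.5}, "g")
        C = mc.model_structure_correlation([f, g])
        assert C.iloc[0, 1] == pytest.approx(-1.0)

    def test_union_alignment_absent_weights_zero(self):
        f = self._fit({"a": 1.0, "b": 2.0}, "f")
        g = self._fit({"b": 2.0, "c": 1.0}, "g")
        C = mc.model_structure_correlation([f, g])
        assert C.shape == (2, 2)
        assert np.isfinite(C.iloc[0, 1])

    def test_zero_variance_flagged_nan(self):
        f = self._fit({"a": 1.0, "b": 2.0}, "f")
        z = self._fit({"a": 0.0, "b": 0.0}, "z")
        C = mc.model_structure_correlation([f, z])
        assert np.isnan(C.iloc[0, 1])
        assert C.iloc[0, 0] == pytest.approx(1.0)

    def test_bootstrap_redraws_share_structure(self, small_cells, small_labels):
        """Two LASSO fits on independent bootstrap re-draws of the same
        cohort share their weight structure (correlation > 0.7)."""
        f1 = mc.fit_lasso(build_dataset(small_cells, small_labels, 90,
                                        B=10, k=16, seed=1))
        f2 = mc.fit_lasso(build_dataset(small_cells, small_labels, 90,
                                        B=10, k=16, seed=2))
        C = mc.model_structure_correlation([f1, f2])
        assert C.iloc[0, 1] > 0.7


class TestMakeModel:
    def test_kinds(self):
        assert isinstance(make_model("lasso"), mc.LassoPotencyModel)
        assert isinstance(make_model("rf"), mc.ForestPotencyModel)
        with pytest.raises(ValueError):
            make_model("svm")
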