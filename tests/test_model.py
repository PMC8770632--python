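"""Ensemble modeling: penalized fits, repeated holdout, frequency/exclusion."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import hadamard
from sklearn.base import clone
from sklearn.linear_model import LinearRegression

import kerndep as kd
from kerndep.errors import DegenerateFitError, ParameterError, ValidationError
from kerndep.model import FittedModel, ModelSpec


def hadamard_design(n=16):
    """Centered, unit-variance, mutually orthogonal +-1 design (no constant col)."""
    h = hadamard(n).astype(float)
    return h[:, 1:]


def lasso_objective(z, y, beta, b0, lam):
    resid = y - b0 - z @ beta
    return float(resid @ resid + lam * np.abs(beta).sum())


def enet_objective(z, y, beta, b0, lam):
    resid = y - b0 - z @ beta
    return float(resid @ resid + lam * (beta @ beta) + lam * np.abs(beta).sum())


def proximal_oracle(z, y, lam, ridge=False, iters=20000):
    """Projected/proximal-gradient minimizer of the penalized least-squares
    objective (intercept profiled out; z must be column-centered)."""
    yc = y - y.mean()
    n, p = z.shape
    lip = 2 * np.linalg.eigvalsh(z.T @ z).max() + (2 * lam if ridge else 0.0)
    t = 1.0 / lip
    beta = np.zeros(p)
    for _ in range(iters):
        grad = -2 * z.T @ (yc - z @ beta)
        if ridge:
            grad = grad + 2 * lam * beta
        b = beta - t * grad
        beta = np.sign(b) * np.maximum(np.abs(b) - t * lam, 0.0)
    return beta, float(y.mean())


class TestFitOne:
    def test_zero_penalty_matches_ols(self, rng):
        X = rng.standard_normal((30, 3))
        y = X @ [1.0, -2.0, 0.5] + rng.standard_normal(30)
        split = (np.arange(24), np.arange(24, 30))
        model = kd.fit_one(X, y, ModelSpec(lambda_=0.0), split)
        ref = LinearRegression().fit(X[:24], y[:24])
        np.testing.assert_allclose(model.coef.to_numpy(), ref.coef_, atol=1e-6)
        np.testing.assert_allclose(model.intercept, ref.intercept_, atol=1e-6)

    def test_soft_threshold_on_orthonormal_design(self, rng):
        # closed form for RSS + lam*|b| with X'X = nI: b_j = S(ols_j, lam/(2n))
        X = hadamard_design(16)
        y = rng.standard_normal(16)
        lam = 8.0
        model = kd.fit_one(X, y, ModelSpec(lambda_=lam), (np.arange(16), np.array([], int)))
        ols = X.T @ y / 16
        expected = np.sign(ols) * np.maximum(np.abs(ols) - lam / 32, 0.0)
        np.testing.assert_allclose(model.coef.to_numpy(), expected, atol=1e-6)

    def test_huge_penalty_zeroes_everything(self, rng):
        X = hadamard_design(16)
        y = rng.permutation(rng.standard_normal(16))
        model = kd.fit_one(X, y, ModelSpec(lambda_=1e4), (np.arange(16), np.array([], int)))
        assert (model.coef == 0).all()

    @pytest.mark.parametrize("algorithm", ["lasso", "elastic_net"])
    def test_objective_matches_proximal_gradient_oracle(self, algorithm, rng):
        z = rng.standard_normal((20, 10))
        z = z - z.mean(axis=0)
        z = z / z.std(axis=0)
        y = z[:, 0] - 0.5 * z[:, 3] + rng.standard_normal(20)
        lam = 4.0
        model = kd.fit_one(z, y, ModelSpec(algorithm=algorithm, lambda_=lam),
                           (np.arange(20), np.array([], int)))
        beta_impl = model.coef.to_numpy() * model.train_scale
        b0_impl = model.intercept + float(model.coef.to_numpy() @ model.train_mean)
        zs = (z - model.train_mean) / model.train_scale
        ridge = algorithm == "elastic_net"
        beta_star, b0_star = proximal_oracle(zs, y, lam, ridge=ridge)
        objective = enet_objective if ridge else lasso_objective
        obj_impl = objective(zs, y, beta_impl, b0_impl, lam)
        obj_star = objective(zs, y, beta_star, b0_star, lam)
        assert obj_impl == pytest.approx(obj_star, abs=1e-5)

    def test_constant_response_rejected(self, rng):
        X = rng.standard_normal((20, 2))
        with pytest.raises(DegenerateFitError):
            kd.fit_one(X, np.ones(20), ModelSpec(), (np.arange(15), np.arange(15, 20)))

    def test_tiny_training_split_rejected(self, rng):
        X = rng.standard_normal((12, 2))
        y = rng.standard_normal(12)
        with pytest.raises(ValidationError):
            kd.fit_one(X, y, ModelSpec(), (np.arange(8), np.arange(8, 12)))


class TestRunEnsemble:
    def test_perfect_signal_recovered(self, rng):
        X = rng.standard_normal((50, 3))
        y = 2.0 * X[:, 0]
        result = kd.run_ensemble(X, y, n_models=30, seed=5)
        assert result.pearson_r >= 0.999

    def test_same_seed_reproduces_result_exactly(self, rng):
        X = rng.standard_normal((40, 4))
        y = X[:, 1] + 0.3 * rng.standard_normal(40)
        a = kd.run_ensemble(X, y, spec=ModelSpec(lambda_=1.0), n_models=20, seed=9)
        b = kd.run_ensemble(X, y, spec=ModelSpec(lambda_=1.0), n_models=20, seed=9)
        pd.testing.assert_series_equal(a.predictions, b.predictions)
        assert a.pearson_r == b.pearson_r
        for ma, mb in zip(a.models, b.models):
            np.testing.assert_array_equal(ma.train_index, mb.train_index)
            pd.testing.assert_series_equal(ma.coef, mb.coef)

    def test_split_bookkeeping_and_coverage(self, rng):
        n = 50
        X = rng.standard_normal((n, 3))
        y = X[:, 0] + rng.standard_normal(n)
        result = kd.run_ensemble(X, y, spec=ModelSpec(lambda_=1.0), n_models=100, seed=2)
        for m in result.models:
            assert m.train_index.size == round(0.8 * n)
            assert np.intersect1d(m.train_index, m.test_index).size == 0
        assert result.coverage.min() >= 5  # expected coverage = 20 of 100
        assert result.coverage.sum() == 100 * (n - round(0.8 * n))

    def test_uncovered_lines_warned_and_excluded(self, rng):
        X = rng.standard_normal((30, 2))
        y = X[:, 0] + 0.1 * rng.standard_normal(30)
        with pytest.warns(UserWarning, match="never appeared"):
            result = kd.run_ensemble(X, y, spec=ModelSpec(lambda_=1.0), n_models=1, seed=0)
        assert len(result.predictions) == 6  # the single 20% test set
        assert len(result.uncovered) == 24

    def test_small_cohort_rejected(self, rng):
        X = rng.standard_normal((20, 2))
        with pytest.raises(ValidationError):
            kd.run_ensemble(X, rng.standard_normal(20))

    def test_alternate_algorithms_share_split_schedule(self, rng):
        X = rng.standard_normal((40, 4))
        y = X[:, 0] + 0.3 * rng.standard_normal(40)
        lasso = kd.run_ensemble(X, y, spec=ModelSpec(lambda_=1.0), n_models=5, seed=3)
        forest = kd.run_ensemble(X, y, spec=ModelSpec(algorithm="random_forest", n_trees=10),
                                 n_models=5, seed=3)
        enet = kd.run_ensemble(X, y, spec=ModelSpec(algorithm="elastic_net", lambda_=1.0),
                               n_models=5, seed=3)
        for m_l, m_f, m_e in zip(lasso.models, forest.models, enet.models):
            np.testing.assert_array_equal(m_l.train_index, m_f.train_index)
            np.testing.assert_array_equal(m_l.train_index, m_e.train_index)

    def test_sklearn_estimator_api(self, rng):
        X = pd.DataFrame(rng.standard_normal((40, 3)), columns=["A", "B", "C"])
        y = X["A"].to_numpy() * 1.5
        est = kd.DependencyEnsembleRegressor(lambda_=0.5, n_models=10, random_state=1)
        cloned = clone(est)
        assert cloned.get_params()["n_models"] == 10
        est.fit(X, y)
        preds = est.predict(X)
        assert preds.shape == (40,)
        assert np.corrcoef(preds, y)[0, 1] > 0.99


def make_model(coefs: dict) -> FittedModel:
    s = pd.Series(coefs, dtype=float)
    return FittedModel(
        intercept=0.0, coef=s, predictor_names=list(s.index),
        train_index=np.arange(10), test_index=np.arange(10, 12),
        spec=ModelSpec(lambda_=1.0), split_seed=0,
    )


class TestFrequencyAndExtraction:
    def test_counts_signs_and_omits_zero_genes(self):
        table = kd.predictor_frequency([make_model({"A": -0.3, "B": 0.0, "C": 0.1})])
        assert table.set_index("gene").loc["A"].tolist()[:2] == [1, 0]
        assert table.set_index("gene").loc["C"].tolist()[:2] == [0, 1]
        assert "B" not in set(table["gene"])

    def test_accumulates_across_models(self):
        models = [make_model({"A": -0.3}), make_model({"A": -0.1})]
        table = kd.predictor_frequency(models).set_index("gene")
        assert table.loc["A", "neg_count"] == 2

    def test_union_semantics_for_disjoint_predictor_sets(self):
        models = [make_model({"A": -0.3}), make_model({"C": 0.2})]
        table = kd.predictor_frequency(models)
        assert set(table["gene"]) == {"A", "C"}
        assert (table["total"] == 1).all()

    def test_extract_nonzero_union(self):
        models = [make_model({"A": -0.3, "B": 0.0}), make_model({"C": 0.2})]
        assert kd.extract_nonzero_predictors(models) == ["A", "C"]

    def test_extract_all_zero_warns(self):
        with pytest.warns(UserWarning, match="no non-zero"):
            assert kd.extract_nonzero_predictors([make_model({"A": 0.0})]) == []


class TestAbsoluteError:
    def test_perfect_predictions_zero_error_and_sorted(self, rng):
        X = rng.standard_normal((50, 2))
        y = X[:, 0]
        result = kd.run_ensemble(X, y, spec=ModelSpec(lambda_=0.0), n_models=30, seed=1)
        table = kd.evaluate_absolute_error(result)
        assert (table["abs_error"] < 1e-8).all()
        assert (np.diff(table["observed"].to_numpy()) >= 0).all()


class TestExclusion:
    def test_empty_exclusion_is_identity(self, rng):
        genes = [f"G{i}" for i in range(8)]
        expr = pd.DataFrame(rng.standard_normal((40, 8)), columns=genes)
        y = expr["G0"] * 1.2 + 0.2 * rng.standard_normal(40)
        full = kd.run_ensemble(expr[genes], y, spec=ModelSpec(lambda_=1.0), n_models=10, seed=4)
        excl = kd.exclusion_run(genes, [], expr, y, spec=ModelSpec(lambda_=1.0),
                                n_models=10, seed=4)
        assert excl.pearson_r == pytest.approx(full.pearson_r, abs=1e-12)

    def test_stray_exclusion_genes_warned(self, rng):
        genes = [f"G{i}" for i in range(8)]
        expr = pd.DataFrame(rng.standard_normal((40, 8)), columns=genes)
        y = expr["G0"] * 1.2
        with pytest.warns(UserWarning, match="not in the network"):
            kd.exclusion_run(genes, ["ZZ"], expr, y, spec=ModelSpec(lambda_=1.0),
                             n_models=5, seed=4)


class TestPlanCounts:
    def test_plan_arithmetic(self):
        assert kd.count_scheduled_models(60) == 12000
        assert kd.count_waterfall_models() == 400
        with pytest.raises(ParameterError):
            kd.count_scheduled_models(0)
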