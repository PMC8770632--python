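"""Penalized-regression ensembles over repeated 80/20 holdout splits.

For one predictor set, ``n_models`` models (lasso by default; elastic net
and random-forest regression as alternatives) are each fit on a random 80%
of the cell lines; test-set predictions are averaged per cell line across
the models in which that line was held out, and the ensemble is scored by
the Pearson correlation between averaged predictions and the observed
dependency. Frequency analysis counts how often each predictor carries a
negative or positive coefficient across models; the exclusion analysis
refits the ensemble on the network superset minus a gene list to test
whether those genes carry non-substitutable signal.

Lasso minimizes RSS + lambda * sum|b_j|; the elastic net adds the ridge
term with the same lambda on both penalties (RSS + lambda * sum b_j^2 +
lambda * sum|b_j|). Fits are delegated to scikit-learn with the penalty
re-parameterized accordingly (alpha = lambda / 2n for the lasso;
l1_ratio = 1/3, alpha = 3*lambda / 2n for the elastic net). The penalty
weight is chosen by 10-fold cross-validation inside each training split
unless a fixed lambda is given. Predictors are standardized on training
statistics; coefficients are reported on the original predictor scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet, ElasticNetCV, Lasso, LassoCV, LinearRegression

from .errors import (
    DegenerateFitError,
    EvaluationError,
    ParameterError,
    SelectionError,
    ValidationError,
)
from .select import drop_missing

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "FittedModel",
    "EnsembleResult",
    "DependencyEnsembleRegressor",
    "fit_one",
    "run_ensemble",
    "evaluate_absolute_error",
    "predictor_frequency",
    "exclusion_run",
    "extract_nonzero_predictors",
    "count_scheduled_models",
    "count_waterfall_models",
]

# elastic net with equal lambda on |b| and b^2 expressed in sklearn's
# (alpha, l1_ratio) parameterization (which halves the L2 term)
ENET_L1_RATIO = 1.0 / 3.0
MIN_TRAIN_ROWS = 10


@dataclass(frozen=True)
class ModelSpec:
    """Algorithm and penalty configuration for one model family.

    ``lambda_`` is either ``"cv"`` (10-fold CV minimum inside each training
    split) or a fixed penalty in the RSS + lambda*penalty parameterization.
    """

    algorithm: str = "lasso"
    lambda_: float | str = "cv"
    cv_folds: int = 10
    n_trees: int = 500
    max_features: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.algorithm not in ("lasso", "elastic_net", "random_forest"):
            raise ParameterError(f"unknown algorithm: {self.algorithm!r}")
        if isinstance(self.lambda_, str):
            if self.lambda_ != "cv":
                raise ParameterError("lambda_ must be 'cv' or a number >= 0")
        elif self.lambda_ < 0:
            raise ParameterError("lambda_ must be >= 0")
        if self.n_trees < 1:
            raise ParameterError("n_trees must be >= 1")


@dataclass
class FittedModel:
    """One fitted model plus its split bookkeeping."""

    intercept: float
    coef: pd.Series | None  # None for random forest
    predictor_names: list[str]
    train_index: np.ndarray
    test_index: np.ndarray
    spec: ModelSpec
    split_seed: int
    lambda_used: float | None = None
    estimator: object | None = None
    train_mean: np.ndarray | None = None
    train_scale: np.ndarray | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.coef is not None:
            return self.intercept + X @ self.coef.to_numpy()
        z = (X - self.train_mean) / self.train_scale
        return self.estimator.predict(z)


@dataclass
class EnsembleResult:
    """Averaged test predictions and the evaluation correlation."""

    predictions: pd.Series  # averaged test prediction per covered cell line
    observed: pd.Series
    abs_error: pd.Series
    pearson_r: float
    pearson_p: float
    n_models: int
    coverage: pd.Series  # test-set appearance count per cell line
    uncovered: list[str]
    models: list[FittedModel] = field(repr=False, default_factory=list)
    spec: ModelSpec | None = None
    seed: int | None = None
    provenance: dict = field(default_factory=dict)


def _as_matrix(X) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns], [str(i) for i in X.index]
    arr = np.asarray(X, dtype=float)
    return arr, [f"x{j}" for j in range(arr.shape[1])], [str(i) for i in range(arr.shape[0])]


def _standardize(train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = train.mean(axis=0)
    scale = train.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)  # constant columns stay zero after centering
    return mean, scale


def _linear_estimator(spec: ModelSpec, n_train: int, rng_seed: int):
    """Map the spec's penalty parameterization onto a sklearn estimator."""
    if spec.lambda_ == "cv":
        if spec.algorithm == "lasso":
            return LassoCV(cv=spec.cv_folds, random_state=rng_seed, alphas=60, max_iter=5000)
        return ElasticNetCV(
            l1_ratio=ENET_L1_RATIO, cv=spec.cv_folds, random_state=rng_seed,
            alphas=60, max_iter=5000,
        )
    lam = float(spec.lambda_)
    if lam == 0.0:
        return LinearRegression()
    if spec.algorithm == "lasso":
        return Lasso(alpha=lam / (2.0 * n_train), max_iter=50000, tol=1e-10)
    return ElasticNet(alpha=3.0 * lam / (2.0 * n_train), l1_ratio=ENET_L1_RATIO,
                      max_iter=50000, tol=1e-10)


def fit_one(
    X,
    y,
    spec: ModelSpec,
    split: tuple[Sequence[int], Sequence[int]],
    split_seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> FittedModel:
    """Fit one model on the training rows of a split.

    Predictors are standardized on training statistics; for the linear
    models the reported coefficients are transformed back to the original
    predictor scale.
    """
    Xm, names, _ = _as_matrix(X)
    if feature_names is not None:
        names = [str(n) for n in feature_names]
    yv = np.asarray(y, dtype=float)
    if Xm.shape[0] != yv.shape[0]:
        raise ValidationError("X rows and y length differ")
    train_idx = np.asarray(split[0], dtype=int)
    test_idx = np.asarray(split[1], dtype=int)
    if np.intersect1d(train_idx, test_idx).size:
        raise ValidationError("train and test indices overlap")
    if train_idx.size < MIN_TRAIN_ROWS:
        raise ValidationError(f"need >= {MIN_TRAIN_ROWS} training rows, got {train_idx.size}")
    y_train = yv[train_idx]
    if np.ptp(y_train) == 0:
        raise DegenerateFitError("response is constant on the training split")
    X_train = Xm[train_idx]
    mean, scale = _standardize(X_train)
    z_train = (X_train - mean) / scale

    if spec.algorithm == "random_forest":
        est = RandomForestRegressor(
            n_estimators=spec.n_trees,
            max_features=spec.max_features,
            random_state=split_seed % (2**31 - 1),
            n_jobs=1,
        )
        est.fit(z_train, y_train)
        return FittedModel(
            intercept=float(np.mean(y_train)), coef=None, predictor_names=names,
            train_index=train_idx, test_index=test_idx, spec=spec,
            split_seed=split_seed, estimator=est, train_mean=mean, train_scale=scale,
        )

    est = _linear_estimator(spec, train_idx.size, split_seed % (2**31 - 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter on near-null CV folds
        est.fit(z_train, y_train)
    coef_std = np.asarray(est.coef_, dtype=float)
    coef = coef_std / scale
    intercept = float(est.intercept_) - float(np.sum(coef_std * mean / scale))
    if spec.lambda_ == "cv":
        lam_used = float(est.alpha_) * 2.0 * train_idx.size
        if spec.algorithm == "elastic_net":
            lam_used /= 3.0
    else:
        lam_used = float(spec.lambda_)
    return FittedModel(
        intercept=intercept, coef=pd.Series(coef, index=names),
        predictor_names=names, train_index=train_idx, test_index=test_idx,
        spec=spec, split_seed=split_seed, lambda_used=lam_used,
        estimator=est, train_mean=mean, train_scale=scale,
    )


class DependencyEnsembleRegressor(RegressorMixin, BaseEstimator):
    """Repeated-holdout ensemble of penalized regressions (sklearn estimator).

    Parameters
    ----------
    algorithm : {"lasso", "elastic_net", "random_forest"}, default "lasso"
    lambda_ : "cv" or float, default "cv"
        Penalty weight in the RSS + lambda*penalty parameterization, or
        "cv" for a 10-fold inner cross-validation minimum per split.
    n_models : int, default 100
        Number of independent 80/20 resamples.
    train_frac : float, default 0.8
    random_state : int, default 0
        Master seed; each model's split draws from a counter-derived child
        stream, so results do not depend on execution order.
    n_trees, max_features : random-forest configuration.

    Attributes (after ``fit``)
    --------------------------
    models_ : list of FittedModel
    prediction_mean_ : pd.Series — per-line average over held-out predictions
    pearson_r_, pearson_p_ : float — correlation with the observed response
    coverage_ : pd.Series — number of models in which each line was held out
    uncovered_ : list of lines never held out (excluded from evaluation)
    """

    def __init__(
        self,
        algorithm: str = "lasso",
        lambda_: float | str = "cv",
        n_models: int = 100,
        train_frac: float = 0.8,
        random_state: int = 0,
        cv_folds: int = 10,
        n_trees: int = 500,
        max_features: float = 1.0 / 3.0,
    ):
        self.algorithm = algorithm
        self.lambda_ = lambda_
        self.n_models = n_models
        self.train_frac = train_frac
        self.random_state = random_state
        self.cv_folds = cv_folds
        self.n_trees = n_trees
        self.max_features = max_features

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            algorithm=self.algorithm, lambda_=self.lambda_, cv_folds=self.cv_folds,
            n_trees=self.n_trees, max_features=self.max_features,
        )

    def fit(self, X, y) -> "DependencyEnsembleRegressor":
        Xm, names, rows = _as_matrix(X)
        yv = np.asarray(y, dtype=float)
        n = Xm.shape[0]
        if n < 25:
            raise ValidationError(f"cohort must have >= 25 cell lines, got {n}")
        if not 0 < self.train_frac < 1:
            raise ParameterError("train_frac must be in (0, 1)")
        spec = self._spec()
        n_train = int(round(self.train_frac * n))
        n_train = min(max(n_train, 1), n - 1)
        pred_sum = np.zeros(n)
        pred_count = np.zeros(n, dtype=int)
        models: list[FittedModel] = []
        for m in range(self.n_models):
            # counter-based child stream: reproducible and order-independent
            seq = np.random.SeedSequence(entropy=self.random_state, spawn_key=(m,))
            rng = np.random.default_rng(seq)
            perm = rng.permutation(n)
            train_idx, test_idx = perm[:n_train], perm[n_train:]
            split_seed = int(seq.generate_state(1)[0] % (2**31 - 1))
            model = fit_one(Xm, yv, spec, (train_idx, test_idx), split_seed=split_seed,
                            feature_names=names)
            preds = model.predict(Xm[test_idx])
            pred_sum[test_idx] += preds
            pred_count[test_idx] += 1
            models.append(model)
        covered = pred_count > 0
        uncovered = [rows[i] for i in np.flatnonzero(~covered)]
        if uncovered:
            warnings.warn(
                f"{len(uncovered)} cell line(s) never appeared in a test set; "
                "excluded from evaluation",
                stacklevel=2,
            )
        if not covered.any():
            raise EvaluationError("no cell line was ever held out; cannot evaluate")
        avg = pred_sum[covered] / pred_count[covered]
        obs = yv[covered]
        covered_rows = [rows[i] for i in np.flatnonzero(covered)]
        if np.ptp(avg) == 0 or np.ptp(obs) == 0:
            warnings.warn("constant predictions or observations; reporting r = 0", stacklevel=2)
            r, p = 0.0, 1.0
        else:
            r, p = stats.pearsonr(avg, obs)
        self.models_ = models
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = Xm.shape[1]
        self.prediction_mean_ = pd.Series(avg, index=covered_rows, name="predicted_mean")
        self.observed_ = pd.Series(obs, index=covered_rows, name="observed")
        self.abs_error_ = (self.prediction_mean_ - self.observed_).abs().rename("abs_error")
        self.pearson_r_ = float(r)
        self.pearson_p_ = float(p)
        self.coverage_ = pd.Series(pred_count, index=rows, name="n_test_appearances")
        self.uncovered_ = uncovered
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "models_"):
            raise ValidationError("ensemble is not fitted")
        Xm, _, _ = _as_matrix(X)
        return np.mean([m.predict(Xm) for m in self.models_], axis=0)

    def result_(self) -> EnsembleResult:
        return EnsembleResult(
            predictions=self.prediction_mean_, observed=self.observed_,
            abs_error=self.abs_error_, pearson_r=self.pearson_r_,
            pearson_p=self.pearson_p_, n_models=self.n_models,
            coverage=self.coverage_, uncovered=self.uncovered_,
            models=self.models_, spec=self._spec(), seed=self.random_state,
        )


def run_ensemble(
    X,
    y,
    spec: ModelSpec | None = None,
    n_models: int = 100,
    train_frac: float = 0.8,
    seed: int = 0,
) -> EnsembleResult:
    """Functional wrapper over :class:`DependencyEnsembleRegressor`."""
    spec = spec or ModelSpec()
    est = DependencyEnsembleRegressor(
        algorithm=spec.algorithm, lambda_=spec.lambda_, n_models=n_models,
        train_frac=train_frac, random_state=seed, cv_folds=spec.cv_folds,
        n_trees=spec.n_trees, max_features=spec.max_features,
    )
    est.fit(X, y)
    return est.result_()


def evaluate_absolute_error(ensemble: EnsembleResult, y: pd.Series | None = None) -> pd.DataFrame:
    """Per-line absolute error ordered by ascending observed dependency."""
    obs = ensemble.observed if y is None else pd.Series(y).reindex(ensemble.predictions.index)
    out = pd.DataFrame(
        {
            "observed": obs,
            "predicted_mean": ensemble.predictions,
            "abs_error": (ensemble.predictions - obs).abs(),
        }
    )
    return out.sort_values("observed", kind="mergesort")


def predictor_frequency(models: Sequence[FittedModel]) -> pd.DataFrame:
    """Count negative/positive non-zero coefficients per gene across models.

    Genes never non-zero are omitted; rows are sorted by total count
    descending, then by gene symbol. Random-forest models (no coefficients)
    are skipped.
    """
    neg: dict[str, int] = {}
    pos: dict[str, int] = {}
    for model in models:
        if model.coef is None:
            continue
        for gene, c in model.coef.items():
            if c < 0:
                neg[gene] = neg.get(gene, 0) + 1
            elif c > 0:
                pos[gene] = pos.get(gene, 0) + 1
    genes = sorted(set(neg) | set(pos))
    table = pd.DataFrame(
        {
            "gene": genes,
            "neg_count": [neg.get(g, 0) for g in genes],
            "pos_count": [pos.get(g, 0) for g in genes],
        }
    )
    table["total"] = table["neg_count"] + table["pos_count"]
    table = table.sort_values(["total", "gene"], ascending=[False, True], kind="mergesort")
    return table.reset_index(drop=True)


def extract_nonzero_predictors(models: Sequence[FittedModel]) -> list[str]:
    """Union of genes with a non-zero coefficient in any model, sorted."""
    genes: set[str] = set()
    for model in models:
        if model.coef is None:
            continue
        genes.update(model.coef.index[model.coef != 0])
    if not genes:
        warnings.warn("no non-zero predictors in any model", stacklevel=2)
    return sorted(genes)


def exclusion_run(
    network_genes: Sequence[str],
    exclude: Sequence[str],
    expr: pd.DataFrame,
    y,
    spec: ModelSpec | None = None,
    n_models: int = 100,
    seed: int = 0,
) -> EnsembleResult:
    """Refit the ensemble on the network predictor superset minus ``exclude``.

    Tests whether the excluded genes carried information that the rest of
    the network cannot substitute.
    """
    exclude_set = {g for g in exclude}
    stray = exclude_set - set(network_genes)
    if stray:
        warnings.warn(
            f"{len(stray)} excluded gene(s) not in the network superset; ignored",
            stacklevel=2,
        )
    remaining = [g for g in network_genes if g not in exclude_set]
    remaining = drop_missing(expr, remaining)
    if not remaining:
        raise SelectionError("exclusion left no usable predictors")
    result = run_ensemble(expr[remaining], y, spec=spec, n_models=n_models, seed=seed)
    result.provenance.update(
        {"excluded": sorted(exclude_set), "n_remaining": len(remaining)}
    )
    return result


def count_scheduled_models(
    n_predictor_sets: int, n_resamples: int = 100, n_datasets: int = 2
) -> int:
    """Total models scheduled across the grid, resamples and datasets."""
    if min(n_predictor_sets, n_resamples, n_datasets) < 1:
        raise ParameterError("all plan dimensions must be >= 1")
    return n_predictor_sets * n_resamples * n_datasets


def count_waterfall_models(
    n_datasets: int = 2,
    predictor_types: Sequence[str] = ("rna", "mutation"),
    n_resamples: int = 100,
) -> int:
    """Models behind the per-line absolute-error (waterfall) comparison."""
    if n_datasets < 1 or n_resamples < 1 or len(predictor_types) < 1:
        raise ParameterError("all plan dimensions must be >= 1")
    return n_datasets * len(predictor_types) * n_resamples
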