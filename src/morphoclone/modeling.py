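"""Potency regression models and the data-usage sweep.

Serial-passage potency (an integer number of passages) is regressed on
morphological profiles with two model families:

* :class:`LassoPotencyModel` — L1-penalized linear regression. Profiles
  are z-scored on the training data; the penalty strength is chosen by an
  inner leave-one-clone-out cross-validation on the training fold.
  Selected parameters are those with nonzero coefficients.
* :class:`ForestPotencyModel` — a random-forest regressor (500 trees,
  one third of the parameters per split), with impurity-decrease
  importances.

Evaluation is leave-one-clone-out cross-validation (LOOCV) scored by
RMSE of the held-out predictions. When a dataset contains bootstrap
replicates, *all* replicates of the held-out clone leave together
(grouped LOOCV), so no replicate of a test clone can leak into its
training fold. Standardization statistics are always fitted on the
training fold only.

``data_usage_grid`` sweeps time-window end x FOV count, recording the
LOOCV RMSE for each cell of the grid; RMSE below 1.0 passage is the
conventional threshold for a well-performing model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone as sk_clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LassoCV, LassoLars
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .profiling import (CloneLabel, CohortDataset, MorphologicalProfile,
                        bootstrap_profiles, build_profile, subsample_fovs)

#: RMSE (passages) below which a model is conventionally called "good"
GOOD_RMSE_THRESHOLD = 1.0


def _grouped_loo_splits(groups: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    uniq = sorted(set(groups.tolist()))
    idx = np.arange(len(groups))
    return [(idx[groups != g], idx[groups == g]) for g in uniq]


class LassoPotencyModel(BaseEstimator, RegressorMixin):
    """L1-penalized linear potency regressor with inner-CV penalty selection.

    Parameters
    ----------
    n_alphas : int
        Length of the automatic penalty path explored by the inner CV.
    eps : float
        Ratio of the smallest to the largest penalty on the path.
    max_iter : int
        Coordinate-descent iteration cap.

    Attributes (after fit)
    ----------------------
    coef_ : ndarray, (n_parameters,)
        Coefficients on the original (unstandardized) parameter scale is
        *not* what is stored — coefficients refer to z-scored parameters,
        matching how the model is applied.
    alpha_ : float
        Penalty chosen by the inner leave-one-clone-out CV.
    feature_names_in_ : ndarray of str
        Profile parameter names, in order.
    """

    def __init__(self, n_alphas: int = 100, eps: float = 1e-3,
                 max_iter: int = 20000, alphas: Sequence[float] | None = None):
        self.n_alphas = n_alphas
        self.eps = eps
        self.max_iter = max_iter
        self.alphas = alphas  # explicit penalty path overrides the auto grid

    def fit(self, X, y, groups: Sequence | None = None):
        X, names = _as_matrix(X)
        y = np.asarray(y, dtype=np.float64)
        if X.shape[0] < 3:
            raise ValueError(f"need >= 3 training samples, got {X.shape[0]}")
        if np.ptp(y) == 0:
            raise ValueError("degenerate target: all potencies identical")
        groups = np.asarray(groups if groups is not None
                            else np.arange(X.shape[0]))
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        splits = _grouped_loo_splits(groups)
        path = list(self.alphas) if self.alphas is not None else self.n_alphas
        cv_fit = LassoCV(alphas=path, eps=self.eps,
                         max_iter=self.max_iter, cv=splits).fit(Xs, y)
        # final fit via LARS at the selected penalty: the exact piecewise-
        # linear path solution, guaranteeing <= n_samples active parameters
        self.alpha_ = float(cv_fit.alpha_)
        self.lasso_ = LassoLars(alpha=self.alpha_).fit(Xs, y)
        self.coef_ = self.lasso_.coef_
        self.intercept_ = float(self.lasso_.intercept_)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "lasso_")
        X, _ = _as_matrix(X)
        return self.lasso_.predict(self.scaler_.transform(X))

    def selected_parameters(self) -> list[str]:
        """Parameter names with nonzero LASSO coefficients."""
        check_is_fitted(self, "lasso_")
        return [str(n) for n, c in zip(self.feature_names_in_, self.coef_)
                if c != 0.0]


class ForestPotencyModel(BaseEstimator, RegressorMixin):
    """Random-forest potency regressor with impurity importances."""

    def __init__(self, n_estimators: int = 500,
                 max_features: float | str = 1.0 / 3.0,
                 random_state: int = 0):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X, y, groups: Sequence | None = None):
        X, names = _as_matrix(X)
        y = np.asarray(y, dtype=np.float64)
        if X.shape[0] < 3:
            raise ValueError(f"need >= 3 training samples, got {X.shape[0]}")
        self.forest_ = RandomForestRegressor(
            n_estimators=self.n_estimators, max_features=self.max_features,
            random_state=self.random_state).fit(X, y)
        self.feature_importances_ = self.forest_.feature_importances_
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "forest_")
        X, _ = _as_matrix(X)
        return self.forest_.predict(X)


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=np.float64), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=np.float64)
    return X, [f"x{i}" for i in range(X.shape[1])]


@dataclass
class ModelFit:
    """A fitted model plus its named weights and training condition."""

    kind: str                       # "lasso" | "rf"
    weights: pd.Series              # lasso coefficients or rf importances
    condition: dict
    alpha: float | None = None
    estimator: BaseEstimator | None = None

    def selected(self) -> list[str]:
        return [str(n) for n, v in self.weights.items() if v != 0.0]


@dataclass
class CvResult:
    """Grouped-LOOCV held-out predictions and their RMSE."""

    predictions: pd.DataFrame       # clone_id, replicate_id, y_true, y_pred
    rmse: float
    condition: dict = field(default_factory=dict)

    @property
    def n_folds(self) -> int:
        return self.predictions["clone_id"].nunique()


def make_model(model_spec, seed: int = 0) -> BaseEstimator:
    """Resolve a model spec ("lasso" | "rf" | estimator) to an estimator."""
    if isinstance(model_spec, str):
        if model_spec == "lasso":
            return LassoPotencyModel()
        if model_spec == "rf":
            return ForestPotencyModel(random_state=seed)
        raise ValueError(f"unknown model kind {model_spec!r}")
    return sk_clone(model_spec)


def fit_lasso(dataset: CohortDataset,
              lambda_strategy: str = "inner-loocv") -> ModelFit:
    """Fit the LASSO potency model on a whole dataset."""
    if lambda_strategy != "inner-loocv":
        raise ValueError(f"unknown lambda_strategy {lambda_strategy!r}")
    X, y, groups = dataset.to_matrices()
    est = LassoPotencyModel().fit(X, y, groups=groups)
    return ModelFit(kind="lasso",
                    weights=pd.Series(est.coef_, index=dataset.parameter_names),
                    condition=dict(dataset.provenance),
                    alpha=est.alpha_, estimator=est)


def fit_rf(dataset: CohortDataset, seed: int = 0, **hyper) -> ModelFit:
    """Fit the random-forest potency model on a whole dataset."""
    X, y, groups = dataset.to_matrices()
    est = ForestPotencyModel(random_state=seed, **hyper).fit(X, y, groups=groups)
    return ModelFit(kind="rf",
                    weights=pd.Series(est.feature_importances_,
                                      index=dataset.parameter_names),
                    condition=dict(dataset.provenance), estimator=est)


def loocv(dataset: CohortDataset, model_spec="lasso",
          seed: int = 0) -> CvResult:
    """Grouped leave-one-clone-out cross-validation scored by RMSE.

    One fold per clone; with bootstrap replicates, every replicate of the
    held-out clone is predicted by a model that never saw any of them.
    """
    X, y, groups = dataset.to_matrices()
    clones = sorted(set(groups.tolist()))
    if len(clones) < 3:
        raise ValueError(f"need >= 3 clones for LOOCV, got {len(clones)}")
    rows = []
    for held in clones:
        test = groups == held
        train = ~test
        if len(set(groups[train].tolist())) < 2:
            raise ValueError(f"fold holding out {held} leaves < 2 training clones")
        model = make_model(model_spec, seed=seed)
        model.fit(X.iloc[train] if isinstance(X, pd.DataFrame) else X[train],
                  y[train], groups=groups[train])
        preds = model.predict(X.iloc[test] if isinstance(X, pd.DataFrame)
                              else X[test])
        reps = [dataset.profiles[i].replicate_id
                for i in np.nonzero(test)[0]]
        for rep, yt, yp in zip(reps, y[test], preds):
            rows.append({"clone_id": held, "replicate_id": rep,
                         "y_true": float(yt), "y_pred": float(yp)})
    pred_df = pd.DataFrame(rows)
    rmse = float(np.sqrt(np.mean((pred_df["y_pred"] - pred_df["y_true"]) ** 2)))
    return CvResult(predictions=pred_df, rmse=rmse,
                    condition=dict(dataset.provenance))


@dataclass
class DataUsageGrid:
    """LOOCV RMSE over the time-window x FOV-count sweep."""

    table: pd.DataFrame             # window_end_h, fov_count, rmse, ok, error
    cv_results: dict[tuple[int, int], CvResult]
    provenance: dict = field(default_factory=dict)
    threshold: float = GOOD_RMSE_THRESHOLD

    def rmse_matrix(self) -> pd.DataFrame:
        return self.table.pivot(index="fov_count", columns="window_end_h",
                                values="rmse")

    def pass_matrix(self) -> pd.DataFrame:
        return self.rmse_matrix() < self.threshold


def _labels_mapping(labels) -> dict[str, CloneLabel]:
    if isinstance(labels, Mapping):
        return {str(k): v for k, v in labels.items()}
    if isinstance(labels, pd.DataFrame):
        out = {}
        for _, r in labels.iterrows():
            out[str(r["clone_id"])] = CloneLabel(
                clone_id=str(r["clone_id"]),
                serial_passage_limit=int(r["potency"]),
                growth_rate=float(r.get("growth_rate", np.nan)))
        return out
    raise TypeError("labels must be a mapping or a clone_id/potency DataFrame")


def build_dataset(cells: pd.DataFrame, labels, window_end_h: int,
                  fov_ids: Sequence[int] | None = None,
                  B: int = 0, k: int | None = None,
                  seed: int = 0) -> CohortDataset:
    """Assemble a CohortDataset (raw or bootstrap) from a cell table.

    Raw mode (``B=0``) pools the given ``fov_ids`` (default: all observed
    FOVs). Bootstrap mode draws ``k`` FOVs with replacement, B times per
    clone.
    """
    label_map = _labels_mapping(labels)
    if B > 0:
        if k is None:
            k = len(fov_ids) if fov_ids is not None \
                else int(cells["fov"].nunique())
        profiles = bootstrap_profiles(cells, window_end_h, k=k, B=B, seed=seed)
        prov = {"window_end_h": window_end_h, "fov_count": k,
                "bootstrap": B, "seed": seed}
    else:
        profiles = []
        for clone_id, sub in cells.groupby("clone_id", sort=True):
            ids = fov_ids if fov_ids is not None \
                else sorted(sub["fov"].unique().tolist())
            profiles.append(build_profile(sub, window_end_h, ids))
        prov = {"window_end_h": window_end_h,
                "fov_count": len(set(profiles[0].fov_ids)), "bootstrap": 0}
    return CohortDataset(profiles=profiles, labels=label_map, provenance=prov)


def data_usage_grid(cells: pd.DataFrame, labels,
                    windows: Sequence[int], fov_counts: Sequence[int],
                    model_spec="lasso", B: int = 0,
                    seed: int = 0) -> DataUsageGrid:
    """Sweep window end x FOV count, scoring each cell by grouped-LOOCV RMSE.

    In the non-bootstrap sweep each grid cell uses one random
    without-replacement FOV draw derived from the master seed; with
    ``B > 0`` each cell uses B with-replacement bootstrap draws per clone.
    Per-cell failures are recorded in the table, never raised.
    """
    rng = np.random.default_rng(seed)
    available = sorted(cells["fov"].unique().tolist())
    rows, cvs, draws = [], {}, {}
    for w in windows:
        for k in fov_counts:
            cell_seed = int(rng.integers(0, 2**31 - 1))
            try:
                if B > 0:
                    ds = build_dataset(cells, labels, w, B=B, k=k,
                                       seed=cell_seed)
                else:
                    ids = subsample_fovs(available, k, cell_seed)
                    draws[(w, k)] = ids
                    ds = build_dataset(cells, labels, w, fov_ids=ids)
                cv = loocv(ds, model_spec, seed=cell_seed)
                cvs[(w, k)] = cv
                rows.append({"window_end_h": w, "fov_count": k,
                             "rmse": cv.rmse, "ok": True, "error": ""})
            except Exception as exc:  # recorded, grid still returned
                rows.append({"window_end_h": w, "fov_count": k,
                             "rmse": np.nan, "ok": False, "error": str(exc)})
    return DataUsageGrid(
        table=pd.DataFrame(rows), cv_results=cvs,
        provenance={"seed": seed, "bootstrap": B, "model": str(model_spec),
                    "fov_draws": {f"{w}h_{k}fov": v
                                  for (w, k), v in draws.items()}})


def model_structure_correlation(fits: Sequence[ModelFit]) -> pd.DataFrame:
    """Pearson correlation matrix of model weight vectors.

    Weights are aligned on the union of parameter names (absent = 0).
    A zero-variance weight vector yields NaN in its row/column.
    """
    if len(fits) < 2:
        raise ValueError("need >= 2 fits to correlate")
    names: list[str] = []
    for f in fits:
        for n in f.weights.index:
            if n not in names:
                names.append(str(n))
    W = np.zeros((len(fits), len(names)))
    for i, f in enumerate(fits):
        W[i] = f.weights.reindex(names).fillna(0.0).to_numpy()
    labels = [f.condition.get("name", f"fit{i}") for i, f in enumerate(fits)]
    sds = W.std(axis=1)
    C = np.full((len(fits), len(fits)), np.nan)
    for i in range(len(fits)):
        for j in range(len(fits)):
            if sds[i] > 0 and sds[j] > 0:
                C[i, j] = float(np.corrcoef(W[i], W[j])[0, 1])
    return pd.DataFrame(C, index=labels, columns=labels)
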