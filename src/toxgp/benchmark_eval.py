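"""Evaluation metrics, cross-validation, grid search and the comparative
regressor benchmark.

Alongside the standard regression metrics (MAE, RMSE, r2, Pearson r) two
uncertainty-aware statistics are reported for probabilistic models:

* ASD — the average per-test-point standard deviation of the predictive
  distribution, an aggregate confidence measure;
* weighted RMSE — RMSE with per-point weights derived from the predictive
  uncertainties, so that points the model itself flags as unreliable count
  less.  The default weighting is inverse-variance (w_i = 1/sd_i^2), the
  standard uncertainty weighting; w_i = 1/sd_i is available as an
  alternative reading.

The benchmark mirrors an eight-family regressor comparison (linear,
random forest, SVR, XGBoost, gradient boosting, GP, KNN, LightGBM) on one
shared train/test split, with dimensionality reduction applied per family
according to a configurable policy (by default the families that benefit
from it: linear, SVR, KNN, XGBoost and GP use the hierarchical truncated
SVD; the tree ensembles run on the raw fused features).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import clone
from sklearn.model_selection import KFold, ParameterGrid, ShuffleSplit

from .datatypes import FusedMatrix, SplitIndices
from .dimred import HierarchicalTSVD, PCAReducer, TruncatedSVDReducer
from .exceptions import ValidationError
from .gp_model import GaussianProcessRegressorARD, PredictionSet

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------
@dataclass
class MetricsReport:
    """Point-prediction and (optionally) uncertainty-aware test metrics."""

    mae: float
    rmse: float
    r2: float | None
    pearson_r: float | None
    weighted_rmse: float | None = None
    asd: float | None = None
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "mae": self.mae,
            "rmse": self.rmse,
            "r2": self.r2,
            "pearson_r": self.pearson_r,
            "weighted_rmse": self.weighted_rmse,
            "asd": self.asd,
            "n": self.n,
        }


def weighted_rmse(y_true, means, sds, weighting: str = "inverse_variance") -> float:
    """Uncertainty-weighted RMSE: sqrt(sum w_i e_i^2 / sum w_i)."""
    y_true = np.asarray(y_true, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if np.any(sds <= 0):
        raise ValidationError(
            "weighted RMSE needs strictly positive predictive SDs; "
            "add jitter / refit with a noise term"
        )
    if weighting == "inverse_variance":
        w = 1.0 / sds**2
    elif weighting == "inverse_sd":
        w = 1.0 / sds
    else:
        raise ValidationError(f"unknown weighting {weighting!r}")
    return float(np.sqrt(np.sum(w * (y_true - means) ** 2) / np.sum(w)))


def average_sd(predictions: PredictionSet) -> float:
    """ASD: arithmetic mean of the per-point predictive SDs."""
    if predictions.sds.size == 0:
        raise ValidationError("empty prediction set")
    return float(np.mean(predictions.sds))


def compute_metrics(y_true, predictions) -> MetricsReport:
    """Standard test metrics; uncertainty-aware ones when ``predictions``
    is a :class:`PredictionSet`.

    r2 = 1 - SS_res/SS_tot is undefined (reported as None, never 0) when
    y_true has zero variance.
    """
    if isinstance(predictions, PredictionSet):
        means, sds = predictions.means, predictions.sds
    else:
        means, sds = np.asarray(predictions, dtype=float), None
    y_true = np.asarray(y_true, dtype=float)
    if y_true.size != means.size or y_true.size < 2:
        raise ValidationError("need equal-length y_true/predictions with n >= 2")
    err = y_true - means
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = None if ss_tot == 0 else float(1.0 - np.sum(err**2) / ss_tot)
    if ss_tot == 0 or np.std(means) == 0:
        pearson = None
    else:
        pearson = float(scipy.stats.pearsonr(y_true, means).statistic)
    report = MetricsReport(mae=mae, rmse=rmse, r2=r2, pearson_r=pearson, n=y_true.size)
    if sds is not None:
        report.asd = average_sd(predictions)
        report.weighted_rmse = weighted_rmse(y_true, means, sds)
    return report


# --------------------------------------------------------------------------
# cross-validation and grid search
# --------------------------------------------------------------------------
def cross_validate(
    estimator,
    X,
    y,
    scheme: str = "shuffle_split",
    n_splits: int = 10,
    seed: int = 0,
    validation_fraction: float = 0.1,
) -> tuple[float, float]:
    """Per-split validation MAE; returns (mean, SD) over splits."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if n_splits < 2:
        raise ValidationError("n_splits must be >= 2")
    if n_splits > len(y):
        raise ValidationError(f"n_splits={n_splits} exceeds N={len(y)}")
    if scheme == "shuffle_split":
        splitter = ShuffleSplit(
            n_splits=n_splits, test_size=validation_fraction, random_state=seed
        )
    elif scheme == "k_fold":
        splitter = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    else:
        raise ValidationError(f"unknown CV scheme {scheme!r}")
    maes = []
    for tr, va in splitter.split(X):
        est = clone(estimator)
        est.fit(X[tr], y[tr])
        maes.append(float(np.mean(np.abs(y[va] - est.predict(X[va])))))
    return float(np.mean(maes)), float(np.std(maes))


def grid_search(
    estimator,
    grid: dict,
    X,
    y,
    scheme: str = "shuffle_split",
    n_splits: int = 10,
    seed: int = 0,
    validation_fraction: float = 0.1,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive search over ``grid``; best = lowest CV mean MAE, ties
    broken by grid enumeration order.  Failing configurations are logged
    and skipped."""
    if not grid:
        raise ValidationError("empty hyperparameter grid")
    rows = []
    best_params, best_mae = None, np.inf
    for params in ParameterGrid(grid):
        est = clone(estimator).set_params(**params)
        try:
            mean_mae, sd_mae = cross_validate(
                est, X, y, scheme=scheme, n_splits=n_splits, seed=seed,
                validation_fraction=validation_fraction,
            )
        except Exception as exc:  # estimator failure: skip, keep searching
            logger.warning("grid point %s failed: %s", params, exc)
            rows.append({**params, "cv_mean_mae": np.nan, "cv_sd_mae": np.nan})
            continue
        rows.append({**params, "cv_mean_mae": mean_mae, "cv_sd_mae": sd_mae})
        if mean_mae < best_mae:  # strict: earlier grid point wins ties
            best_params, best_mae = params, mean_mae
    if best_params is None:
        raise ValidationError("every grid configuration failed")
    return best_params, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# regressor registry and benchmark
# --------------------------------------------------------------------------
def _gradient_boosting(seed: int):
    from sklearn.ensemble import GradientBoostingRegressor

    return GradientBoostingRegressor(random_state=seed)


def make_estimator(name: str, seed: int = 0):
    """Instantiate a registered regressor family by name."""
    name = name.lower()
    if name == "linear":
        from sklearn.linear_model import LinearRegression

        return LinearRegression()
    if name == "random_forest":
        from sklearn.ensemble import RandomForestRegressor

        return RandomForestRegressor(random_state=seed)
    if name == "svr":
        from sklearn.svm import SVR

        return SVR()
    if name == "gradient_boosting":
        return _gradient_boosting(seed)
    if name == "knn":
        from sklearn.neighbors import KNeighborsRegressor

        return KNeighborsRegressor()
    if name == "gp":
        return GaussianProcessRegressorARD(seed=seed)
    if name == "mean":
        from sklearn.dummy import DummyRegressor

        return DummyRegressor(strategy="mean")
    if name == "xgboost":
        try:
            from xgboost import XGBRegressor

            return XGBRegressor(random_state=seed, verbosity=0)
        except ImportError:
            warnings.warn("xgboost unavailable; using gradient boosting instead")
            return _gradient_boosting(seed)
    if name == "lightgbm":
        try:
            from lightgbm import LGBMRegressor

            return LGBMRegressor(random_state=seed, verbose=-1)
        except ImportError:
            warnings.warn("lightgbm unavailable; using gradient boosting instead")
            return _gradient_boosting(seed)
    raise ValidationError(
        f"unknown regressor {name!r}; registered: {sorted(REGISTRY_NAMES)}"
    )


REGISTRY_NAMES = frozenset(
    {"linear", "random_forest", "svr", "xgboost", "gradient_boosting", "gp",
     "knn", "lightgbm", "mean"}
)

# families for which reduction helped; the rest run on raw fused features
DEFAULT_REDUCTION_POLICY = {
    "linear": "tsvdh",
    "svr": "tsvdh",
    "knn": "tsvdh",
    "xgboost": "tsvdh",
    "gp": "tsvdh",
    "random_forest": "none",
    "gradient_boosting": "none",
    "lightgbm": "none",
}


def make_reducer(kind: str, fused: FusedMatrix, k: int | None = None,
                 variance_threshold: float = 0.95):
    """Reducer factory: 'none' | 'tsvdh' | 'tsvd' | 'pca'."""
    if kind == "none":
        return None
    if kind == "tsvdh":
        return HierarchicalTSVD(
            variance_threshold=variance_threshold, n_chemical=fused.n_chemical
        )
    if kind == "tsvd":
        return TruncatedSVDReducer(k=k, variance_target=None if k else variance_threshold)
    if kind == "pca":
        return PCAReducer(k=k or 2)
    raise ValidationError(f"unknown reduction {kind!r}")


@dataclass
class BenchmarkResult:
    """Per-(regressor, reduction) test metrics on one shared split."""

    table: pd.DataFrame
    split: SplitIndices
    cv_scores: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def run_benchmark(
    fused: FusedMatrix,
    y,
    split: SplitIndices,
    suite: list[str] | None = None,
    reduction_policy: dict | None = None,
    variance_threshold: float = 0.95,
    seed: int = 0,
    cv: bool = False,
    cv_kwargs: dict | None = None,
) -> BenchmarkResult:
    """Fit every suite member on the shared training rows (reducers fitted
    on training rows only) and score it on the shared test rows.

    Estimator failures are recorded in ``result.errors``; the run
    continues.
    """
    y = np.asarray(y, dtype=float).ravel()
    suite = list(suite) if suite is not None else sorted(REGISTRY_NAMES)
    policy = dict(DEFAULT_REDUCTION_POLICY)
    if reduction_policy:
        policy.update(reduction_policy)
    unknown = [s for s in suite if s not in REGISTRY_NAMES]
    if unknown:
        raise ValidationError(
            f"unknown regressor(s) {unknown}; registered: {sorted(REGISTRY_NAMES)}"
        )

    rows, errors, cv_scores = [], {}, {}
    X_tr_full, X_te_full = fused.X[split.train], fused.X[split.test]
    y_tr, y_te = y[split.train], y[split.test]
    for name in suite:
        kinds = policy.get(name, "none")
        if isinstance(kinds, str):
            kinds = [kinds]
        for kind in kinds:
            try:
                reducer = make_reducer(kind, fused, variance_threshold=variance_threshold)
                if reducer is None:
                    X_tr, X_te = X_tr_full, X_te_full
                else:
                    X_tr = reducer.fit_transform(X_tr_full)
                    X_te = reducer.transform(X_te_full)
                est = make_estimator(name, seed=seed)
                if isinstance(est, GaussianProcessRegressorARD):
                    est.set_params(ard=reducer is not None)
                est.fit(X_tr, y_tr)
                if isinstance(est, GaussianProcessRegressorARD):
                    preds = est.predict_set(X_te)
                else:
                    preds = est.predict(X_te)
                report = compute_metrics(y_te, preds)
                if cv:
                    cv_scores[(name, kind)] = cross_validate(
                        make_estimator(name, seed=seed), X_tr, y_tr, **(cv_kwargs or {})
                    )
                rows.append({"regressor": name, "reduction": kind, **report.to_dict()})
            except Exception as exc:
                logger.warning(
                    "benchmark configuration %s/%s failed: %s", name, kind, exc
                )
                errors[(name, kind)] = str(exc)
    return BenchmarkResult(
        table=pd.DataFrame(rows), split=split, cv_scores=cv_scores, errors=errors
    )
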