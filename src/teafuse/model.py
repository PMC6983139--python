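"""Calibration/validation split, min-max normalization, grid-searched
regressors (epsilon-SVR, random forest, gradient boosting) and evaluation.

The split is stratified by tea variety: 7 calibration / 3 validation per
10-sample variety and 12 / 3 per 15-sample variety, giving 80 / 30 for
the default design. Features are min-max scaled with statistics fit on
the calibration set only; hyperparameters are chosen by 5-fold
cross-validated RMSE over ladders spanning the study's printed ranges.
Reports carry R^2, adjusted R^2 = 1 - (1-R^2)(n-1)/(n-p-1), and RMSE for
both sets.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import KFold
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .containers import EvaluationReport, FeatureTable, SetMetrics

log = logging.getLogger(__name__)

MODEL_NAMES = ("gridsvr", "rf", "xgboost")


# ---------------------------------------------------------------------------
# Stratified split
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    """Calibration/validation sample ids with per-variety allocation."""

    calibration_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    allocation: dict[str, tuple[int, int]]  # variety -> (n_cal, n_val)

    def __post_init__(self) -> None:
        if set(self.calibration_ids) & set(self.validation_ids):
            raise ValueError("calibration and validation sets overlap")


def _allocate(n: int) -> tuple[int, int]:
    """Near-7:3 allocation consistent with the 80/30 totals: 3 held out."""
    if n < 4:
        raise ValueError(f"variety with {n} samples cannot be split")
    return n - 3, 3


def stratified_split(
    sample_ids: list[str], varieties: list[str], seed: int
) -> SplitPlan:
    """Randomly split within each variety (7/3 per 10, 12/3 per 15)."""
    if len(sample_ids) != len(varieties):
        raise ValueError("sample_ids and varieties length mismatch")
    rng = np.random.Generator(np.random.PCG64(seed))
    groups: dict[str, list[str]] = {}
    for sid, var in zip(sample_ids, varieties):
        groups.setdefault(var, []).append(sid)
    cal: list[str] = []
    val: list[str] = []
    allocation: dict[str, tuple[int, int]] = {}
    for var in groups:  # insertion order: deterministic
        ids = groups[var]
        n_cal, n_val = _allocate(len(ids))
        perm = rng.permutation(len(ids))
        cal.extend(ids[i] for i in sorted(perm[:n_cal]))
        val.extend(ids[i] for i in sorted(perm[n_cal:]))
        allocation[var] = (n_cal, n_val)
    return SplitPlan(tuple(cal), tuple(val), allocation)


# ---------------------------------------------------------------------------
# Min-max normalization
# ---------------------------------------------------------------------------

def minmax_fit_apply(
    train: FeatureTable, apply_to: FeatureTable | None = None
) -> tuple[FeatureTable, FeatureTable | None, pd.DataFrame]:
    """Scale features to V' = (V - Vmin)/(Vmax - Vmin), statistics from
    ``train`` only; applied values are not clipped to [0, 1].

    Constant training features map to 0 (with a warning). Returns the
    scaled train table, the scaled apply table (or None) and a DataFrame
    of per-feature (Vmin, Vmax).
    """
    vmin = train.features.min(axis=0)
    vmax = train.features.max(axis=0)
    span = vmax - vmin
    constant = span == 0
    if constant.any():
        names = list(span.index[constant])
        warnings.warn(f"constant training features mapped to 0: {names}")
        span = span.mask(constant, 1.0)

    def _apply(tbl: FeatureTable) -> FeatureTable:
        scaled = (tbl.features - vmin) / span
        scaled = scaled.mask(
            pd.DataFrame(
                np.broadcast_to(constant.to_numpy(), scaled.shape),
                index=scaled.index, columns=scaled.columns,
            ),
            0.0,
        )
        return FeatureTable(scaled, tbl.target)

    stats = pd.DataFrame({"Vmin": vmin, "Vmax": vmax})
    return _apply(train), (_apply(apply_to) if apply_to is not None else None), stats


# ---------------------------------------------------------------------------
# Hyperparameter grids
# ---------------------------------------------------------------------------

def default_grid(algorithm: str) -> dict[str, list]:
    """Default search ladders within the study's printed ranges.

    SVR follows the libsvm convention (c = cost, g = RBF gamma, p =
    epsilon tube; the type code s = 3, epsilon-SVR, is fixed). RF and
    XGBoost ladders contain the printed optimum values.
    """
    if algorithm == "gridsvr":
        return {
            "C": list(20.0 / 2.0 ** np.arange(7, -1, -1.0)),  # (0, 20]
            "gamma": list(10.0 / 2.0 ** np.arange(7, -1, -1.0)),  # (0, 10]
            "epsilon": list(10.0 ** np.linspace(-3, 0, 5)),  # [0.001, 1]
        }
    if algorithm == "rf":
        return {
            "n_estimators": [100, 500, 1000, 2000],
            "max_depth": [1, 3, 5, 10],
        }
    if algorithm == "xgboost":
        return {
            "learning_rate": [0.1, 0.3, 1.0],
            "n_estimators": [100, 400, 1000],
            "max_depth": [3, 5, 10],
        }
    raise ValueError(f"unknown algorithm {algorithm!r}")


def fast_grid(algorithm: str) -> dict[str, list]:
    """Coarsened ladders for repeated end-to-end runs (documented choice)."""
    if algorithm == "gridsvr":
        return {
            "C": [0.625, 2.5, 10.0, 20.0],
            "gamma": [0.078125, 0.625, 2.5, 10.0],
            "epsilon": [0.001, 0.1],
        }
    if algorithm == "rf":
        return {"n_estimators": [100, 500], "max_depth": [3, 10]}
    if algorithm == "xgboost":
        return {"learning_rate": [0.1], "n_estimators": [100, 400], "max_depth": [3, 5]}
    raise ValueError(f"unknown algorithm {algorithm!r}")


_GRID_BOUNDS = {
    "gridsvr": {"C": (0.0, 20.0), "gamma": (0.0, 10.0), "epsilon": (0.001, 1.0)},
    "rf": {"n_estimators": (100, 2000), "max_depth": (1, 10)},
    "xgboost": {
        "learning_rate": (0.1, 1.0), "n_estimators": (100, 1000),
        "max_depth": (1, 10), "gamma": (0.1, 1.0), "subsample": (0.1, 1.0),
        "min_child_weight": (3, 10),
    },
}


@dataclass
class ModelConfig:
    """Algorithm choice plus its search grid and seed."""

    algorithm: str
    grid: dict[str, list] = field(default_factory=dict)
    seed: int = 0
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if self.algorithm not in MODEL_NAMES:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if not self.grid:
            self.grid = default_grid(self.algorithm)
        bounds = _GRID_BOUNDS[self.algorithm]
        for key, values in self.grid.items():
            if key not in bounds:
                raise ValueError(f"unknown grid parameter {key!r}")
            low, high = bounds[key]
            for v in values:
                if not (low <= v <= high):
                    raise ValueError(
                        f"{self.algorithm}: {key}={v} outside printed range "
                        f"[{low}, {high}]"
                    )


def _make_estimator(algorithm: str, params: dict, seed: int):
    if algorithm == "gridsvr":
        return SVR(kernel="rbf", **params)
    if algorithm == "rf":
        # full calibration set per tree (no bootstrap), feature subsampling only
        return RandomForestRegressor(
            bootstrap=False, max_features="sqrt", random_state=seed,
            n_jobs=1, **params,
        )
    return XGBRegressor(
        gamma=0.1, subsample=0.9, min_child_weight=5,
        random_state=seed, n_jobs=1, tree_method="hist", **params,
    )


@dataclass
class TrainedModel:
    """A fitted regressor plus the context needed to apply it."""

    algorithm: str
    estimator: object
    feature_names: list[str]
    best_params: dict
    cv_rmse: float
    permutation_importance_: pd.Series | None = None

    def predict(self, table: FeatureTable) -> np.ndarray:
        if table.feature_names != self.feature_names:
            raise ValueError(
                "feature names differ from the training table; expected "
                f"{self.feature_names}"
            )
        return np.asarray(self.estimator.predict(table.features.to_numpy(float)))


def train_model(config: ModelConfig, train: FeatureTable) -> TrainedModel:
    """Grid search by k-fold cross-validated RMSE, then refit on all of
    ``train``. Deterministic for a fixed seed; ties go to the first
    parameter combination in ladder order."""
    if train.target is None:
        raise ValueError("training table has no target")
    X = train.features.to_numpy(dtype=float)
    y = train.target.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    keys = list(config.grid)
    best: tuple[float, dict] | None = None
    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    folds = list(kf.split(X))
    for combo in itertools.product(*(config.grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        sse, n_tot = 0.0, 0
        for tr, te in folds:
            est = _make_estimator(config.algorithm, params, config.seed)
            est.fit(X[tr], y[tr])
            resid = y[te] - est.predict(X[te])
            sse += float(resid @ resid)
            n_tot += len(te)
        rmse = np.sqrt(sse / n_tot)
        if best is None or rmse < best[0]:
            best = (rmse, params)
    assert best is not None
    cv_rmse, params = best
    est = _make_estimator(config.algorithm, params, config.seed)
    est.fit(X, y)
    perm = None
    if config.algorithm == "rf":
        # single permutation round, computed once on the calibration data
        res = permutation_importance(
            est, X, y, n_repeats=1, random_state=config.seed, n_jobs=1
        )
        perm = pd.Series(res.importances_mean, index=train.feature_names)
    log.info("%s grid search: best %s (cv RMSE %.4f)", config.algorithm, params, cv_rmse)
    return TrainedModel(
        config.algorithm, est, train.feature_names, params, float(cv_rmse), perm
    )


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def adjusted_r2(r2: float, n: int, p: int) -> float:
    """1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    if n - p - 1 <= 0:
        raise ValueError(f"adjusted R^2 undefined for n={n}, p={p}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _metrics(y: np.ndarray, pred: np.ndarray, p: int) -> SetMetrics:
    resid = y - pred
    sstot = float(np.sum((y - y.mean()) ** 2))
    ssres = float(resid @ resid)
    r2 = 1.0 - ssres / sstot
    rmse = float(np.sqrt(np.mean(resid**2)))
    n = len(y)
    try:
        adj = adjusted_r2(r2, n, p)
    except ValueError:
        adj = float("nan")
    return SetMetrics(r2=r2, adjusted_r2=adj, rmse=rmse, n=n, p=p)


def evaluate(
    model: TrainedModel,
    cal: FeatureTable,
    val: FeatureTable,
    feature_set: str = "features",
) -> EvaluationReport:
    """R^2 / adjusted R^2 / RMSE on the calibration and validation sets;
    p is the number of model features."""
    if cal.target is None or val.target is None:
        raise ValueError("both tables need the polyphenol target")
    p = len(model.feature_names)
    return EvaluationReport(
        model_name=model.algorithm,
        feature_set=feature_set,
        n_variables=p,
        calibration=_metrics(cal.target.to_numpy(float), model.predict(cal), p),
        validation=_metrics(val.target.to_numpy(float), model.predict(val), p),
        best_params=model.best_params,
    )
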