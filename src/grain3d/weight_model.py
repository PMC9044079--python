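"""Single-grain weight prediction from the 32-trait record.

Five regressors — multivariable linear regression (LR), Bayesian ridge
(BR), k-nearest-neighbour regression (KNN), random forest (RF) and
gradient boosting (GBR) — are evaluated by 10-fold cross-validation.
Features are standardized on each training fold only, and the
hyperparameters of KNN/RF/GBR are chosen by grid search nested inside
each training fold, so the reported fold metrics see no leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import BayesianRidge, LinearRegression
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .traits import TRAIT_NAMES, metrics

__all__ = ["WeightModelReport", "train_weight_models", "predict_weight", "MODEL_NAMES"]

MODEL_NAMES = ("LR", "BR", "KNN", "RF", "GBR")

# grid-search spaces for the tunable regressors; LR/BR have none
_GRIDS = {
    "KNN": {"model__n_neighbors": [3, 5, 7, 9, 11]},
    "RF": {"model__n_estimators": [100, 300, 500], "model__max_depth": [None, 5, 10]},
    "GBR": {
        "model__learning_rate": [0.05, 0.1],
        "model__n_estimators": [100, 300],
        "model__max_depth": [2, 3],
    },
}


def _make_estimator(name: str, seed: int) -> Pipeline:
    if name == "LR":
        model = LinearRegression()
    elif name == "BR":
        model = BayesianRidge()
    elif name == "KNN":
        model = KNeighborsRegressor()
    elif name == "RF":
        model = RandomForestRegressor(random_state=seed, n_jobs=1)
    elif name == "GBR":
        model = GradientBoostingRegressor(random_state=seed)
    else:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    return Pipeline([("scale", StandardScaler()), ("model", model)])


@dataclass
class WeightModelReport:
    """Cross-validated performance per regressor plus refitted final models."""

    folds: int
    seed: int
    results: dict[str, dict] = field(default_factory=dict)
    fitted: dict[str, Pipeline] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"model": name, "R2": res["r2"], "MAPE_pct": res["mape_pct"], "RMSE_mg": res["rmse_mg"]}
            for name, res in self.results.items()
        ]
        return pd.DataFrame(rows).set_index("model")


def _feature_matrix(table: pd.DataFrame) -> np.ndarray:
    missing = [t for t in TRAIT_NAMES if t not in table.columns]
    if missing:
        raise ValueError(f"trait table missing feature columns: {missing}")
    X = table[TRAIT_NAMES].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("trait features contain non-finite values")
    return X


def train_weight_models(
    table: pd.DataFrame,
    models: Sequence[str] = MODEL_NAMES,
    folds: int = 10,
    seed: int = 0,
    r2_definition: str = "system_mean",
    inner_cv: int = 3,
) -> WeightModelReport:
    """Cross-validate weight regressors on a trait table with a weight column.

    Per outer fold: features are standardized and hyperparameters grid-
    searched on the training part only; MAPE/RMSE/R^2 are computed on the
    held-out part with the same metric definitions as the trait-accuracy
    evaluation, and averaged over folds.  Deterministic for a fixed seed.
    Finally each model is refitted on the full table (with full-data grid
    search) for use with :func:`predict_weight`.
    """
    if "weight" not in table.columns:
        raise ValueError("trait table has no 'weight' column")
    y = table["weight"].to_numpy(dtype=np.float64)
    X = _feature_matrix(table)
    n = len(y)
    if n < folds:
        raise ValueError(f"need at least folds={folds} rows, got {n}")
    if np.all(y == y[0]):
        raise ValueError("weight column is constant")
    if (y <= 0).any():
        raise ValueError("weights must be positive (mg)")
    if y.min() < 25.0 or y.max() > 50.0:
        warnings.warn(
            f"weights span [{y.min():.1f}, {y.max():.1f}] mg; single wheat grains "
            "are typically 25-50 mg", stacklevel=2,
        )

    report = WeightModelReport(folds=folds, seed=seed)
    outer = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(outer.split(X))
    for name in models:
        fold_metrics = []
        chosen = []
        for train_idx, test_idx in splits:
            est = _make_estimator(name, seed)
            if name in _GRIDS:
                est = GridSearchCV(est, _GRIDS[name], cv=inner_cv,
                                   scoring="neg_mean_squared_error", n_jobs=1)
            est.fit(X[train_idx], y[train_idx])
            if name in _GRIDS:
                chosen.append(est.best_params_)
                est = est.best_estimator_
            pred = est.predict(X[test_idx])
            fold_metrics.append(metrics(y[test_idx], pred, r2_definition=r2_definition))
        mape, rmse, r2 = (float(np.mean([m[i] for m in fold_metrics])) for i in range(3))
        report.results[name] = {
            "r2": r2,
            "mape_pct": mape,
            "rmse_mg": rmse,
            "fold_metrics": fold_metrics,
            "chosen_params": chosen,
        }
        final = _make_estimator(name, seed)
        if name in _GRIDS:
            search = GridSearchCV(final, _GRIDS[name], cv=inner_cv,
                                  scoring="neg_mean_squared_error", n_jobs=1)
            search.fit(X, y)
            report.results[name]["final_params"] = search.best_params_
            final = search.best_estimator_
        else:
            final.fit(X, y)
        report.fitted[name] = final
    return report


def predict_weight(model: Pipeline, traits) -> float:
    """Predict a single grain's weight (mg) from its 32-trait record.

    ``traits`` is a mapping (or single-row DataFrame) holding every trait
    column; a missing trait is a schema error.
    """
    if isinstance(traits, pd.DataFrame):
        row = traits.iloc[0].to_dict()
    else:
        row = dict(traits)
    missing = [t for t in TRAIT_NAMES if t not in row]
    if missing:
        raise ValueError(f"trait record missing features: {missing}")
    x = np.array([[float(row[t]) for t in TRAIT_NAMES]])
    return float(model.predict(x)[0])
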