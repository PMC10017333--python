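"""Spectral trait-prediction models: PLSR, SVM (RBF), GBM and RF.

All four predictors consume the 21-variable feature set (5 band means +
16 vegetation indices), are trained on a seeded 80/20 calibration/
validation split, standardize predictors with calibration statistics
only, and tune hyperparameters by cross-validated RMSE inside the
calibration set (leave-one-out for the PLSR component count, 5-fold for
the others).  Accuracy is reported as R2 = 1 - SS_res/SS_tot about the
evaluated set's own mean, and RMSE in trait percent units.  Variable
importance is permutation-based for every method so rankings are
comparable across methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import GridSearchCV, KFold, LeaveOneOut
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .spectral_indices import FEATURE_COLUMNS

__all__ = ["SplitSpec", "ModelSpec", "ModelResult", "split_data", "fit_model",
           "evaluate", "variable_importance", "compare_methods",
           "default_specs", "METHODS"]

METHODS = ("PLSR", "SVM", "GBM", "RF")


@dataclass(frozen=True)
class SplitSpec:
    """Unstratified random calibration/validation partition."""

    calibration_fraction: float = 0.8
    seed: int = 0


@dataclass(frozen=True)
class ModelSpec:
    """One method plus its tuning grid.

    Grid values are conventional defaults: SVM cost/width and the GBM
    learning-rate x size grid are searched by inner CV; PLSR searches
    its component count by leave-one-out; RF uses 300 trees untuned.
    """

    method: str
    params: Mapping[str, Sequence] = field(default_factory=dict)
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")


def default_specs(seed: int = 0) -> dict[str, ModelSpec]:
    return {
        "PLSR": ModelSpec("PLSR", {"n_components": list(range(1, 11))}, seed=seed),
        "SVM": ModelSpec("SVM", {"C": [0.25, 0.5, 1.0, 2.0, 4.0],
                                 "gamma": [0.01, 0.1, 1.0]}, seed=seed),
        "GBM": ModelSpec("GBM", {"learning_rate": [0.01, 0.05, 0.1],
                                 "n_estimators": [100, 300, 500, 1000]}, seed=seed),
        "RF": ModelSpec("RF", {"n_estimators": [300]}, seed=seed),
    }


@dataclass
class ModelResult:
    method: str
    trait: str
    cal_r2: float
    cal_rmse: float
    val_r2: float
    val_rmse: float
    chosen_params: dict
    importance: pd.Series | None = None

    @property
    def overfit_gap(self) -> float:
        return self.cal_r2 - self.val_r2


def split_data(table: pd.DataFrame, spec: SplitSpec = SplitSpec()
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded uniform partition: floor(fraction*n) calibration rows,
    remainder validation."""
    n = len(table)
    if n < 10:
        raise ValueError(f"need at least 10 rows to split, got {n}")
    if not 0 < spec.calibration_fraction <= 1:
        raise ValueError("calibration fraction must lie in (0, 1]")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_cal = int(np.floor(spec.calibration_fraction * n))
    cal = table.iloc[np.sort(perm[:n_cal])].reset_index(drop=True)
    val = table.iloc[np.sort(perm[n_cal:])].reset_index(drop=True)
    return cal, val


def _feature_matrix(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise KeyError(f"feature table lacks predictor columns {missing}")
    if "vi_undefined" in table.columns and table["vi_undefined"].any():
        raise ValueError("feature table contains rows flagged vi_undefined; "
                         "drop them before fitting")
    return table[list(FEATURE_COLUMNS)]


def fit_model(spec: ModelSpec, calibration: pd.DataFrame, trait: str) -> Pipeline:
    """Fit one method on the calibration set.

    Standardization statistics and grid-search CV folds come from the
    calibration rows only; validation data never enters this function.
    """
    X = _feature_matrix(calibration)
    y = calibration[trait].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError(f"trait {trait!r} is constant in calibration; R2 undefined")

    if spec.method == "PLSR":
        est = PLSRegression(scale=False)
        grid = {"model__n_components":
                [c for c in spec.params.get("n_components", range(1, 11))
                 if c <= X.shape[1]]}
        cv = LeaveOneOut()
    elif spec.method == "SVM":
        est = SVR(kernel="rbf")
        grid = {"model__C": list(spec.params.get("C", [1.0])),
                "model__gamma": list(spec.params.get("gamma", ["scale"]))}
        cv = KFold(spec.cv_folds, shuffle=True, random_state=spec.seed)
    elif spec.method == "GBM":
        est = GradientBoostingRegressor(random_state=spec.seed)
        grid = {"model__learning_rate": list(spec.params.get("learning_rate", [0.1])),
                "model__n_estimators": list(spec.params.get("n_estimators", [100]))}
        cv = KFold(spec.cv_folds, shuffle=True, random_state=spec.seed)
    else:  # RF
        est = RandomForestRegressor(
            n_estimators=int(spec.params.get("n_estimators", [300])[0]),
            random_state=spec.seed)
        grid = {}
        cv = None

    pipe = Pipeline([("scale", StandardScaler()), ("model", est)])
    if grid and max(len(v) for v in grid.values()) > 1 or len(grid) > 1:
        search = GridSearchCV(pipe, grid, cv=cv,
                              scoring="neg_root_mean_squared_error", n_jobs=1)
        search.fit(X, y)
        fitted: Pipeline = search.best_estimator_
        fitted.chosen_params_ = {k.removeprefix("model__"): v
                                 for k, v in search.best_params_.items()}
    else:
        if grid:
            pipe.set_params(**{k: v[0] for k, v in grid.items()})
        pipe.fit(X, y)
        fitted = pipe
        fitted.chosen_params_ = {k.removeprefix("model__"): v[0] for k, v in grid.items()}
        if spec.method == "RF":
            fitted.chosen_params_ = {"n_estimators": est.n_estimators}
    fitted.trait_ = trait
    return fitted


def evaluate(predictor: Pipeline, dataset: pd.DataFrame,
             trait: str | None = None) -> tuple[float, float]:
    """(R2, RMSE) on a dataset; R2 about the dataset's own mean."""
    if len(dataset) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    trait = trait or predictor.trait_
    y = dataset[trait].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError(f"trait {trait!r} has zero variance; R2 undefined")
    pred = np.ravel(predictor.predict(_feature_matrix(dataset)))
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot, float(np.sqrt(ss_res / len(y)))


def variable_importance(predictor: Pipeline, calibration: pd.DataFrame,
                        trait: str | None = None, n_repeats: int = 10,
                        seed: int = 0) -> pd.Series:
    """Permutation importance rescaled to a 0-100 scale.

    Mean RMSE increase over ``n_repeats`` seeded permutations of each
    predictor column, linearly rescaled so the largest score is 100
    (all-zero when no predictor is informative).  Scores do not depend
    on predictor column order.
    """
    trait = trait or predictor.trait_
    X = _feature_matrix(calibration)
    y = calibration[trait].to_numpy(dtype=float)
    res = permutation_importance(predictor, X, y, n_repeats=n_repeats,
                                 random_state=seed,
                                 scoring="neg_root_mean_squared_error")
    scores = np.clip(res.importances_mean, 0.0, None)
    top = scores.max()
    if top > 0:
        scores = scores * (100.0 / top)
    return pd.Series(scores, index=list(FEATURE_COLUMNS), name="importance")


def compare_methods(table: pd.DataFrame,
                    traits: Sequence[str] = ("N", "NSC"),
                    specs: Mapping[str, ModelSpec] | None = None,
                    split: SplitSpec = SplitSpec(),
                    importance: bool = True) -> tuple[pd.DataFrame, list[ModelResult]]:
    """Fit every method for every trait on one split.

    Returns a tidy comparison frame (one row per method x trait with
    calibration/validation R2 and RMSE, the overfitting gap and a
    best-validation flag) plus the full ModelResult objects.
    """
    specs = specs or default_specs(seed=split.seed)
    cal, val = split_data(table, split)
    if len(val) == 0:
        raise ValueError("validation set is empty; lower the calibration fraction")
    results: list[ModelResult] = []
    for trait in traits:
        for method in METHODS:
            if method not in specs:
                raise ValueError(f"no ModelSpec supplied for {method}")
            fitted = fit_model(specs[method], cal, trait)
            cal_r2, cal_rmse = evaluate(fitted, cal, trait)
            val_r2, val_rmse = evaluate(fitted, val, trait)
            imp = (variable_importance(fitted, cal, trait, seed=specs[method].seed)
                   if importance else None)
            results.append(ModelResult(method, trait, cal_r2, cal_rmse,
                                       val_r2, val_rmse,
                                       dict(fitted.chosen_params_), imp))
    rows = []
    for trait in traits:
        tr = [r for r in results if r.trait == trait]
        best = max(tr, key=lambda r: r.val_r2)
        for r in tr:
            rows.append({"trait": r.trait, "method": r.method,
                         "cal_r2": r.cal_r2, "cal_rmse": r.cal_rmse,
                         "val_r2": r.val_r2, "val_rmse": r.val_rmse,
                         "overfit_gap": r.overfit_gap,
                         "best": r.method == best.method})
    return pd.DataFrame(rows), results
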