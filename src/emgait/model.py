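"""Severity regression: univariate feature selection + random forest.

For each PROM target the pipeline splits limbs 80/20 (stratified by
severity class, optionally grouped by subject so both limbs stay on the
same side of the split), selects the k best features by the univariate
F-statistic for regression on the training portion only, tunes the
forest's ``max_depth`` by k-fold cross-validation on the training
portion, refits at the chosen depth, and evaluates on the held-out
split. Alternate model families (linear, ridge, lasso, SVR) share the
same interface; the random forest is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats
from sklearn.ensemble import RandomForestRegressor
from sklearn.feature_selection import f_regression
from sklearn.linear_model import Lasso, LinearRegression, Ridge
from sklearn.model_selection import GroupShuffleSplit, KFold, train_test_split
from sklearn.svm import SVR

from .features import TARGET_COLUMNS, emg_feature_columns
from .prom import categorize_vas, categorize_womac_total

DEFAULT_DEPTH_GRID: tuple[int, ...] = (4, 5, 6, 7, 8, 9, 10, 11, 12)

MODEL_FAMILIES = ("rforest", "linear", "ridge", "lasso", "svr")


@dataclass
class ModelConfig:
    k_features: int = 15
    test_fraction: float = 0.20
    cv_folds: int = 5
    depth_grid: tuple[int, ...] = DEFAULT_DEPTH_GRID
    n_trees: int = 500
    seed: int = 0
    targets: tuple[str, ...] = TARGET_COLUMNS
    family: str = "rforest"
    group_by_subject: bool = True
    include_temporospatial: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError(f"test_fraction must lie in (0, 1), got {self.test_fraction}")
        if self.cv_folds < 2:
            raise ValueError(f"cv_folds must be >= 2, got {self.cv_folds}")
        if self.k_features < 1:
            raise ValueError(f"k_features must be >= 1, got {self.k_features}")
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")


def select_k_best(
    X: pd.DataFrame, y: np.ndarray, k: int
) -> tuple[list[str], np.ndarray]:
    """Top-k feature names by the univariate F-statistic for regression.

    Ties break deterministically by column order. Constant features score
    zero rather than NaN.
    """
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds the {X.shape[1]} available features")
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("target is constant; univariate F-scores undefined")
    scores, _ = f_regression(X.to_numpy(dtype=float), y)
    scores = np.nan_to_num(scores, nan=0.0)
    # stable: sort by (-score, column index)
    order = np.lexsort((np.arange(len(scores)), -scores))
    chosen = order[:k]
    chosen_sorted = np.sort(chosen)  # keep original column order among winners
    return [X.columns[i] for i in chosen_sorted], scores


def _make_estimator(config: ModelConfig, depth: int | None = None):
    if config.family == "rforest":
        return RandomForestRegressor(
            n_estimators=config.n_trees,
            max_depth=depth,
            random_state=config.seed,
            n_jobs=1,
        )
    if config.family == "linear":
        return LinearRegression()
    if config.family == "ridge":
        return Ridge(random_state=config.seed)
    if config.family == "lasso":
        return Lasso(random_state=config.seed)
    return SVR()


def fit_rf(
    X: pd.DataFrame, y: np.ndarray, config: ModelConfig
) -> tuple[RandomForestRegressor, pd.DataFrame]:
    """Tune ``max_depth`` by k-fold CV, refit on all training rows.

    Returns the refit model and a frame with one row per depth in the
    grid (mean and per-fold validation R^2). Ties in mean CV R^2 go to
    the smaller depth.
    """
    Xv = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(Xv)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in features or target")
    if len(y) < config.cv_folds:
        raise ValueError(f"need at least cv_folds={config.cv_folds} training rows")
    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    folds = list(kf.split(Xv))
    rows = []
    for depth in config.depth_grid:
        fold_scores = []
        for tr, va in folds:
            est = _make_estimator(config, depth)
            est.fit(Xv[tr], y[tr])
            pred = est.predict(Xv[va])
            fold_scores.append(_r2(y[va], pred))
        rows.append(
            {"max_depth": depth, "mean_cv_r2": float(np.mean(fold_scores)),
             **{f"fold{i}_r2": s for i, s in enumerate(fold_scores)}}
        )
    cv = pd.DataFrame(rows)
    best = cv.sort_values(["mean_cv_r2", "max_depth"], ascending=[False, True]).iloc[0]
    model = _make_estimator(config, int(best["max_depth"]))
    model.fit(Xv, y)
    return model, cv


def _r2(y: np.ndarray, pred: np.ndarray) -> float:
    sse = float(np.sum((y - pred) ** 2))
    sst = float(np.sum((y - np.mean(y)) ** 2))
    if sst == 0:
        raise ValueError("zero-variance target: R^2 undefined")
    return 1.0 - sse / sst


def evaluate(model, X: pd.DataFrame, y: np.ndarray) -> dict[str, float]:
    """Held-out metrics: R^2 = 1 - SSE/SST, RMSE, Pearson r."""
    y = np.asarray(y, dtype=float)
    if len(y) == 0:
        raise ValueError("empty test set")
    pred = model.predict(X.to_numpy(dtype=float))
    r2 = _r2(y, pred)
    rmse = float(np.sqrt(np.mean((y - pred) ** 2)))
    if np.ptp(pred) == 0 or np.ptp(y) == 0:
        r = 0.0
    else:
        r = float(spstats.pearsonr(y, pred)[0])
    return {"r2": r2, "rmse": rmse, "pearson_r": r}


@dataclass
class TargetReport:
    target: str
    selected_features: list[str]
    max_depth: int
    cv_curve: pd.DataFrame
    fold_r2: list[float]
    mean_cv_r2: float
    test_metrics: dict[str, float]
    model: object
    train_index: np.ndarray
    test_index: np.ndarray
    predictions: pd.DataFrame = field(repr=False, default=None)


def _severity_strata(table: pd.DataFrame, target: str) -> np.ndarray:
    if target == "vas":
        return table["vas"].map(categorize_vas).to_numpy()
    return table["womac_total"].map(categorize_womac_total).to_numpy()


def split_table(
    table: pd.DataFrame, target: str, config: ModelConfig
) -> tuple[np.ndarray, np.ndarray]:
    """80/20 row split, stratified by severity class; grouped by subject
    when ``group_by_subject`` so limbs of one subject never straddle it."""
    idx = np.arange(len(table))
    if config.group_by_subject and "subject_id" in table.columns:
        splitter = GroupShuffleSplit(
            n_splits=1, test_size=config.test_fraction, random_state=config.seed
        )
        tr, te = next(splitter.split(idx, groups=table["subject_id"].to_numpy()))
        return idx[tr], idx[te]
    strata = _severity_strata(table, target)
    # stratification needs every class at least twice; fall back otherwise
    labels, counts = np.unique(strata, return_counts=True)
    stratify = strata if counts.min() >= 2 and len(labels) > 1 else None
    tr, te = train_test_split(
        idx, test_size=config.test_fraction, random_state=config.seed, stratify=stratify
    )
    return np.sort(tr), np.sort(te)


def run_target(table: pd.DataFrame, target: str, config: ModelConfig) -> TargetReport:
    if target not in table.columns:
        raise KeyError(f"target column {target!r} missing from feature table")
    feat_cols = emg_feature_columns(table)
    if config.include_temporospatial:
        feat_cols = feat_cols + [c for c in ("speed", "step_length", "stride_length", "cadence") if c in table.columns]
    k = min(config.k_features, len(feat_cols))
    train_idx, test_idx = split_table(table, target, config)
    X_all = table[feat_cols]
    y_all = table[target].to_numpy(dtype=float)

    selected, _scores = select_k_best(X_all.iloc[train_idx], y_all[train_idx], k)
    X_train, y_train = X_all.iloc[train_idx][selected], y_all[train_idx]
    X_test, y_test = X_all.iloc[test_idx][selected], y_all[test_idx]

    model, cv = fit_rf(X_train, y_train, config)
    best_row = cv.sort_values(["mean_cv_r2", "max_depth"], ascending=[False, True]).iloc[0]
    fold_cols = [c for c in cv.columns if c.startswith("fold")]
    metrics = evaluate(model, X_test, y_test)
    preds = pd.DataFrame(
        {
            "actual": y_test,
            "predicted": model.predict(X_test.to_numpy(dtype=float)),
        },
        index=test_idx,
    )
    depth = model.max_depth if hasattr(model, "max_depth") and model.max_depth else int(best_row["max_depth"])
    return TargetReport(
        target=target,
        selected_features=selected,
        max_depth=int(depth),
        cv_curve=cv,
        fold_r2=[float(best_row[c]) for c in fold_cols],
        mean_cv_r2=float(best_row["mean_cv_r2"]),
        test_metrics=metrics,
        model=model,
        train_index=train_idx,
        test_index=test_idx,
        predictions=preds,
    )


def run_all_targets(table: pd.DataFrame, config: ModelConfig) -> dict[str, TargetReport]:
    """Fit and evaluate one model per requested PROM target."""
    missing = [t for t in config.targets if t not in table.columns]
    if missing:
        raise KeyError(f"feature table is missing target column(s): {missing}")
    return {t: run_target(table, t, config) for t in config.targets}


def report_to_dict(reports: dict[str, TargetReport]) -> dict:
    """JSON-serializable summary of a multi-target regression run."""
    out = {}
    for target, rep in reports.items():
        out[target] = {
            "selected_features": rep.selected_features,
            "max_depth": rep.max_depth,
            "fold_r2": rep.fold_r2,
            "mean_cv_r2": rep.mean_cv_r2,
            "test_r2": rep.test_metrics["r2"],
            "rmse": rep.test_metrics["rmse"],
            "pearson_r": rep.test_metrics["pearson_r"],
        }
    return out
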