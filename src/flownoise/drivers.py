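"""Attribution of spatial variation in noise color to drivers.

A random-forest regression links the per-gage noise color to 13 covariates
in four categories (geography, hydroclimate, land use, water management).
The workflow mirrors the standard hydro-informatics setup: an 80/20
train/test split, out-of-bag MSE on the training forest, held-out Pearson
r and percent bias, per-covariate relative importance normalized to sum to
100% (with per-category sums for the pie-chart view), partial-dependence
curves on a min-max normalized [0, 1] covariate scale, and prediction on
new reaches restricted to the calibration range of every covariate so the
model never extrapolates to unobserved environmental conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import GridSearchCV, train_test_split

__all__ = [
    "DriverTable",
    "DriverModelResult",
    "DriverModelConfig",
    "KSComparison",
    "fit_driver_model",
    "grouped_importance",
    "partial_dependence",
    "compare_groups_ks",
    "scale_correlation",
    "predict_network",
]

RESPONSE_COL = "noise_color"
ID_COLS = ("gage_id", "reach_id")


@dataclass
class DriverTable:
    """Per-gage (or per-reach) covariates, optionally with the response.

    ``data`` holds one row per gage/reach: an optional identifier column,
    the 13 covariate columns, and — for modeling tables — a
    ``noise_color`` response column. ``categories`` maps every covariate to
    one of Geo / Hydro / Land use / Water use.
    """

    data: pd.DataFrame
    categories: dict[str, str]
    response_col: str = RESPONSE_COL

    def __post_init__(self) -> None:
        if len(self.categories) != 13:
            raise ValueError("category map must cover exactly 13 covariates")
        missing = set(self.categories) - set(self.data.columns)
        if missing:
            raise ValueError(f"covariate columns absent from table: {sorted(missing)}")
        if self.has_response:
            model_rows = self.data[self.data[self.response_col].notna()]
            if model_rows[self.covariates].isna().any().any():
                raise ValueError("modeling rows must have no missing covariates")

    @property
    def covariates(self) -> list[str]:
        return list(self.categories)

    @property
    def has_response(self) -> bool:
        return self.response_col in self.data.columns

    @property
    def X(self) -> pd.DataFrame:
        return self.data[self.covariates]

    @property
    def y(self) -> pd.Series:
        if not self.has_response:
            raise ValueError("table has no response column")
        return self.data[self.response_col]

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class DriverModelConfig:
    """Random-forest settings.

    ``max_features=1/3`` and ``min_samples_leaf=5`` are the canonical
    regression-forest defaults; ``tune=True`` instead selects them by
    ``n_folds``-fold cross-validation on the training split over a small
    grid. Importance defaults to permutation importance on the held-out
    split (less biased than impurity importance for mixed-scale
    covariates); ``impurity`` is available as an option.
    """

    train_fraction: float = 0.8
    n_folds: int = 10
    n_estimators: int = 300
    tune: bool = False
    tuning_grid: dict = field(
        default_factory=lambda: {
            "max_features": [1.0 / 3.0, "sqrt", 1.0],
            "min_samples_leaf": [1, 5],
        }
    )
    importance: Literal["permutation", "impurity"] = "permutation"
    n_permutation_repeats: int = 10
    pdp_grid_size: int = 21
    compute_pdp: bool = True
    seed: int = 0


@dataclass
class DriverModelResult:
    """A fitted driver model plus its diagnostics.

    ``importance`` and ``grouped_importance`` are percentages summing to
    100; ``pdp`` maps each covariate to a (normalized grid, mean
    prediction) pair; ``calibration_ranges`` records per-covariate
    [min, max] over the modeling rows, used to mask extrapolation when
    predicting on new reaches.
    """

    model: RandomForestRegressor
    oob_mse: float
    test_r: float
    test_pbias: float
    test_mse: float
    importance: pd.Series
    grouped_importance: pd.Series
    pdp: dict[str, tuple[np.ndarray, np.ndarray]]
    calibration_ranges: pd.DataFrame
    categories: dict[str, str]
    covariates: list[str]
    seed: int
    best_params: dict
    flags: set[str] = field(default_factory=set)
    X_model: pd.DataFrame | None = None


def _normalize_importance(raw: np.ndarray, names: Sequence[str], flags: set[str]) -> pd.Series:
    vals = np.clip(np.asarray(raw, dtype=float), 0.0, None)
    total = vals.sum()
    if total <= 0:
        flags.add("degenerate_importance")
        return pd.Series(np.nan, index=list(names))
    return pd.Series(vals / total * 100.0, index=list(names))


def fit_driver_model(table: DriverTable, config: DriverModelConfig | None = None) -> DriverModelResult:
    """Fit the random-forest driver model and compute all diagnostics.

    The table is split 80/20 (by ``config.train_fraction``); the forest is
    fitted on the training split with out-of-bag scoring, evaluated on the
    held-out split (Pearson r, percent bias, MSE), and interrogated for
    normalized importance, grouped importance and partial dependence.
    Deterministic given ``config.seed``.
    """
    cfg = config or DriverModelConfig()
    if not table.has_response:
        raise ValueError("driver table has no response column")
    model_rows = table.data[table.data[table.response_col].notna()]
    if len(model_rows) < 30:
        raise ValueError("need at least 30 modeling rows")
    X = model_rows[table.covariates]
    y = model_rows[table.response_col].astype(float)
    flags: set[str] = set()
    if float(y.std()) == 0.0:
        flags.add("constant_response")

    X_train, X_test, y_train, y_test = train_test_split(
        X, y, train_size=cfg.train_fraction, random_state=cfg.seed
    )

    base = dict(
        n_estimators=cfg.n_estimators,
        oob_score=True,
        bootstrap=True,
        random_state=cfg.seed,
        n_jobs=1,
    )
    if cfg.tune and "constant_response" not in flags:
        search = GridSearchCV(
            RandomForestRegressor(**base),
            cfg.tuning_grid,
            cv=cfg.n_folds,
            scoring="neg_mean_squared_error",
            n_jobs=1,
        )
        search.fit(X_train, y_train)
        model = search.best_estimator_
        best_params = dict(search.best_params_)
    else:
        best_params = {"max_features": 1.0 / 3.0, "min_samples_leaf": 5}
        model = RandomForestRegressor(**base, **best_params)
        model.fit(X_train, y_train)

    oob_mse = float(np.mean((model.oob_prediction_ - y_train.values) ** 2))
    pred = model.predict(X_test)
    if float(np.std(pred)) == 0.0 or float(y_test.std()) == 0.0:
        test_r = math.nan
        flags.add("test_r_undefined")
    else:
        test_r = float(stats.pearsonr(pred, y_test.values).statistic)
    denom = float(np.sum(y_test.values))
    test_pbias = math.nan if denom == 0 else float(100.0 * np.sum(pred - y_test.values) / denom)
    test_mse = float(np.mean((pred - y_test.values) ** 2))

    if cfg.importance == "permutation":
        perm = permutation_importance(
            model, X_test, y_test,
            n_repeats=cfg.n_permutation_repeats,
            random_state=cfg.seed,
            scoring="neg_mean_squared_error",
        )
        importance = _normalize_importance(perm.importances_mean, table.covariates, flags)
    elif cfg.importance == "impurity":
        importance = _normalize_importance(model.feature_importances_, table.covariates, flags)
    else:
        raise ValueError(f"unknown importance kind: {cfg.importance}")

    grouped = grouped_importance(importance, table.categories)
    ranges = pd.DataFrame({"min": X.min(), "max": X.max()})

    result = DriverModelResult(
        model=model,
        oob_mse=oob_mse,
        test_r=test_r,
        test_pbias=test_pbias,
        test_mse=test_mse,
        importance=importance,
        grouped_importance=grouped,
        pdp={},
        calibration_ranges=ranges,
        categories=dict(table.categories),
        covariates=table.covariates,
        seed=cfg.seed,
        best_params=best_params,
        flags=flags,
        X_model=X,
    )
    if cfg.compute_pdp:
        grid = np.linspace(0.0, 1.0, cfg.pdp_grid_size)
        result.pdp = {c: partial_dependence(result, c, grid) for c in table.covariates}
    return result


def grouped_importance(importance: pd.Series, category_map: Mapping[str, str]) -> pd.Series:
    """Sum per-covariate importances (%) within each driver category."""
    missing = set(importance.index) - set(category_map)
    if missing:
        raise ValueError(f"covariates missing from category map: {sorted(missing)}")
    cats = pd.Series({c: category_map[c] for c in importance.index})
    return importance.groupby(cats).sum()


def partial_dependence(
    result: DriverModelResult, covariate: str, grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Partial-dependence curve of one covariate on a normalized [0, 1] grid.

    Each grid point g maps to min + g*(max - min) on the covariate's
    calibration range; the curve value is the mean model prediction over
    the modeling rows with that covariate pinned — the change in noise
    color attributed to the covariate with the others averaged out.
    """
    if covariate not in result.covariates:
        raise ValueError(f"unknown covariate: {covariate}")
    if result.X_model is None:
        raise ValueError("result holds no modeling rows")
    grid = np.linspace(0.0, 1.0, 21) if grid is None else np.asarray(grid, dtype=float)
    lo = float(result.calibration_ranges.loc[covariate, "min"])
    hi = float(result.calibration_ranges.loc[covariate, "max"])
    curve = np.empty(grid.size)
    work = result.X_model.copy()
    for i, g in enumerate(grid):
        work[covariate] = lo + g * (hi - lo)
        curve[i] = float(result.model.predict(work).mean())
    return grid, curve


@dataclass
class KSComparison:
    d_statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


def compare_groups_ks(colors_a: Sequence[float], colors_b: Sequence[float]) -> KSComparison:
    """Two-sample Kolmogorov-Smirnov comparison of noise-color distributions.

    Used to contrast regulated against free-flowing gages; reports the D
    statistic, the asymptotic p-value and both group means.
    """
    a = np.asarray(colors_a, dtype=float)
    b = np.asarray(colors_b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("each group needs at least 5 values")
    res = stats.ks_2samp(a, b, method="asymp")
    return KSComparison(
        d_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n_a=int(a.size),
        n_b=int(b.size),
    )


def scale_correlation(records: Sequence) -> pd.DataFrame:
    """Pearson correlation of daily global color with annual and banded colors.

    Consumes :class:`flownoise.spectral.GageColorRecord` objects; each
    comparison uses the gages where both estimates exist and is reported
    with its sample size. At least 3 overlapping gages are required per
    comparison (others are NaN).
    """
    rows = []
    for rec in records:
        row = {"gage_id": rec.gage_id, "daily_global": rec.daily_global.a}
        for metric in ("mean", "min", "max"):
            est = getattr(rec, f"annual_{metric}")
            row[f"annual_{metric}"] = est.a if est is not None else np.nan
        for label, est in rec.daily_bands.items():
            if label != "global":
                row[f"band_{label}"] = est.a
        rows.append(row)
    frame = pd.DataFrame(rows).set_index("gage_id")
    others = [c for c in frame.columns if c != "daily_global"]
    out = []
    for col in others:
        both = frame[["daily_global", col]].dropna()
        if len(both) < 3:
            out.append({"comparison": col, "r": np.nan, "n": len(both)})
            continue
        x, y = both["daily_global"].values, both[col].values
        if np.std(x) == 0 or np.std(y) == 0:
            out.append({"comparison": col, "r": np.nan, "n": len(both)})
            continue
        out.append(
            {"comparison": col, "r": float(stats.pearsonr(x, y).statistic), "n": len(both)}
        )
    table = pd.DataFrame(out).set_index("comparison")
    if table["n"].max() < 3:
        raise ValueError("fewer than 3 gages with overlapping estimates")
    return table


def predict_network(
    result: DriverModelResult,
    reaches: DriverTable,
    calibration_ranges: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Predict noise color for new reaches, masking extrapolation.

    A reach is predicted only when every covariate lies inside the
    calibration range observed among the modeling gages; otherwise it is
    masked and the violating covariates are named. Masking depends only on
    the covariate values and the ranges, never on the forest's seed.
    Predictions are classified onto the five-color scheme.
    """
    from .spectral import classify_color

    if list(reaches.covariates) != list(result.covariates):
        raise ValueError("reach table covariates do not match the fitted model")
    ranges = result.calibration_ranges if calibration_ranges is None else calibration_ranges
    X = reaches.X
    lo = ranges["min"].reindex(result.covariates)
    hi = ranges["max"].reindex(result.covariates)
    below = X.lt(lo, axis=1)
    above = X.gt(hi, axis=1)
    out_of_range = below | above
    masked = out_of_range.any(axis=1)

    predictions = np.full(len(X), np.nan)
    if (~masked).any():
        predictions[~masked.values] = result.model.predict(X[~masked])

    violators = [
        ",".join(sorted(out_of_range.columns[out_of_range.iloc[i].values])) if masked.iloc[i] else ""
        for i in range(len(X))
    ]
    out = pd.DataFrame(
        {
            "prediction": predictions,
            "masked": masked.values,
            "mask_reason": violators,
            "category": [
                classify_color(p) if np.isfinite(p) else "" for p in predictions
            ],
        },
        index=X.index,
    )
    id_col = next((c for c in ID_COLS if c in reaches.data.columns), None)
    if id_col:
        out.insert(0, id_col, reaches.data[id_col].values)
    return out
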