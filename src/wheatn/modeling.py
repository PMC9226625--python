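"""Model fitting and evaluation for nitrogen-status estimation.

The protocol: observations are split 70/30 into training and test sets
(train size = floor(0.7 n), optionally stratified by zone), a simple linear
regression on NDRE provides the baseline, and random-forest regressors are
tuned by exhaustive grid search with K-fold cross-validation (score = mean
CV R^2).  Accuracy is reported as

- R^2: coefficient of determination, 1 - SS_res / SS_tot
- RMSE: sqrt(mean squared error), in target units
- RE: relative error, 100 * RMSE / mean(observed), in %

Cross-validated metrics are the plain mean of the per-fold values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold, ParameterGrid

__all__ = [
    "DEFAULT_RFR_GRID",
    "CVSpec",
    "SplitSpec",
    "EvalMetrics",
    "SLRResult",
    "RFRResult",
    "split_train_test",
    "fit_slr",
    "fit_rfr_cv",
    "compute_metrics",
    "evaluate",
]

#: Default hyperparameter grid for the random-forest search: tree counts
#: 10..260 by 50, depths 2..20 by 2, minimum split sizes 2..12 by 2
#: (6 x 10 x 6 = 360 combinations).  "10 to 300 by 50" does not land on
#: 300, so the sequence stops at 260; append 300 to the list to widen it.
DEFAULT_RFR_GRID: dict[str, list[int]] = {
    "n_estimators": list(range(10, 301, 50)),
    "max_depth": list(range(2, 21, 2)),
    "min_samples_split": list(range(2, 13, 2)),
}


@dataclass(frozen=True)
class CVSpec:
    """Cross-validation layout: seeded, shuffled K-fold."""

    folds: int = 5
    seed: int = 0

    def kfold(self) -> KFold:
        return KFold(n_splits=self.folds, shuffle=True, random_state=self.seed)


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split specification."""

    train_fraction: float = 0.7
    seed: int = 0
    stratify_by: str | None = "zone"

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly between 0 and 1")


@dataclass(frozen=True)
class EvalMetrics:
    """R^2, RMSE (target units), RE (%) and the sample count."""

    r2: float
    rmse: float
    re: float
    n: int


def compute_metrics(observed, estimated) -> EvalMetrics:
    """Metrics between observed and estimated values.

    RMSE = sqrt(mean((E - O)^2)); RE = 100 * RMSE / mean(O);
    R^2 = 1 - SS_res / SS_tot.
    """
    o = np.asarray(observed, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if o.size == 0:
        raise ValueError("cannot evaluate on empty data")
    o_bar = o.mean()
    if o_bar == 0:
        raise ValueError("RE undefined: mean of observed values is zero")
    rmse = float(np.sqrt(np.mean((e - o) ** 2)))
    ss_tot = float(np.sum((o - o_bar) ** 2))
    r2 = 1.0 - float(np.sum((e - o) ** 2)) / ss_tot if ss_tot > 0 else float("nan")
    return EvalMetrics(r2=r2, rmse=rmse, re=100.0 * rmse / abs(o_bar), n=o.size)


def evaluate(model, data: pd.DataFrame, target: str) -> EvalMetrics:
    """Evaluate any fitted result object exposing ``predict(DataFrame)``."""
    if len(data) == 0:
        raise ValueError("cannot evaluate on empty data")
    return compute_metrics(data[target].to_numpy(float), model.predict(data))


def split_train_test(
    feature_table: pd.DataFrame, split_spec: SplitSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive 70/30 partition with train = floor(f * n).

    With zone stratification each zone contributes floor(f * n_zone) rows,
    topped up (largest fractional remainder first) until the overall floor
    is met; row order within the partitions is randomized by the seed.
    """
    n = len(feature_table)
    if n < 10:
        raise ValueError("need at least 10 rows to split")
    spec = split_spec
    rng = np.random.default_rng(spec.seed)
    n_train = int(np.floor(spec.train_fraction * n))

    if spec.stratify_by:
        groups = feature_table.groupby(spec.stratify_by, sort=True).indices
        take: dict = {}
        remainders = []
        total = 0
        for key, idx in groups.items():
            k = int(np.floor(spec.train_fraction * len(idx)))
            take[key] = k
            total += k
            remainders.append((spec.train_fraction * len(idx) - k, key))
        remainders.sort(reverse=True)
        i = 0
        while total < n_train and i < len(remainders):
            _, key = remainders[i]
            if take[key] < len(groups[key]):
                take[key] += 1
                total += 1
            i += 1
        train_pos: list[int] = []
        for key, idx in groups.items():
            perm = rng.permutation(len(idx))
            train_pos.extend(np.asarray(idx)[perm[: take[key]]])
        train_mask = np.zeros(n, dtype=bool)
        train_mask[train_pos] = True
    else:
        perm = rng.permutation(n)
        train_mask = np.zeros(n, dtype=bool)
        train_mask[perm[:n_train]] = True

    train = feature_table.iloc[np.where(train_mask)[0]].reset_index(drop=True)
    test = feature_table.iloc[np.where(~train_mask)[0]].reset_index(drop=True)
    return train, test


# --- simple linear regression baseline --------------------------------------

@dataclass
class SLRResult:
    """Fitted single-predictor ordinary-least-squares baseline."""

    predictor: str
    target: str
    slope: float
    intercept: float
    r2: float  # train coefficient of determination
    n: int

    def predict(self, data) -> np.ndarray:
        x = (
            data[self.predictor].to_numpy(float)
            if isinstance(data, pd.DataFrame)
            else np.asarray(data, dtype=float)
        )
        return self.intercept + self.slope * x

    def evaluate(self, data: pd.DataFrame) -> EvalMetrics:
        return evaluate(self, data, self.target)

    def summary(self) -> str:
        return (
            f"SLR  {self.target} ~ {self.predictor}   (n = {self.n})\n"
            f"  slope     {self.slope:12.6g}\n"
            f"  intercept {self.intercept:12.6g}\n"
            f"  train R2  {self.r2:12.4f}"
        )


def fit_slr(train: pd.DataFrame, predictor: str = "NDRE", target: str = "NNI") -> SLRResult:
    """Ordinary least squares of the target on one predictor."""
    if len(train) < 3:
        raise ValueError("SLR needs at least 3 training rows")
    x = train[predictor].to_numpy(float)
    y = train[target].to_numpy(float)
    if np.std(x) == 0:
        raise ValueError(f"predictor {predictor!r} has zero variance")
    fit = _stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    return SLRResult(
        predictor=predictor,
        target=target,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=r2,
        n=len(train),
    )


# --- random forest with grid-search cross-validation ------------------------

@dataclass
class RFRResult:
    """Tuned random-forest regressor refit on the full training set."""

    predictors: list[str]
    target: str
    best_params: dict
    cv_metrics: EvalMetrics  # mean of the per-fold validation metrics
    model: RandomForestRegressor = field(repr=False)
    cv_curve: pd.DataFrame = field(repr=False)  # one row per grid point

    @property
    def importances(self) -> pd.Series:
        """Impurity-based (mean decrease in impurity) importances."""
        return pd.Series(
            self.model.feature_importances_, index=self.predictors, name="importance"
        )

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        return self.model.predict(data[self.predictors].to_numpy(float))

    def evaluate(self, data: pd.DataFrame) -> EvalMetrics:
        return evaluate(self, data, self.target)

    def summary(self) -> str:
        imp = self.importances.sort_values(ascending=False)
        lines = [
            f"RFR  {self.target} ~ {' + '.join(self.predictors)}",
            f"  best params  {self.best_params}",
            f"  CV R2 {self.cv_metrics.r2:.4f}  RMSE {self.cv_metrics.rmse:.4f}"
            f"  RE {self.cv_metrics.re:.2f}%",
            "  importances:",
        ]
        lines += [f"    {k:6s} {v:8.4f}" for k, v in imp.items()]
        return "\n".join(lines)


def _cv_metrics_for_params(
    X: np.ndarray,
    y: np.ndarray,
    params: Mapping,
    cv_spec: CVSpec,
    rf_seed: int,
) -> EvalMetrics:
    r2s, rmses, res = [], [], []
    for tr_idx, va_idx in cv_spec.kfold().split(X):
        rf = RandomForestRegressor(random_state=rf_seed, n_jobs=1, **params)
        rf.fit(X[tr_idx], y[tr_idx])
        m = compute_metrics(y[va_idx], rf.predict(X[va_idx]))
        r2s.append(m.r2)
        rmses.append(m.rmse)
        res.append(m.re)
    return EvalMetrics(
        r2=float(np.mean(r2s)),
        rmse=float(np.mean(rmses)),
        re=float(np.mean(res)),
        n=len(y),
    )


def fit_rfr_cv(
    train: pd.DataFrame,
    predictors: Sequence[str],
    target: str,
    grid: Mapping[str, Sequence[int]] | None = None,
    cv_spec: CVSpec | None = None,
) -> tuple[RFRResult, EvalMetrics]:
    """Exhaustive grid search scored by mean cross-validated R^2.

    Every grid point is evaluated with the same seeded K-fold layout; the
    winner (ties: first in grid order) is refit on the full training set.
    Returns the result object and its mean CV metrics.
    """
    predictors = list(predictors)
    if not predictors:
        raise ValueError("predictors must be non-empty")
    grid = dict(grid) if grid is not None else DEFAULT_RFR_GRID
    for key, values in grid.items():
        if len(values) == 0:
            raise ValueError(f"empty candidate list for grid key {key!r}")
    cv_spec = cv_spec or CVSpec()
    if len(train) < 2 * cv_spec.folds:
        raise ValueError("training set too small for the requested folds")

    X = train[predictors].to_numpy(float)
    y = train[target].to_numpy(float)
    rf_seed = cv_spec.seed

    best: tuple[float, dict, EvalMetrics] | None = None
    curve_rows = []
    for params in ParameterGrid(grid):
        m = _cv_metrics_for_params(X, y, params, cv_spec, rf_seed)
        curve_rows.append({**params, "cv_r2": m.r2, "cv_rmse": m.rmse, "cv_re": m.re})
        if best is None or m.r2 > best[0]:
            best = (m.r2, dict(params), m)
    assert best is not None
    _, best_params, cv_metrics = best

    model = RandomForestRegressor(random_state=rf_seed, n_jobs=1, **best_params)
    model.fit(X, y)
    result = RFRResult(
        predictors=predictors,
        target=target,
        best_params=best_params,
        cv_metrics=cv_metrics,
        model=model,
        cv_curve=pd.DataFrame(curve_rows),
    )
    return result, cv_metrics
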