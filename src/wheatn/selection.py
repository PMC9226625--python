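"""Variable-selection strategies for nitrogen-status models.

Two strategies are implemented, each run per (zone, target) pair with NDRE
always retained as a fixed predictor:

PCC (Pearson-correlation two-step rule)
    The 12 non-NDRE predictors are partitioned into three groups —
    temperature-related (GDD, RAD, Tmean, Tmin, Tmax), water-related
    (PPT, SDI, AWDR, HU) and management (SD, SR, BN).  Within each group the
    first pick is the member with the largest |r| against the target; the
    second pick is, among members whose |r| with the first pick is strictly
    below the threshold (0.5), the one with the largest |r| against the
    target.  A group may thus contribute one or two variables.

VIRRFR (random-forest importance forward selection)
    A random-forest regressor tuned on all 13 predictors provides an
    impurity-importance ranking; prefixes of that ranking of length
    1..13 are scored by K-fold cross-validated R^2 (RMSE as tiebreaker,
    then fewer variables) and the best prefix is returned.

Both selectors operate on the training partition only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .indices import PREDICTORS, TARGETS
from . import modeling as _modeling

__all__ = [
    "VariableGroup",
    "DEFAULT_GROUPS",
    "PCC_THRESHOLD",
    "SelectionResult",
    "pcc_select",
    "virrfr_select",
    "compare_strategies",
    "correlation_matrix",
]

PCC_THRESHOLD = 0.5


@dataclass(frozen=True)
class VariableGroup:
    """A named, ordered group of candidate predictors."""

    name: str
    members: tuple[str, ...]


#: The three predictor groups; together they partition the 12 non-NDRE
#: candidates.  Member order is the declared tie-break order.
DEFAULT_GROUPS: tuple[VariableGroup, ...] = (
    VariableGroup("temperature", ("GDD", "RAD", "Tmean", "Tmin", "Tmax")),
    VariableGroup("water", ("PPT", "SDI", "AWDR", "HU")),
    VariableGroup("management", ("SD", "SR", "BN")),
)


@dataclass
class SelectionResult:
    """Outcome of one selection run for a (zone, target) pair."""

    strategy: str  # "PCC" | "VIRRFR"
    zone: str
    target: str
    selected: list[str]  # ordered, always starts with NDRE
    diagnostics: pd.DataFrame

    def __post_init__(self) -> None:
        if "NDRE" not in self.selected:
            raise ValueError("selected set must contain NDRE")


def _safe_pearson(x: np.ndarray, y: np.ndarray, name: str) -> tuple[float, float]:
    """Pearson r and two-sided p; a constant column counts as r = 0."""
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn(
            f"constant column {name!r}: correlation undefined, treated as 0",
            stacklevel=3,
        )
        return 0.0, 1.0
    r, p = _stats.pearsonr(x, y)
    return float(r), float(p)


def correlation_matrix(table: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Pairwise Pearson correlations with two-sided p-value stars.

    Reporting aid mirroring the usual correlation-heatmap figure; selection
    itself uses only correlation magnitudes.
    """
    rows = []
    for a in columns:
        for b in columns:
            r, p = _safe_pearson(
                table[a].to_numpy(float), table[b].to_numpy(float), a
            )
            stars = "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
            rows.append({"var_a": a, "var_b": b, "r": r, "p": p, "stars": stars})
    return pd.DataFrame(rows)


def pcc_select(
    feature_table: pd.DataFrame,
    target: str,
    groups: Sequence[VariableGroup] = DEFAULT_GROUPS,
    threshold: float = PCC_THRESHOLD,
    *,
    zone: str = "",
) -> SelectionResult:
    """Two-step Pearson-correlation selection (up to 2 picks per group).

    Deterministic: ties in |r| are broken by the group's declared member
    order.  Raises ``ValueError`` on fewer than 3 rows or missing columns.
    """
    if len(feature_table) < 3:
        raise ValueError("PCC selection needs at least 3 rows")
    if target not in feature_table.columns:
        raise ValueError(f"target column {target!r} missing")
    y = feature_table[target].to_numpy(float)

    selected = ["NDRE"]
    diag_rows = []
    for group in groups:
        missing = [m for m in group.members if m not in feature_table.columns]
        if missing:
            raise ValueError(f"group {group.name!r} members missing: {missing}")
        r_target = {}
        for m in group.members:
            r, p = _safe_pearson(feature_table[m].to_numpy(float), y, m)
            r_target[m] = r
            diag_rows.append(
                {"group": group.name, "variable": m, "r_target": r, "p_target": p,
                 "step": 0, "picked": False}
            )
        # step 1: max |r| with the target (first-listed member wins ties)
        first = max(group.members, key=lambda m: abs(r_target[m]))
        selected.append(first)
        # step 2: among members weakly correlated with the first pick,
        # max |r| with the target; omitted when none qualifies
        second = None
        best = -1.0
        x_first = feature_table[first].to_numpy(float)
        for m in group.members:
            if m == first:
                continue
            r_first, _ = _safe_pearson(feature_table[m].to_numpy(float), x_first, m)
            qualifies = abs(r_first) < threshold
            diag_rows.append(
                {"group": group.name, "variable": m, "r_target": r_target[m],
                 "p_target": np.nan, "step": 2, "picked": False,
                 "r_with_first": r_first, "qualifies": qualifies}
            )
            if qualifies and abs(r_target[m]) > best:
                best = abs(r_target[m])
                second = m
        if second is not None:
            selected.append(second)
        for row in diag_rows:
            if row["group"] == group.name and row["variable"] in (first, second):
                row["picked"] = True

    return SelectionResult(
        strategy="PCC",
        zone=zone,
        target=target,
        selected=selected,
        diagnostics=pd.DataFrame(diag_rows),
    )


def virrfr_select(
    feature_table: pd.DataFrame,
    target: str,
    cv_spec: "_modeling.CVSpec | None" = None,
    rfr_grid: "Mapping[str, Sequence[int]] | None" = None,
    seed: int = 0,
    *,
    zone: str = "",
    predictors: Sequence[str] = tuple(PREDICTORS),
) -> SelectionResult:
    """Random-forest importance ranking with forward prefix evaluation.

    Tunes a forest on all candidate predictors, ranks them by impurity
    importance, scores every top-k prefix by cross-validated R^2 (RMSE
    tiebreaker, then fewer variables) and returns the winning prefix.
    Reproducible given (data, grid, folds, seed).
    """
    if len(predictors) < 2:
        raise ValueError("VIRRFR needs at least 2 candidate predictors")
    y = feature_table[target].to_numpy(float)
    if np.std(y) == 0:
        raise ValueError(f"target {target!r} has zero variance")
    cv_spec = cv_spec or _modeling.CVSpec(folds=5, seed=seed)

    ranking = virrfr_rank(feature_table, target, rfr_grid, seed, predictors=predictors)
    # NDRE is the protocol's fixed predictor: only prefixes containing it are
    # eligible, which keeps the selected set an exact prefix of the ranking.
    min_k = ranking.index("NDRE") + 1 if "NDRE" in ranking else 1
    curve = []
    best_k, best_key = min_k, None
    for k in range(1, len(ranking) + 1):
        prefix = ranking[:k]
        _, cv = _modeling.fit_rfr_cv(
            feature_table, prefix, target, grid=rfr_grid, cv_spec=cv_spec
        )
        curve.append(
            {"k": k, "variable_added": ranking[k - 1], "cv_r2": cv.r2,
             "cv_rmse": cv.rmse, "cv_re": cv.re}
        )
        key = (round(cv.r2, 12), -round(cv.rmse, 12), -k)
        if k >= min_k and (best_key is None or key > best_key):
            best_key, best_k = key, k

    selected = list(ranking[:best_k])
    return SelectionResult(
        strategy="VIRRFR",
        zone=zone,
        target=target,
        selected=selected,
        diagnostics=pd.DataFrame(curve),
    )


def virrfr_rank(
    feature_table: pd.DataFrame,
    target: str,
    rfr_grid: "Mapping[str, Sequence[int]] | None" = None,
    seed: int = 0,
    *,
    predictors: Sequence[str] = tuple(PREDICTORS),
) -> list[str]:
    """Impurity-importance ranking of the candidate predictors (step 1)."""
    cv_spec = _modeling.CVSpec(folds=5, seed=seed)
    result, _ = _modeling.fit_rfr_cv(
        feature_table, list(predictors), target, grid=rfr_grid, cv_spec=cv_spec
    )
    imp = result.importances
    order = np.argsort(-imp.to_numpy())  # stable sort: ties keep column order
    return [imp.index[i] for i in order]


def compare_strategies(
    results: Mapping[str, Mapping[str, float]]
) -> pd.DataFrame:
    """Relative metrics across model entries sharing one (zone, target).

    ``results`` maps an entry label (e.g. "PCC", "VIRRFR", "full") to its
    metrics dict with keys ``r2``, ``rmse``, ``re`` and ``n_vars``.  Each
    metric is divided by its maximum across entries, yielding the relative
    R^2, RMSE, RE and number of variables (all in (0, 1]).
    """
    df = pd.DataFrame(results).T[["r2", "rmse", "re", "n_vars"]]
    rel = df / df.max(axis=0)
    rel.columns = ["RR2", "RRMSE", "RRE", "RN"]
    return rel
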