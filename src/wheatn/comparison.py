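"""Multi-source data-combination experiment.

How much do climate (C) and management (M) data add to a canopy vegetation
index when estimating crop N status?  Four nested predictor sets are
compared per (zone, target): NDRE alone, NDRE+C, NDRE+M and NDRE+C+M.  All
four are fitted with the same protocol on the same train/test partition,
and the change in test RMSE relative to the NDRE-only model is

    dRMSE (%) = 100 * (RMSE_multi-source - RMSE_NDRE) / RMSE_NDRE

Negative dRMSE means the extra source improved the model; reports also
print the magnitude labelled as a "decrease" for improvements.  Variable
importances of the full (NDRE+C+M) model attribute the gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import modeling as _modeling
from .indices import CLIMATE_PREDICTORS, MANAGEMENT_PREDICTORS
from .selection import SelectionResult

__all__ = [
    "COMBO_LABELS",
    "DEFAULT_COMBO_GRID",
    "ComboModelSpec",
    "ComboReport",
    "compute_drmse",
    "build_combos",
    "run_combo_experiment",
    "importance_profile",
    "zone_subset",
]

COMBO_LABELS = ("NDRE", "NDRE+C", "NDRE+M", "NDRE+C+M")

#: Small hyperparameter grid used by default for the combination experiment,
#: where many forests are trained on identical partitions and a full sweep
#: adds cost without changing the ranking of the combos (see docs/methods.md).
DEFAULT_COMBO_GRID: dict[str, list] = {
    "n_estimators": [110],
    "max_depth": [6, 14],
    "min_samples_split": [2, 8],
}


@dataclass(frozen=True)
class ComboModelSpec:
    """Model protocol for the combination experiment."""

    grid: Mapping[str, Sequence] = field(
        default_factory=lambda: dict(DEFAULT_COMBO_GRID)
    )
    folds: int = 5
    train_fraction: float = 0.7
    use_all_variables: bool = False  # combos from all 13 instead of selected


def compute_drmse(rmse_multi: float, rmse_ndre: float) -> float:
    """Relative change (%) of a multi-source RMSE versus the NDRE-only RMSE.

    Sign-faithful: improvement is negative.
    """
    if rmse_ndre <= 0:
        raise ValueError("reference RMSE must be positive")
    return 100.0 * (rmse_multi - rmse_ndre) / rmse_ndre


def zone_subset(feature_table: pd.DataFrame, zone: str) -> pd.DataFrame:
    """Rows of one zone, or the pooled table for 'AZ1+2'."""
    if zone == "AZ1+2":
        return feature_table
    sub = feature_table[feature_table["zone"] == zone]
    if sub.empty:
        raise ValueError(f"no rows for zone {zone!r}")
    return sub


def build_combos(
    selected: Sequence[str], *, all_variables: bool = False
) -> dict[str, list[str]]:
    """The four nested predictor sets from a selected-variable list.

    Climate members of the selection populate the +C combos, management
    members the +M combos; NDRE is present in every combo.  The sets nest:
    NDRE < NDRE+C < NDRE+C+M and NDRE < NDRE+M < NDRE+C+M.
    """
    pool = (
        ["NDRE"] + CLIMATE_PREDICTORS + MANAGEMENT_PREDICTORS
        if all_variables
        else list(selected)
    )
    climate = [v for v in pool if v in CLIMATE_PREDICTORS]
    management = [v for v in pool if v in MANAGEMENT_PREDICTORS]
    combos = {
        "NDRE": ["NDRE"],
        "NDRE+C": ["NDRE"] + climate,
        "NDRE+M": ["NDRE"] + management,
        "NDRE+C+M": ["NDRE"] + climate + management,
    }
    for label, preds in combos.items():
        assert preds, f"combo {label} has no predictors"
    return combos


@dataclass
class ComboReport:
    """Per-combo test metrics and dRMSE for one (zone, target) pair."""

    zone: str
    target: str
    seed: int
    combos: pd.DataFrame  # label, n_vars, test_r2, test_rmse, test_re, drmse_pct
    importances: pd.Series  # full-combo impurity importances, descending
    slr_test: _modeling.EvalMetrics  # NDRE-only linear baseline on the test set

    def summary(self) -> str:
        lines = [f"Combination experiment  zone={self.zone}  target={self.target}"]
        lines.append(
            f"  SLR(NDRE) baseline: test R2 {self.slr_test.r2:.3f}, "
            f"RMSE {self.slr_test.rmse:.3f}, RE {self.slr_test.re:.1f}%"
        )
        for _, row in self.combos.iterrows():
            d = row["drmse_pct"]
            note = f"RMSE decrease {abs(d):.1f}%" if d < 0 else f"dRMSE +{d:.1f}%"
            lines.append(
                f"  {row['label']:9s} R2 {row['test_r2']:.3f} "
                f"RMSE {row['test_rmse']:.3f}  {note}"
            )
        return "\n".join(lines)


def run_combo_experiment(
    feature_table: pd.DataFrame,
    zone: str,
    target: str,
    selection_result: SelectionResult,
    model_spec: ComboModelSpec | None = None,
    seed: int = 0,
) -> ComboReport:
    """Fit the four source combinations and report dRMSE versus NDRE alone.

    One 70/30 split (stratified by zone when pooled) is made from ``seed``
    and shared across all four combos so that their dRMSE differences do not
    include split noise.
    """
    spec = model_spec or ComboModelSpec()
    table = zone_subset(feature_table, zone)
    split = _modeling.SplitSpec(
        train_fraction=spec.train_fraction,
        seed=seed,
        stratify_by="zone" if zone == "AZ1+2" else None,
    )
    train, test = _modeling.split_train_test(table, split)
    cv_spec = _modeling.CVSpec(folds=spec.folds, seed=seed)

    combos = build_combos(
        selection_result.selected, all_variables=spec.use_all_variables
    )
    rows = []
    full_importances: pd.Series | None = None
    rmse_ndre: float | None = None
    for label in COMBO_LABELS:
        preds = combos[label]
        result, _ = _modeling.fit_rfr_cv(
            train, preds, target, grid=spec.grid, cv_spec=cv_spec
        )
        m = result.evaluate(test)
        if label == "NDRE":
            rmse_ndre = m.rmse
        assert rmse_ndre is not None
        rows.append(
            {
                "label": label,
                "n_vars": len(preds),
                "predictors": "+".join(preds),
                "test_r2": m.r2,
                "test_rmse": m.rmse,
                "test_re": m.re,
                "drmse_pct": compute_drmse(m.rmse, rmse_ndre),
            }
        )
        if label == "NDRE+C+M":
            full_importances = importance_profile(result)

    slr = _modeling.fit_slr(train, predictor="NDRE", target=target)
    assert full_importances is not None
    return ComboReport(
        zone=zone,
        target=target,
        seed=seed,
        combos=pd.DataFrame(rows),
        importances=full_importances,
        slr_test=slr.evaluate(test),
    )


def importance_profile(fitted) -> pd.Series:
    """Descending impurity-importance profile of a fitted forest.

    Accepts an :class:`wheatn.modeling.RFRResult`; importances are
    non-negative and sum to 1.
    """
    try:
        imp = fitted.importances
    except Exception as exc:  # unfitted or foreign object
        raise ValueError("model must be a fitted RFRResult") from exc
    return imp.sort_values(ascending=False)
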