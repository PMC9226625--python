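"""End-to-end orchestration of the nitrogen-status analysis.

``run_all`` executes the whole workflow for each requested zone set (AZ1,
AZ2, pooled AZ1+2) and target (AGB, PNU, NNI):

1. simulate the two-zone study (or a replicate-scaled version of it),
2. derive seasonal climate features and build the 13-predictor table,
3. fit the NDRE-only linear baseline,
4. run both variable-selection strategies on the training partition,
5. tune and cross-validate random forests on the full and selected
   variable sets, with relative-metric comparison of the strategies,
6. run the multi-source combination experiment with variable importances.

Every stage writes a CSV report into the output directory; a
machine-readable ``summary.json`` and a provenance log complete the run.
The whole run is a pure function of the configuration (byte-identical
summary for a fixed seed).
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import climate as _climate
from . import comparison as _comparison
from . import indices as _indices
from . import modeling as _modeling
from . import selection as _selection
from . import synthetic as _synthetic
from .config import RunConfig, save_config

__all__ = ["run_all"]


def _stage_seed(root: int, stage: int) -> int:
    return int(np.random.SeedSequence((root, 101, stage)).generate_state(1)[0] % 2**31)


def _scaled_designs(scale: float) -> list[_synthetic.ExperimentDesign]:
    designs = _synthetic.default_designs()
    if scale >= 1.0:
        return designs
    return [
        dataclasses.replace(d, replicates=max(1, math.ceil(d.replicates * scale)))
        for d in designs
    ]


def _metrics_dict(m: _modeling.EvalMetrics) -> dict:
    return {"r2": round(m.r2, 6), "rmse": round(m.rmse, 6), "re": round(m.re, 6),
            "n": int(m.n)}


def run_all(config: RunConfig) -> Path:
    """Run the full pipeline; returns the report directory.

    Any stage failure aborts with a stage-tagged exception message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    summary: dict = {"seed": config.seed, "zones": list(config.zones),
                     "targets": list(config.targets)}
    stage = "simulate"
    try:
        # 1. synthetic study ------------------------------------------------
        sim_seed = _stage_seed(config.seed, 1)
        log(f"[simulate] root seed {config.seed}, stage seed {sim_seed}, "
            f"replicate_scale {config.replicate_scale}")
        obs_frames, wx_frames = [], []
        for k, design in enumerate(_scaled_designs(config.replicate_scale)):
            sub_seed = int(
                np.random.SeedSequence((sim_seed, 37, k)).generate_state(1)[0] % 2**31
            )
            o, w = _synthetic.generate_plots(
                design,
                _synthetic.DEFAULT_ZONE_CONFIGS[design.zone_id],
                _synthetic.DEFAULT_CROP_PARAMS[design.zone_id],
                sub_seed,
            )
            obs_frames.append(o)
            wx_frames.append(w)
        observations = pd.concat(obs_frames, ignore_index=True)
        weather = pd.concat(wx_frames, ignore_index=True)
        _synthetic.write_observations_csv(observations, out / "observations.csv")
        _synthetic.write_weather_csv(weather, out / "weather.csv")
        summary["n_observations"] = int(len(observations))

        # 2. features -------------------------------------------------------
        stage = "features"
        climate_feats = _climate.climate_feature_table(weather)
        climate_feats.to_csv(out / "climate_features.csv", index=False)
        table = _indices.build_feature_table(observations, climate_feats)
        table.to_csv(out / "feature_table.csv", index=False)
        summary["n_predictors"] = len(_indices.PREDICTORS)

        split_seed = _stage_seed(config.seed, 2)
        cv_spec = _modeling.CVSpec(folds=config.folds, seed=split_seed)
        slr_rows, sel_rows, model_rows, relative_rows = [], [], [], []
        combo_rows, importance_rows = [], []
        summary["models"] = {}

        for zone in config.zones:
            ztab = _comparison.zone_subset(table, zone)
            split = _modeling.SplitSpec(
                train_fraction=config.train_fraction,
                seed=split_seed,
                stratify_by="zone" if zone == "AZ1+2" else None,
            )
            train, test = _modeling.split_train_test(ztab, split)
            log(f"[split] zone {zone}: {len(train)} train / {len(test)} test "
                f"(seed {split_seed})")

            for target in config.targets:
                zkey = f"{zone}/{target}"
                entry: dict = {}

                # 3. SLR baseline ------------------------------------------
                stage = f"slr:{zkey}"
                slr = _modeling.fit_slr(train, "NDRE", target)
                slr_test = slr.evaluate(test)
                slr_rows.append({"zone": zone, "target": target,
                                 "slope": slr.slope, "intercept": slr.intercept,
                                 "train_r2": slr.r2, **_metrics_dict(slr_test)})
                entry["slr_test"] = _metrics_dict(slr_test)

                # 4. variable selection ------------------------------------
                stage = f"select:{zkey}"
                variable_sets: dict[str, list[str]] = {
                    "full": list(_indices.PREDICTORS)
                }
                pcc_result = None
                if config.selection_strategy in ("pcc", "both"):
                    pcc_result = _selection.pcc_select(train, target, zone=zone)
                    variable_sets["PCC"] = pcc_result.selected
                    for rank, v in enumerate(pcc_result.selected, 1):
                        sel_rows.append({"strategy": "PCC", "zone": zone,
                                         "target": target, "rank": rank,
                                         "variable": v})
                if config.selection_strategy in ("virrfr", "both"):
                    vir = _selection.virrfr_select(
                        train, target, cv_spec, config.rfr_grid, split_seed,
                        zone=zone,
                    )
                    variable_sets["VIRRFR"] = vir.selected
                    for rank, v in enumerate(vir.selected, 1):
                        sel_rows.append({"strategy": "VIRRFR", "zone": zone,
                                         "target": target, "rank": rank,
                                         "variable": v})
                log(f"[select] {zkey}: " + "; ".join(
                    f"{k}={'+'.join(v)}" for k, v in variable_sets.items()))

                # 5. RFR models + strategy comparison ----------------------
                stage = f"fit:{zkey}"
                strat_metrics: dict[str, dict[str, float]] = {}
                for set_name, preds in variable_sets.items():
                    result, cv = _modeling.fit_rfr_cv(
                        train, preds, target, grid=config.rfr_grid, cv_spec=cv_spec
                    )
                    rfr_test = result.evaluate(test)
                    model_rows.append({
                        "zone": zone, "target": target, "variable_set": set_name,
                        "n_vars": len(preds), "best_params": json.dumps(
                            result.best_params, sort_keys=True),
                        "cv_r2": cv.r2, "cv_rmse": cv.rmse, "cv_re": cv.re,
                        "test_r2": rfr_test.r2, "test_rmse": rfr_test.rmse,
                        "test_re": rfr_test.re,
                    })
                    strat_metrics[set_name] = {"r2": cv.r2, "rmse": cv.rmse,
                                               "re": cv.re, "n_vars": len(preds)}
                    entry.setdefault("rfr_test", {})[set_name] = _metrics_dict(rfr_test)
                rel = _selection.compare_strategies(strat_metrics)
                for set_name, row in rel.iterrows():
                    relative_rows.append({"zone": zone, "target": target,
                                          "variable_set": set_name,
                                          **row.round(6).to_dict()})

                # 6. combinations + importances ----------------------------
                stage = f"compare:{zkey}"
                sel_for_combo = (
                    pcc_result
                    if pcc_result is not None
                    else _selection.SelectionResult(
                        "PCC", zone, target, list(_indices.PREDICTORS),
                        pd.DataFrame(),
                    )
                )
                spec = _comparison.ComboModelSpec(
                    grid=config.rfr_grid,
                    folds=config.folds,
                    train_fraction=config.train_fraction,
                    use_all_variables=config.use_all_variables,
                )
                report = _comparison.run_combo_experiment(
                    ztab, zone, target, sel_for_combo, spec, seed=split_seed
                )
                for _, row in report.combos.iterrows():
                    combo_rows.append({"zone": zone, "target": target,
                                       **row.to_dict()})
                for rank, (var, imp) in enumerate(report.importances.items(), 1):
                    importance_rows.append({"zone": zone, "target": target,
                                            "rank": rank, "variable": var,
                                            "importance": imp})
                entry["combos"] = {
                    row["label"]: {"test_rmse": round(row["test_rmse"], 6),
                                   "drmse_pct": round(row["drmse_pct"], 6)}
                    for _, row in report.combos.iterrows()
                }
                summary["models"][zkey] = entry
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    pd.DataFrame(slr_rows).to_csv(out / "slr_models.csv", index=False)
    pd.DataFrame(sel_rows).to_csv(out / "selection.csv", index=False)
    pd.DataFrame(model_rows).to_csv(out / "rfr_models.csv", index=False)
    pd.DataFrame(relative_rows).to_csv(out / "strategy_comparison.csv", index=False)
    pd.DataFrame(combo_rows).to_csv(out / "combo_report.csv", index=False)
    pd.DataFrame(importance_rows).to_csv(out / "importances.csv", index=False)
    save_config(config, out / "config.yaml")
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
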