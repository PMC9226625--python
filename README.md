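# wheatn

Estimating winter-wheat nitrogen status from multi-source data across
agro-ecological zones.

Deciding how much nitrogen a wheat crop needs mid-season requires knowing
its current N status. The standard indicators — aboveground biomass (AGB,
t ha⁻¹), plant N uptake (PNU, kg N ha⁻¹) and the nitrogen nutrition index
(NNI) — are destructive to measure, so they are usually estimated from an
active canopy sensor via the normalized difference red edge index,
NDRE = (NIR₇₈₀ − RE₇₃₀)/(NIR₇₈₀ + RE₇₃₀). A single-index linear model,
however, transfers poorly between regions with different climate and
management. `wheatn` implements the full analysis that quantifies how much
seasonal climate (GDD, PPT, SDI, AWDR, T extremes, humidity, radiation)
and management data (sowing date, seeding rate, basal N) add to NDRE when
estimating N status with random-forest regression, in and across two
contrasting zones: a higher-latitude dry zone (AZ1) and a subtropical
monsoon zone (AZ2).

At its agronomic core are the critical N dilution curves
`Nc = 4.15·AGB^−0.38` (AZ1) and `Nc = 4.33·AGB^−0.45` (AZ2), which define
`NNI = N% / Nc(AGB)`, and the evaluation metrics R², RMSE and
RE = 100·RMSE/mean(observed). Multi-source benefit is measured as
`dRMSE (%) = 100·(RMSE_combo − RMSE_NDRE)/RMSE_NDRE` (negative =
improvement).

The package contains:

- `wheatn.synthetic` — a calibrated generator of the two-zone study
  (daily weather, N-rate trials, farmers' fields; 396 plots, 126:270),
  since no field data of this kind are publicly deposited;
- `wheatn.climate` — the nine seasonal climate features;
- `wheatn.indices` — NDRE, Nc, PNU, NNI and the 13-predictor feature table;
- `wheatn.selection` — two variable-selection strategies: a two-step
  Pearson-correlation rule within temperature/water/management groups
  (threshold 0.5) and random-forest-importance forward selection;
- `wheatn.modeling` — 70/30 split, NDRE-only OLS baseline, grid-search
  cross-validated random forests, metrics;
- `wheatn.comparison` — the NDRE / NDRE+C / NDRE+M / NDRE+C+M combination
  experiment with dRMSE and variable importances;
- a `wheatn` CLI (`simulate`, `features`, `select`, `fit`, `compare`,
  `run-all`) plus YAML configuration.

## Worked example

```python
from wheatn import *

obs, weather = default_study(7)                       # 396 synthetic plots
table = build_feature_table(obs, climate_feature_table(weather))
train, test = split_train_test(table, SplitSpec(seed=7, stratify_by="zone"))

sel = pcc_select(train, "NNI", zone="AZ1+2")
print("selected:", " + ".join(sel.selected))

report = run_combo_experiment(table, "AZ1+2", "NNI", sel, seed=7)
print(report.summary())
```

prints

```
selected: NDRE + Tmax + Tmin + SDI + BN + SR
Combination experiment  zone=AZ1+2  target=NNI
  SLR(NDRE) baseline: test R2 0.659, RMSE 0.229, RE 22.7%
  NDRE      R2 0.642 RMSE 0.235  dRMSE +0.0%
  NDRE+C    R2 0.658 RMSE 0.230  RMSE decrease 2.3%
  NDRE+M    R2 0.842 RMSE 0.156  RMSE decrease 33.5%
  NDRE+C+M  R2 0.860 RMSE 0.147  RMSE decrease 37.5%
```

Reading it: the correlation rule kept six of the 13 candidates (NDRE plus
two temperature, one water and two management variables). On the shared
30% test set, NDRE alone explains about 64–66% of NNI variance; adding the
selected climate variables trims the RMSE slightly, adding management
(here dominated by basal N) cuts it by a third, and the full combination
is best, reducing RMSE by 37.5% relative to NDRE alone and raising test
R² from 0.66 to 0.86. `report.importances` attributes the gain (basal N
and NDRE lead on this realization).

The same experiment for every zone set and target, with all intermediate
CSV reports and a machine-readable summary:

```sh
wheatn run-all --seed 42 --out-dir runs/demo
```

## Documentation

`docs/methods.md` describes the generating mechanism and its calibration,
the selection and modelling protocols, the numerical conventions (GDD cap
and floor, SDI of a dry season, grid endpoints), and what results on
synthetic data do and do not establish.
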