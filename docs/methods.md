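# Methods

`wheatn` implements a complete analysis pipeline for estimating winter-wheat
nitrogen status at the stem-elongation stage from multi-source data: an
active-canopy-sensor vegetation index, seasonal agro-climatic features, and
crop-management attributes, across two contrasting agro-ecological zones.
This note documents the models, the synthetic data they are exercised on,
and the numerical choices a maintainer would want to know about.

## N-status indicators

Three indicators are estimated per plot:

- **AGB** — aboveground dry biomass at sensing (t ha⁻¹).
- **PNU** — plant N uptake (kg N ha⁻¹), `PNU = AGB × N% × 10` (the factor 10
  converts t → kg and % → fraction).
- **NNI** — nitrogen nutrition index, `NNI = N% / Nc(AGB)`, where the
  critical N concentration follows a zone-specific dilution power law:
  `Nc = 4.15·AGB^−0.38` in the higher-latitude dry zone (AZ1) and
  `Nc = 4.33·AGB^−0.45` in the subtropical monsoon zone (AZ2), both in % of
  dry mass with AGB in t ha⁻¹. NNI = 1 marks optimal status, < 1 deficiency,
  > 1 luxury uptake. Pooled-zone analyses always evaluate each row against
  its own zone's curve before pooling.

The sensor signal is the normalized difference red edge index,
`NDRE = (NIR₇₈₀ − RE₇₃₀)/(NIR₇₈₀ + RE₇₃₀)`, chosen over NDVI because it
saturates less at high biomass.

## Climate features

Nine seasonal features summarize the sowing-to-sensing daily weather:
PPT (total precipitation, mm), Tmax/Tmin (extremes of the daily maxima and
minima, °C), Tmean (mean of daily midpoints, °C), GDD (growing degree days,
°C·day), SDI (Shannon diversity of daily precipitation shares ∈ [0, 1]),
AWDR = PPT × SDI (mm), HU (mean relative humidity, %), and RAD (total solar
radiation, MJ m⁻²).

Conventions where the standard definitions leave room:

- GDD uses base 0 °C with the **daily maximum capped at 30 °C**; negative
  daily contributions are floored at 0 (the usual agronomic convention —
  only the cap is part of the printed definition; `floor_daily=False`
  disables it). The cap applies *only* inside GDD, not to the seasonal Tmax.
- SDI normalizes the precipitation-share entropy by `ln(d)`, where `d`
  counts **all** calendar days in the window, rainy or not. A completely dry
  window is assigned SDI = 0 (an empty distribution carries no information;
  avoids 0/0).
- Tmean is the mean of `(tmax+tmin)/2` because daily mean temperature is not
  part of the weather schema.

## Synthetic study

No plot data from this kind of trial are publicly deposited, so the package
generates a synthetic study with the same design skeleton: 396 plots, 126 in
AZ1 (three N-rate × cultivar plot experiments plus eight farmers' fields
comparing farmer practice / regional optimum / sensor-based precision N
management) and 270 in AZ2 (two cultivar × N-rate experiments plus two
experiments pairing late sowing dates with raised seeding rates). N rates
span 0–300 kg ha⁻¹ in AZ1 and 0–360 in AZ2, with 40–50% applied as basal N.
Replicate counts (3 in AZ1 plot trials, 5 in AZ2) were fixed once so the
zone totals land exactly on 126/270.

The generating mechanism is deliberately simple — a statistical emulator,
not a crop model:

- **Weather**: daily midpoint temperature = zone sinusoid (annual mean,
  amplitude, coldest day ≈ mid-January) + Gaussian noise, split into
  tmax/tmin by a positive random diurnal range; precipitation from a
  two-state Markov chain whose stationary wet-day probability is the
  configured value, with gamma wet-day amounts; humidity and radiation are
  clipped Gaussians. AZ2 is configured wetter (≈ 350 vs ≈ 115 mm per
  season) and warmer than AZ1, reproducing the monsoon-vs-dry contrast.
- **Biomass**: Michaelis–Menten response to plant-available N supply
  (indigenous soil N + fertilizer), scaled by thermal time
  `(GDD/GDD_ref)^0.5`, seasonal water `(AWDR/AWDR_ref)^0.1`, a sowing-delay
  penalty, a mild seeding-rate power law and a cultivar multiplier, with
  multiplicative lognormal noise.
- **N status**: NNI is linear in supply around an optimum (`1 +
  luxury_slope·(S − n_opt)`), modulated by seasonal water and clipped to
  [0.32, 1.95]; plant N% is then `NNI × Nc(AGB)`, which guarantees
  deficiency at 0 N and luxury uptake at the top rates in expectation.
- **Sensing**: `NDRE = 0.46·(1 − exp(−0.012·PNU)) + ε`, ε ~ N(0, 0.07²),
  clipped to (−1, 1).

### Calibration (done once, then frozen)

Free parameters were tuned once against the descriptive statistics this
experimental design is expected to produce and then frozen in
`DEFAULT_CROP_PARAMS`; no later result feeds back into them. Achieved
moments (12-seed average) vs. targets:

| statistic | AZ1 | AZ2 | pooled |
|---|---|---|---|
| AGB mean (t/ha) | 2.68 (2.79) | 2.83 (2.66) | 2.78 (2.63) |
| AGB CV (%) | 50.4 (50.2) | 40.2 (38.5) | 43.5 (41.6) |
| PNU CV (%) | 55.4 (60.5) | 51.5 (51.0) | 52.8 (52.3) |
| NNI mean | 1.04 (1.05) | 1.04 (1.03) | 1.04 (1.04) |
| NNI CV (%) | 36.8 (33.7) | 36.3 (34.8) | 36.5 (32.4) |

All statistics sit inside the calibration envelope (means within ±20%, CVs
within ±10 points). Pushing the AZ1 PNU CV higher was possible only at the
cost of pushing the NNI CV outside its band, so this compromise was frozen.
The NDRE noise sd (0.07) was chosen so the NDRE-only linear baseline
explains roughly 50–75% of target variance — the regime in which a
vegetation index alone is informative but clearly improvable, which is the
empirical situation that motivates multi-source modelling.

### What the generator does *not* emulate

Within-field spatial variability, phenology beyond a fixed sowing→sensing
window, real inter-annual weather (each experiment-year draws an
independent season), soil processes, and measurement error structure beyond
lognormal/Gaussian noise. Passing tests therefore demonstrate that the
*pipeline* behaves correctly and that its qualitative conclusions are
recoverable when the data-generating process genuinely contains climate and
management signal — not that the same numbers would be obtained on real
field data.

## Variable selection

Twelve non-NDRE candidates are grouped as temperature-related
{GDD, RAD, Tmean, Tmin, Tmax}, water-related {PPT, SDI, AWDR, HU} and
management {SD, SR, BN}; NDRE is always retained.

- **PCC**: per group, pick the member with the largest |Pearson r| with the
  target; then, among remaining members whose |r| with the first pick is
  strictly `< 0.5`, pick the one with the largest |r| with the target
  (omitted when none qualifies). Deterministic; ties break by declared
  member order; a constant column counts as r = 0 with a warning. The same
  two-step rule is applied to the 3-member management group. Selection runs
  per (zone, target) on the training partition only, to avoid leakage.
  Correlation p-value stars are computed for reporting but never used for
  selection.
- **VIRRFR**: a random forest tuned on all 13 candidates yields an
  impurity-importance ranking; every top-k prefix (k = 1…13) is scored by
  K-fold cross-validated R² (mean over folds), with mean CV RMSE as the
  tiebreaker and then fewer variables. Only prefixes containing NDRE are
  eligible, so the selected set is simultaneously an exact prefix of the
  ranking and NDRE-containing; in practice NDRE ranks first.

Strategies are compared by relative metrics (RR², RRMSE, RRE, RN): each
metric divided by its maximum across the PCC, VIRRFR and full-variable
models for the same (zone, target).

## Modelling protocol

- 70/30 train/test split with `n_train = floor(0.7·n)` (396 → 277/119);
  pooled-zone analyses stratify by zone (per-zone floors: 88 + 189 = 277).
- Baseline: ordinary least squares of each target on NDRE alone.
- Random forest regression tuned by exhaustive grid search scored by mean
  5-fold CV R² (folds seeded and shuffled, shared across the grid; ties go
  to the first grid point). The full tuning grid is n_estimators
  {10, 60, 110, 160, 210, 260} × max_depth {2…20 step 2} ×
  min_samples_split {2…12 step 2} = 360 points; "10 to 300 by 50" does not
  land on 300, so the sequence stops at 260 — append 300 to widen it.
- Metrics: R² = 1 − SS_res/SS_tot (not squared correlation), RMSE, and
  RE = 100·RMSE/mean(observed). CV metrics are plain means of per-fold
  values. Impurity-based (MDI) importances are the default wherever
  "variable importance" is reported.

## Multi-source combination experiment

Four nested predictor sets — NDRE, NDRE+C, NDRE+M, NDRE+C+M — are built
from the PCC-selected variables (a flag switches to all 13), fitted with an
identical protocol on one shared train/test partition per (zone, target),
and compared by `dRMSE (%) = 100·(RMSE_combo − RMSE_NDRE)/RMSE_NDRE`. The
formula is implemented sign-faithfully (improvement is negative); report
text additionally prints |dRMSE| labelled "decrease" for improvements,
matching the convention of quoting decreases as positive numbers. Test-set
RMSE (not CV RMSE) feeds dRMSE.

## Problem sizes and numerical choices

- The combination experiment and the orchestrated `run_all` default to a
  reduced tuning grid (n_estimators {110} × max_depth {6, 14} ×
  min_samples_split {2, 8}): the experiment trains dozens of forests on
  identical partitions, the full 360-point sweep multiplies cost by ~50×
  on a single CPU, and on this generator it does not change the ranking of
  the four combinations. The full grid remains the default of
  `fit_rfr_cv` and is one config key away (`rfr_grid: "full"`).
- All randomness flows from explicit integer seeds; nested streams are
  derived with `numpy.random.SeedSequence`, so every stage is independently
  reproducible and `run_all` is byte-identical for a fixed seed.
- Degenerate inputs fail loudly: empty weather series, zero-variance
  targets or predictors, PPT = 0 (defined SDI = 0), `NIR + RE = 0`,
  mean(observed) = 0 for RE, a reference RMSE of 0 for dRMSE.

## Known limitations

- The generator is an emulator; absolute R²/RMSE values on it are not
  comparable to field results, only orderings and magnitudes of change.
- The PCC rule inherits the instability of sample correlations near the
  0.5 threshold; on small zone subsets the second pick can flip between
  close competitors across seeds.
- VIRRFR cost grows linearly in the number of candidates times the grid
  size; with the full grid it is an overnight computation for all nine
  (zone, target) pairs.
- No spatial cross-validation: plots within an experiment share a weather
  series, so random K-fold CV is mildly optimistic about transfer to new
  site-years.
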