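"""Canopy and agronomic nitrogen-status indices.

Computes the normalized difference red edge index (NDRE), the critical N
concentration from zone-specific N dilution curves, plant N uptake (PNU)
and the nitrogen nutrition index (NNI), and assembles the plot-level
feature table used by the selection and modelling stages.

Units
-----
- aboveground biomass (AGB): t ha^-1 dry mass
- plant N concentration: % of dry mass
- PNU: kg N ha^-1 (= AGB * N% * 10, converting t->kg and %->fraction)
- NNI: dimensionless ratio actual N% / critical N%
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ZONES",
    "NC_CURVES",
    "PREDICTORS",
    "CLIMATE_PREDICTORS",
    "MANAGEMENT_PREDICTORS",
    "TARGETS",
    "KEY_COLUMNS",
    "compute_ndre",
    "critical_n_concentration",
    "compute_pnu",
    "compute_nni",
    "build_feature_table",
]

ZONES = ("AZ1", "AZ2")

#: Critical N dilution curves Nc = a * AGB^-b (% N at AGB in t/ha), one per
#: agro-ecological zone.  AZ1 is the higher-latitude dry zone, AZ2 the
#: subtropical monsoon zone; each zone has its own published curve.
NC_CURVES: Mapping[str, tuple[float, float]] = {
    "AZ1": (4.15, 0.38),
    "AZ2": (4.33, 0.45),
}

CLIMATE_PREDICTORS = ["GDD", "RAD", "Tmax", "Tmin", "Tmean", "PPT", "SDI", "AWDR", "HU"]
MANAGEMENT_PREDICTORS = ["SD", "SR", "BN"]
#: The 13 candidate predictors: the vegetation index, nine seasonal climate
#: features and three management attributes.
PREDICTORS = ["NDRE"] + CLIMATE_PREDICTORS + MANAGEMENT_PREDICTORS
TARGETS = ["AGB", "PNU", "NNI"]
KEY_COLUMNS = ["zone", "experiment", "plot", "cultivar"]


def compute_ndre(nir_780, re_730):
    """Normalized difference red edge: (NIR780 - RE730) / (NIR780 + RE730).

    Parameters are reflectances in [0, 1]; the result lies in (-1, 1).
    Accepts scalars or aligned arrays.
    """
    nir = np.asarray(nir_780, dtype=float)
    re = np.asarray(re_730, dtype=float)
    denom = nir + re
    if np.any(denom <= 0):
        raise ValueError("NDRE undefined: NIR780 + RE730 must be positive")
    out = (nir - re) / denom
    return float(out) if out.ndim == 0 else out


def critical_n_concentration(agb, zone_id: str):
    """Critical N concentration (% dry mass) at a given biomass.

    Evaluates the zone's critical N dilution power law ``Nc = a * AGB**-b``,
    the minimum plant N concentration that sustains maximum growth at
    aboveground biomass ``agb`` (t/ha).  Strictly decreasing in biomass.
    """
    if zone_id not in NC_CURVES:
        raise ValueError(f"unknown zone {zone_id!r}; expected one of {list(NC_CURVES)}")
    agb_arr = np.asarray(agb, dtype=float)
    if np.any(agb_arr <= 0):
        raise ValueError("critical N concentration requires AGB > 0")
    a, b = NC_CURVES[zone_id]
    out = a * agb_arr ** -b
    return float(out) if out.ndim == 0 else out


def compute_pnu(agb, n_conc):
    """Plant N uptake (kg N/ha) from biomass (t/ha) and N concentration (%).

    PNU = AGB * 1000 * n_conc / 100 = AGB * n_conc * 10.
    """
    agb_arr = np.asarray(agb, dtype=float)
    nc_arr = np.asarray(n_conc, dtype=float)
    if np.any(agb_arr <= 0) or np.any(nc_arr <= 0):
        raise ValueError("PNU requires positive AGB and N concentration")
    out = agb_arr * nc_arr * 10.0
    return float(out) if out.ndim == 0 else out


def compute_nni(n_conc, agb, zone_id: str):
    """Nitrogen nutrition index: actual N% over critical N% at the same AGB.

    NNI = 1 marks optimal N status, < 1 deficiency, > 1 luxury uptake.
    """
    nc_arr = np.asarray(n_conc, dtype=float)
    if np.any(nc_arr <= 0):
        raise ValueError("NNI requires positive N concentration")
    out = nc_arr / critical_n_concentration(agb, zone_id)
    return float(out) if np.ndim(out) == 0 else out


def _empty_feature_table() -> pd.DataFrame:
    return pd.DataFrame(columns=KEY_COLUMNS + PREDICTORS + TARGETS)


def build_feature_table(
    observations: pd.DataFrame, climate_features: pd.DataFrame
) -> pd.DataFrame:
    """Join plot observations to their seasonal climate features.

    Parameters
    ----------
    observations
        One row per plot: keys (zone, experiment, plot, cultivar), management
        attributes (sowing_doy, seeding_rate, basal_n), the sensor reading
        (``ndre`` or the band reflectances ``nir_780``/``re_730``), and the
        measurements ``agb`` and ``n_conc``.
    climate_features
        One row per (zone, experiment, sowing_doy) with the nine seasonal
        climate predictors in lower case (ppt, tmax, ... as produced by
        :func:`wheatn.climate.compute_climate_features`).

    Returns
    -------
    DataFrame with the key columns, the 13 candidate predictors
    (NDRE; GDD, RAD, Tmax, Tmin, Tmean, PPT, SDI, AWDR, HU; SD, SR, BN)
    and the 3 targets (AGB, PNU, NNI).

    Raises
    ------
    KeyError
        If any observation has no matching climate record; the error lists
        the offending (zone, experiment, sowing_doy) keys.
    """
    if observations.empty:
        return _empty_feature_table()

    obs = observations.copy()
    if "ndre" not in obs.columns:
        obs["ndre"] = compute_ndre(obs["nir_780"], obs["re_730"])

    join_keys = ["zone", "experiment", "sowing_doy"]
    merged = obs.merge(
        climate_features, on=join_keys, how="left", validate="many_to_one"
    )
    missing = merged["gdd"].isna()
    if missing.any():
        bad = merged.loc[missing, join_keys].drop_duplicates().to_records(index=False)
        raise KeyError(f"observations without climate features for keys: {list(bad)}")

    out = pd.DataFrame(index=merged.index)
    out["zone"] = merged["zone"]
    out["experiment"] = merged["experiment"]
    out["plot"] = merged["plot"]
    out["cultivar"] = merged["cultivar"]
    out["NDRE"] = merged["ndre"].astype(float)
    for name in CLIMATE_PREDICTORS:
        out[name] = merged[name.lower()].astype(float)
    out["SD"] = merged["sowing_doy"].astype(float)
    out["SR"] = merged["seeding_rate"].astype(float)
    out["BN"] = merged["basal_n"].astype(float)
    out["AGB"] = merged["agb"].astype(float)
    out["PNU"] = compute_pnu(merged["agb"], merged["n_conc"])
    nni = np.empty(len(merged))
    for zone in merged["zone"].unique():
        mask = (merged["zone"] == zone).to_numpy()
        nni[mask] = compute_nni(
            merged.loc[mask, "n_conc"], merged.loc[mask, "agb"], zone
        )
    out["NNI"] = nni
    return out
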