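"""Seasonal agro-climatic features over the sowing-to-sensing window.

From a daily weather series (tmax, tmin, precip, rh, rad) the module derives
the nine climate predictors used for nitrogen-status modelling:

- PPT: seasonal total precipitation (mm)
- Tmax / Tmin: extreme of the daily maxima / minima (deg C)
- Tmean: mean of the daily midpoint temperature (tmax+tmin)/2 (deg C)
- GDD: growing degree days, base 0 deg C with daily maxima capped at 30 deg C
- SDI: Shannon diversity index of daily precipitation shares in [0, 1]
- AWDR: abundant and well-distributed rainfall, PPT * SDI (mm)
- HU: mean relative humidity (%)
- RAD: seasonal total solar radiation (MJ m^-2)

Conventions chosen where the definitions leave room: negative daily GDD
contributions are floored at zero (standard agronomic practice; only the
30 deg C cap on the maximum is part of the printed definition), a dry season
(PPT = 0) has SDI = 0, and Tmean uses daily midpoints because daily mean
temperature is not part of the weather schema.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GDD_TMAX_CAP",
    "GDD_T_BASE",
    "compute_gdd",
    "compute_sdi",
    "compute_awdr",
    "compute_seasonal_aggregates",
    "compute_climate_features",
    "climate_feature_table",
]

GDD_TMAX_CAP = 30.0  # deg C, applied to the daily maximum inside GDD only
GDD_T_BASE = 0.0  # deg C


def _as_weather_frame(days) -> pd.DataFrame:
    df = pd.DataFrame(days) if not isinstance(days, pd.DataFrame) else days
    if len(df) == 0:
        raise ValueError("weather series is empty")
    return df


def compute_gdd(days, *, floor_daily: bool = True) -> float:
    """Growing degree days summed over the series.

    Each day contributes ``(min(tmax, 30) + tmin) / 2 - 0``; with
    ``floor_daily`` (the default) negative contributions count as zero.
    """
    df = _as_weather_frame(days)
    tmax = np.minimum(df["tmax"].to_numpy(float), GDD_TMAX_CAP)
    daily = (tmax + df["tmin"].to_numpy(float)) / 2.0 - GDD_T_BASE
    if floor_daily:
        daily = np.maximum(daily, 0.0)
    return float(daily.sum())


def compute_sdi(daily_precip: Sequence[float], d: int | None = None) -> float:
    """Shannon diversity index of the daily precipitation distribution.

    ``p_i`` is each day's share of seasonal precipitation; the entropy
    ``sum(-p_i ln p_i)`` is normalized by ``ln(d)`` where ``d`` is the number
    of days from sowing to sensing (all calendar days, rainy or not).
    Equal rain every day gives 1, all rain on one day gives 0, and a dry
    season is defined as 0.
    """
    p = np.asarray(daily_precip, dtype=float)
    if d is None:
        d = len(p)
    if d < 2:
        raise ValueError("SDI requires at least 2 days")
    if np.any(p < 0):
        raise ValueError("precipitation amounts must be non-negative")
    ppt = p.sum()
    if ppt == 0:
        return 0.0
    shares = p / ppt
    nz = shares[shares > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(d))


def compute_awdr(ppt: float, sdi: float) -> float:
    """Abundant and well-distributed rainfall: PPT * SDI (mm)."""
    return float(ppt) * float(sdi)


def compute_seasonal_aggregates(days) -> dict[str, float]:
    """Seasonal PPT, Tmax, Tmin, Tmean, HU and RAD from a daily series.

    No temperature cap applies here: the 30 deg C cap belongs to GDD only.
    """
    df = _as_weather_frame(days)
    tmax = df["tmax"].to_numpy(float)
    tmin = df["tmin"].to_numpy(float)
    return {
        "ppt": float(df["precip"].sum()),
        "tmax": float(tmax.max()),
        "tmin": float(tmin.min()),
        "tmean": float(((tmax + tmin) / 2.0).mean()),
        "hu": float(df["rh"].mean()),
        "rad": float(df["rad"].sum()),
    }


def compute_climate_features(days) -> dict[str, float]:
    """All nine seasonal climate features for one zone-season series."""
    df = _as_weather_frame(days)
    feats = compute_seasonal_aggregates(df)
    feats["gdd"] = compute_gdd(df)
    feats["sdi"] = compute_sdi(df["precip"].to_numpy(float), len(df))
    feats["awdr"] = compute_awdr(feats["ppt"], feats["sdi"])
    return feats


def climate_feature_table(weather: pd.DataFrame) -> pd.DataFrame:
    """Per-(zone, experiment, sowing_doy) climate features from daily weather.

    ``weather`` is the long-format daily table written by the simulator
    (columns zone, experiment, sowing_doy, date, tmax, tmin, precip, rh,
    rad).  Returns one row per series, keyed so it joins onto the
    observation table.
    """
    rows = []
    for (zone, experiment, sowing_doy), grp in weather.groupby(
        ["zone", "experiment", "sowing_doy"], sort=True
    ):
        feats = compute_climate_features(grp)
        rows.append(
            {"zone": zone, "experiment": experiment, "sowing_doy": sowing_doy, **feats}
        )
    return pd.DataFrame(rows)
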