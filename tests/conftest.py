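import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import numpy as np
import pandas as pd
import pytest

from wheatn import (
    build_feature_table,
    climate_feature_table,
    default_study,
)
from wheatn.comparison import DEFAULT_COMBO_GRID

#: Tiny single-point grid for tests that need a forest but not a search.
TINY_GRID = {"n_estimators": [60], "max_depth": [8], "min_samples_split": [2]}


@pytest.fixture(scope="session")
def study():
    """The default synthetic study at a fixed seed (observations, weather)."""
    return default_study(42)


@pytest.fixture(scope="session")
def feature_table(study):
    obs, weather = study
    return build_feature_table(obs, climate_feature_table(weather))


@pytest.fixture(scope="session")
def combo_grid():
    return dict(DEFAULT_COMBO_GRID)


def make_weather_frame(tmax, tmin, precip=None, rh=None, rad=None):
    """Hand-specified daily weather for oracle tests."""
    n = len(tmax)
    return pd.DataFrame(
        {
            "tmax": np.asarray(tmax, float),
            "tmin": np.asarray(tmin, float),
            "precip": np.zeros(n) if precip is None else np.asarray(precip, float),
            "rh": np.full(n, 60.0) if rh is None else np.asarray(rh, float),
            "rad": np.full(n, 10.0) if rad is None else np.asarray(rad, float),
        }
    )
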