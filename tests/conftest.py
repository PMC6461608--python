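"""Shared fixtures: synthetic weather, grids and cultivars.

Everything is generated programmatically with fixed seeds; nothing is
read from disk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ricegap import CultivarParameters, gen_area_grid, gen_weather
from ricegap.synthetic import SiteSpec
from ricegap.weather import COLUMNS, WeatherSeries


@pytest.fixture(scope="session")
def subtropical_weather() -> "WeatherSeries":
    """Eleven years of daily weather for a subtropical rice station."""
    site = SiteSpec("rws01", 28.0, 113.0, climate_preset="subtropical", seed=7)
    return gen_weather(site, n_years=11)


@pytest.fixture(scope="session")
def cool_weather() -> "WeatherSeries":
    site = SiteSpec("rws02", 45.0, 127.0, climate_preset="cool-temperate", seed=7)
    return gen_weather(site, n_years=11)


@pytest.fixture(scope="session")
def cultivar() -> CultivarParameters:
    return CultivarParameters()


@pytest.fixture(scope="session")
def area_grid() -> pd.DataFrame:
    """Clustered 30.3 Mha rice-area grid over a toy country."""
    return gen_area_grid((20.0, 40.0, 100.0, 122.0), cell_size=1.0,
                         n_clusters=6, total_area_mha=30.3, seed=11)


@pytest.fixture(scope="session")
def toy_country_cells(area_grid) -> pd.DataFrame:
    """Area grid with per-cell climate summaries spanning 16 distinct
    climate zones by construction (8 GDD levels x 2 aridity levels)."""
    cells = area_grid.copy()
    rng = np.random.default_rng(5)
    # smooth north-south GDD gradient across 8 bins, east-west aridity split
    lat01 = (cells["lat"] - cells["lat"].min()) / np.ptp(cells["lat"].to_numpy())
    cells["gdd"] = 7800.0 - 6200.0 * lat01 + rng.normal(0, 30.0, len(cells))
    cells["aridity"] = np.where(cells["lon"] > 111.0, 1.3, 0.65)
    cells["seasonality"] = 9.5 + rng.normal(0, 0.2, len(cells))
    return cells


def constant_weather(n_days: int = 365, tmax: float = 25.0, tmin: float = 15.0,
                     srad: float = 15.0, rain: float = 3.0,
                     latitude: float = 28.0, start: str = "2010-01-01",
                     site_id: str = "const") -> WeatherSeries:
    """Uniform synthetic series for closed-form checks."""
    dates = pd.date_range(start, periods=n_days, freq="D")
    df = pd.DataFrame({
        "date": dates,
        "tmax_C": tmax, "tmin_C": tmin, "srad_MJ_m2": srad,
        "rain_mm": rain, "wind_m_s": 2.0, "rh_pct": 75.0,
    }, columns=COLUMNS)
    return WeatherSeries(site_id, latitude, df)


def replicated_weather(base: WeatherSeries, years: range) -> WeatherSeries:
    """Repeat one station-year by calendar month-day over several years
    (leap days copy Feb 28), so every season sees identical weather."""
    src = base.data.copy()
    src["md"] = src["date"].dt.strftime("%m-%d")
    lookup = src.drop_duplicates("md").set_index("md")
    dates = pd.date_range(f"{years.start}-01-01", f"{years.stop - 1}-12-31", freq="D")
    md = dates.strftime("%m-%d").str.replace("02-29", "02-28", regex=False)
    out = lookup.loc[md].reset_index(drop=True)
    out["date"] = dates
    return WeatherSeries(base.site_id, base.latitude, out[COLUMNS])
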