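"""Synthetic generators for every external input of the analysis.

The real study drew on national weather archives, a gridded crop-area
map, county/province yield statistics and field experiments.  None of
those can ship with the package, so this module generates statistically
realistic stand-ins with *known ground truth*, which makes every
downstream stage testable by parameter or aggregate recovery:

* :func:`gen_weather` — multi-year daily weather from an annual
  temperature sinusoid with AR(1) noise, an extraterrestrial-radiation
  envelope times beta-distributed transmissivity (capped at 0.75), and
  two-state Markov rainfall occurrence with gamma amounts.  Year-level
  radiation and temperature anomalies induce realistic year-to-year
  variability in simulated potential yield (~5-10% CV).
* :func:`gen_area_grid` — clustered rice harvested area on a regular
  lat/lon grid, conserving a requested national total exactly.
* :func:`gen_admin_yields` — county yield records with a known
  province-level reporting bias, plus the true provincial yields.
* :func:`gen_phenology_obs` — phenology dates and organ biomass/LAI
  samples produced by the package's own crop simulator for a known
  cultivar, optionally with observation noise, for calibration tests.

All generators are pure functions of their spec plus an explicit seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import solar
from .crop import CultivarParameters, simulate_crop
from .weather import COLUMNS, WeatherSeries

#: climate presets: mean annual temperature (C), seasonal amplitude (C),
#: diurnal range (C), wet-day probability, mean wet-day rain (mm)
CLIMATE_PRESETS = {
    "cool-temperate": dict(tmean=6.0, amplitude=16.0, diurnal=11.0,
                           p_wet=0.28, rain_mean=6.0),
    "warm-temperate": dict(tmean=13.0, amplitude=12.5, diurnal=10.0,
                           p_wet=0.30, rain_mean=7.5),
    "subtropical": dict(tmean=18.0, amplitude=9.0, diurnal=8.5,
                        p_wet=0.38, rain_mean=9.0),
}


@dataclass
class SiteSpec:
    """Synthetic weather-station site."""

    site_id: str
    latitude: float
    longitude: float
    elevation: float = 50.0
    climate_preset: str = "subtropical"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.climate_preset not in CLIMATE_PRESETS:
            raise ValueError(
                f"unknown climate preset {self.climate_preset!r}; "
                f"choose from {sorted(CLIMATE_PRESETS)}"
            )
        if not -60.0 <= self.latitude <= 60.0:
            raise ValueError("latitude must be within +/-60 degrees for rice presets")


@dataclass
class ProvinceSpec:
    """Synthetic province for county yield statistics."""

    province_id: str
    n_counties: int = 10
    true_mean_yield: float = 6.5      # t/ha
    county_sd: float = 0.6            # t/ha
    reporting_bias: float = 1.0       # multiplicative bias on county figures

    def __post_init__(self) -> None:
        if self.n_counties < 1:
            raise ValueError("n_counties must be >= 1")
        if self.true_mean_yield <= 0:
            raise ValueError("true_mean_yield must be > 0")
        if self.county_sd < 0:
            raise ValueError("county_sd must be >= 0")


def gen_weather(site: SiteSpec, n_years: int = 11, start_year: int = 2004) -> WeatherSeries:
    """Generate a complete multi-year daily weather series for a site.

    Temperature is a site-specific annual sinusoid plus AR(1) noise and
    a yearly anomaly; radiation is the extraterrestrial envelope times a
    beta-distributed transmissivity capped at 0.75 (so the series passes
    the clear-sky QC check by construction); rainfall occurrence follows
    a two-state Markov chain with gamma-distributed amounts.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    preset = CLIMATE_PRESETS[site.climate_preset]
    site_key = zlib.crc32(site.site_id.encode()) % 2**31
    rng = np.random.default_rng(np.random.SeedSequence([site.seed, site_key]))

    dates = pd.date_range(f"{start_year}-01-01", f"{start_year + n_years - 1}-12-31", freq="D")
    n = len(dates)
    doy = dates.dayofyear.to_numpy()
    year_index = dates.year.to_numpy() - start_year

    # yearly anomalies shared by all days of a calendar year
    year_t_anom = rng.normal(0.0, 0.6, n_years)
    year_tau_anom = rng.normal(1.0, 0.055, n_years).clip(0.8, 1.15)

    # temperature: sinusoid peaking ~July 20 (doy 201) in the north hemisphere
    hemi = -1.0 if site.latitude < 0 else 1.0
    seasonal = preset["tmean"] + hemi * preset["amplitude"] * np.cos(
        2.0 * np.pi * (doy - 201) / 365.25
    )
    ar = np.empty(n)
    rho, sd = 0.75, 1.6
    eps = rng.normal(0.0, sd * np.sqrt(1 - rho**2), n)
    ar[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        ar[i] = rho * ar[i - 1] + eps[i]
    tmean = seasonal + ar + year_t_anom[year_index]
    half_range = 0.5 * (preset["diurnal"] + rng.normal(0.0, 1.2, n))
    half_range = np.clip(half_range, 0.5, None)
    tmax = tmean + half_range
    tmin = tmean - half_range

    # radiation: envelope times beta transmissivity, capped at 0.75
    ra = solar.extraterrestrial_radiation(site.latitude, doy)
    tau = solar.MAX_TRANSMISSIVITY * rng.beta(4.0, 1.6, n) * year_tau_anom[year_index]
    tau = np.clip(tau, 0.03, solar.MAX_TRANSMISSIVITY)
    # round, then clamp back under the envelope so the series passes QC
    srad = np.minimum(np.round(ra * tau, 3), ra * solar.MAX_TRANSMISSIVITY)

    # rainfall: two-state Markov occurrence, gamma amounts
    p_wet = preset["p_wet"]
    p11 = min(0.95, p_wet + 0.35)           # wet-after-wet persistence
    p01 = max(0.02, (p_wet - p_wet * p11) / (1 - p_wet))
    wet = np.empty(n, dtype=bool)
    u = rng.random(n)
    wet[0] = u[0] < p_wet
    for i in range(1, n):
        wet[i] = u[i] < (p11 if wet[i - 1] else p01)
    amounts = rng.gamma(shape=0.75, scale=preset["rain_mean"] / 0.75, size=n)
    rain = np.where(wet, amounts, 0.0)

    wind = rng.lognormal(mean=np.log(2.0), sigma=0.45, size=n)
    rh = np.clip(rng.normal(76.0, 8.0, n) + np.where(wet, 6.0, -2.0), 20.0, 100.0)

    df = pd.DataFrame({
        "date": dates,
        "tmax_C": np.round(tmax, 2),
        "tmin_C": np.round(tmin, 2),
        "srad_MJ_m2": srad,
        "rain_mm": np.round(rain, 2),
        "wind_m_s": np.round(wind, 2),
        "rh_pct": np.round(rh, 1),
    }, columns=COLUMNS)
    return WeatherSeries(site.site_id, site.latitude, df, site.elevation)


def gen_area_grid(extent: tuple, cell_size: float, n_clusters: int,
                  total_area_mha: float, seed: int = 0,
                  cluster_radius_cells: float = 4.0) -> pd.DataFrame:
    """Clustered gridded rice harvested area.

    ``extent`` is (lat_min, lat_max, lon_min, lon_max) in degrees;
    cells are squares of ``cell_size`` degrees located by their centers.
    Cell areas (ha) are a mixture of Gaussian cluster kernels times
    lognormal noise, rescaled so the grid sums to ``total_area_mha``
    exactly.  Returns a DataFrame (cell_id, lat, lon, rice_area_ha).
    """
    lat_min, lat_max, lon_min, lon_max = extent
    if not (lat_max > lat_min and lon_max > lon_min):
        raise ValueError("empty extent")
    if total_area_mha <= 0:
        raise ValueError("total_area must be > 0")
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    rng = np.random.default_rng(seed)

    lats = np.arange(lat_min + cell_size / 2, lat_max, cell_size)
    lons = np.arange(lon_min + cell_size / 2, lon_max, cell_size)
    if len(lats) == 0 or len(lons) == 0:
        raise ValueError("cell_size larger than extent")
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    glat, glon = glat.ravel(), glon.ravel()

    centers = rng.choice(len(glat), size=min(n_clusters, len(glat)), replace=False)
    sigma = cluster_radius_cells * cell_size / 2.0  # "cluster radius" = 2 sigma
    weight = np.zeros(len(glat))
    for c in centers:
        d2 = (glat - glat[c]) ** 2 + (glon - glon[c]) ** 2
        weight += np.exp(-0.5 * d2 / sigma**2)
    weight *= rng.lognormal(0.0, 0.5, size=len(glat))
    weight = np.where(weight < 1e-4 * weight.max(), 0.0, weight)
    area = weight / weight.sum() * total_area_mha * 1e6  # Mha -> ha

    return pd.DataFrame({
        "cell_id": [f"c{i:05d}" for i in range(len(glat))],
        "lat": np.round(glat, 5),
        "lon": np.round(glon, 5),
        "rice_area_ha": area,
    })


def gen_admin_yields(provinces: list, years, seed: int = 0) -> tuple:
    """County yield records and provincial official yields.

    County true yields are drawn around each province's true mean and
    rescaled so their area-weighted mean equals it exactly; reported
    county yields carry the province's multiplicative reporting bias.
    Provincial official yields equal the true means.

    Returns ``(county_df, province_df)`` with columns
    (province_id, county_id, year, yield_t_ha, rice_area_ha) and
    (province_id, year, yield_t_ha).
    """
    years = list(years)
    if not years:
        raise ValueError("years must be non-empty")
    rng = np.random.default_rng(seed)
    county_rows, prov_rows = [], []
    for prov in provinces:
        areas = rng.lognormal(np.log(2e4), 0.4, prov.n_counties)
        base = rng.normal(prov.true_mean_yield, prov.county_sd, prov.n_counties)
        base = np.clip(base, 0.2 * prov.true_mean_yield, None)
        # rescale so the area-weighted mean equals the true mean exactly
        base *= prov.true_mean_yield / (np.sum(base * areas) / np.sum(areas))
        for year in years:
            year_factor = 1.0 + rng.normal(0.0, 0.015)
            for j in range(prov.n_counties):
                county_rows.append((
                    prov.province_id, f"{prov.province_id}-cty{j:03d}", int(year),
                    base[j] * year_factor * prov.reporting_bias, areas[j],
                ))
            prov_rows.append((prov.province_id, int(year),
                              prov.true_mean_yield * year_factor))
    county_df = pd.DataFrame(
        county_rows,
        columns=["province_id", "county_id", "year", "yield_t_ha", "rice_area_ha"],
    )
    prov_df = pd.DataFrame(prov_rows, columns=["province_id", "year", "yield_t_ha"])
    return county_df, prov_df


def gen_phenology_obs(cultivar: CultivarParameters, weather: WeatherSeries,
                      sowing, noise_sd_days: float = 0.0,
                      biomass_noise_cv: float = 0.0, seed: int = 0) -> tuple:
    """Phenology dates and organ biomass/LAI samples for a known cultivar.

    The forward model is the package's own simulator, so with zero
    noise calibration must recover the generating parameters.  Returns
    ``(stage_days, samples)``: stage name -> fractional days after
    sowing, and a DataFrame (day, dvs, leaf, stem, panicle, lai) sampled
    at the first day reaching each partition-table dvs edge plus the
    terminal state.
    """
    if noise_sd_days < 0:
        raise ValueError("noise_sd_days must be >= 0")
    rng = np.random.default_rng(seed)
    season = simulate_crop(weather, cultivar, sowing)  # raises if weather too short

    stage_days = dict(season.stage_days)
    if noise_sd_days > 0:
        for k in stage_days:
            if k != "emergence":
                stage_days[k] += rng.normal(0.0, noise_sd_days)
        # preserve stage ordering even under extreme noise draws
        order = ["emergence", "juvenile_end", "panicle_initiation", "flowering", "maturity"]
        vals = np.sort([stage_days[k] for k in order])
        stage_days = dict(zip(order, vals))

    traj = season.trajectory.reset_index(drop=True)
    picks = []
    for edge in cultivar.partition_table.edges:
        hit = traj.index[traj["dvs"] >= edge - 1e-12]
        if len(hit):
            picks.append(int(hit[0]))
    picks = sorted(set(picks + [len(traj) - 1]))
    samples = traj.loc[picks, ["dvs", "leaf", "stem", "panicle", "lai"]].copy()
    samples.insert(0, "day", (traj.loc[picks, "date"] - pd.Timestamp(sowing)).dt.days.to_numpy())
    if biomass_noise_cv > 0:
        for col in ("leaf", "stem", "panicle", "lai"):
            samples[col] *= rng.lognormal(0.0, biomass_noise_cv, len(samples))
    return stage_days, samples.reset_index(drop=True)
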