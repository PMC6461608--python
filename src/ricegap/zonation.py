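"""Climate zonation, station buffer zones, and reference-station selection.

Climate zones are classes over three annual climate summaries computed
from station weather: growing degree days (potential season length),
aridity index (rainfall over reference evapotranspiration), and
temperature seasonality (standard deviation of monthly means).  Each
reference weather station represents the rice area inside a 100-km
buffer clipped to the station's own climate zone; stations are selected
greedily by buffer rice area until a target share of national rice
area is covered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import solar
from .weather import WeatherSeries

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# Annual climate summaries
# ---------------------------------------------------------------------------

def _complete_year_groups(series: WeatherSeries):
    years = series.complete_years()
    if not years:
        raise ValueError("no complete calendar year in weather series")
    skipped = set(series.years()) - set(years)
    if skipped:
        warnings.warn(f"incomplete years excluded: {sorted(skipped)}", stacklevel=3)
    df = series.data
    return [df[df["date"].dt.year == y] for y in years]


def growing_degree_days(series: WeatherSeries, tbase: float = 10.0) -> float:
    """Mean annual growing degree days (degree-days above ``tbase``).

    Daily contribution is max(0, mean(tmax, tmin) - tbase); incomplete
    calendar years are excluded with a warning.
    """
    per_year = []
    for g in _complete_year_groups(series):
        tmean = 0.5 * (g["tmax_C"] + g["tmin_C"])
        per_year.append(float(np.maximum(tmean - tbase, 0.0).sum()))
    return float(np.mean(per_year))


def aridity_index(series: WeatherSeries) -> float:
    """Mean annual rainfall over annual reference evapotranspiration.

    PET uses the Hargreaves temperature-and-radiation closed form (the
    exact PET method behind published zonation tables is not fixed by
    this package; Hargreaves needs only the weather the series carries).
    """
    per_year = []
    for g in _complete_year_groups(series):
        ra = solar.extraterrestrial_radiation(series.latitude, g["date"].dt.dayofyear)
        pet = solar.hargreaves_pet(g["tmax_C"], g["tmin_C"], ra).sum()
        if pet <= 0:
            raise ValueError("zero annual PET; aridity index undefined")
        per_year.append(float(g["rain_mm"].sum() / pet))
    return float(np.mean(per_year))


def temperature_seasonality(series: WeatherSeries) -> float:
    """Standard deviation (C) of the twelve monthly mean temperatures,
    averaged over complete years."""
    per_year = []
    for g in _complete_year_groups(series):
        tmean = 0.5 * (g["tmax_C"] + g["tmin_C"])
        monthly = tmean.groupby(g["date"].dt.month).mean()
        per_year.append(float(monthly.std(ddof=0)))
    return float(np.mean(per_year))


def climate_summary(series: WeatherSeries, gdd_tbase: float = 10.0) -> dict:
    return {
        "gdd": growing_degree_days(series, gdd_tbase),
        "aridity": aridity_index(series),
        "seasonality": temperature_seasonality(series),
    }


# ---------------------------------------------------------------------------
# Zone classification
# ---------------------------------------------------------------------------

#: Default bin edges (interior edges; values outside the outermost edge
#: fall in the boundary bin).  Chosen to spread typical rice climates
#: over several GDD and aridity classes.
DEFAULT_BIN_EDGES = {
    "gdd": [2000.0, 3000.0, 4000.0, 5000.0, 6000.0, 7000.0],
    "aridity": [0.5, 0.8, 1.1, 1.5],
    "seasonality": [5.0, 8.0, 11.0],
}


def _bin_index(values: np.ndarray, edges) -> np.ndarray:
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    return np.digitize(values, edges)


def make_cz_id(gdd_bin, aridity_bin, seasonality_bin) -> np.ndarray:
    """Bijective encoding of the three bin indices into one zone id."""
    return (np.asarray(gdd_bin) * 10000 + np.asarray(aridity_bin) * 100
            + np.asarray(seasonality_bin)).astype(int)


def classify_zones(cells: pd.DataFrame, bin_edges: dict | None = None) -> pd.DataFrame:
    """Assign a climate-zone id to every cell.

    ``cells`` needs columns gdd, aridity, seasonality (per-cell climate
    summaries).  Returns a copy with integer columns gdd_bin,
    aridity_bin, seasonality_bin and cz_id; every cell lands in exactly
    one zone.  Values outside the outermost edges fall into the
    boundary bins (with a warning).
    """
    edges = dict(DEFAULT_BIN_EDGES)
    if bin_edges:
        edges.update(bin_edges)
    out = cells.copy()
    for var, col in (("gdd", "gdd"), ("aridity", "aridity"), ("seasonality", "seasonality")):
        vals = out[col].to_numpy(dtype=float)
        e = np.asarray(edges[var], dtype=float)
        if np.any(vals < e[0]) or np.any(vals >= e[-1]):
            warnings.warn(f"{var}: values outside outermost bin edges assigned "
                          f"to boundary bins", stacklevel=2)
        out[f"{var}_bin"] = _bin_index(vals, e)
    out["cz_id"] = make_cz_id(out["gdd_bin"], out["aridity_bin"], out["seasonality_bin"])
    return out


def n_zones(cells: pd.DataFrame) -> int:
    return int(cells["cz_id"].nunique())


# ---------------------------------------------------------------------------
# Buffers and station selection
# ---------------------------------------------------------------------------

def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    lat1, lon1, lat2, lon2 = map(np.radians, (np.asarray(lat1, dtype=float),
                                              np.asarray(lon1, dtype=float),
                                              np.asarray(lat2, dtype=float),
                                              np.asarray(lon2, dtype=float)))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


@dataclass
class BufferZone:
    """Cells represented by one weather station."""

    station_id: str
    lat: float
    lon: float
    cz_id: int
    radius_km: float = 100.0
    member_cells: list = field(default_factory=list)
    rice_area_ha: float = 0.0


def build_buffer(station: pd.Series, cells: pd.DataFrame,
                 radius_km: float = 100.0) -> BufferZone:
    """Buffer zone of a station: cells within ``radius_km`` great-circle
    distance (closed boundary: a cell at exactly the radius is included)
    AND sharing the station's climate zone.

    ``station`` needs fields station_id, lat, lon, cz_id; ``cells``
    needs cell_id, lat, lon, rice_area_ha, cz_id.
    """
    if "cz_id" not in station or pd.isna(station["cz_id"]):
        raise ValueError("station must carry a cz_id (classify its weather first)")
    d = haversine_km(station["lat"], station["lon"], cells["lat"], cells["lon"])
    member = (d <= radius_km + 1e-9) & (cells["cz_id"] == station["cz_id"])
    members = cells.loc[member]
    if members.empty:
        warnings.warn(f"station {station['station_id']}: empty buffer", stacklevel=2)
    return BufferZone(
        station_id=str(station["station_id"]),
        lat=float(station["lat"]),
        lon=float(station["lon"]),
        cz_id=int(station["cz_id"]),
        radius_km=radius_km,
        member_cells=members["cell_id"].tolist(),
        rice_area_ha=float(members["rice_area_ha"].sum()),
    )


def select_rws(stations: pd.DataFrame, cells: pd.DataFrame,
               target_coverage: float = 0.50,
               radius_km: float = 100.0) -> tuple:
    """Greedy reference-weather-station selection.

    Stations are picked in sequence by the largest *remaining* rice
    area within their buffer (cells already claimed by an earlier
    selection are excluded, so buffers partition the covered area).
    Selection stops with the first pick that reaches
    ``target_coverage`` of national rice area; if the target is
    unreachable all stations are returned with a warning.

    Returns ``(selected, coverage, assignment)``: ordered station ids,
    achieved coverage fraction, and a cell_id -> station_id mapping.
    """
    if len(stations) == 0:
        raise ValueError("at least one station required")
    total = float(cells["rice_area_ha"].sum())
    if total <= 0:
        raise ValueError("grid has zero rice area")

    buffers = {s["station_id"]: build_buffer(s, cells, radius_km)
               for _, s in stations.iterrows()}
    area_of = dict(zip(cells["cell_id"], cells["rice_area_ha"]))

    selected: list = []
    assignment: dict = {}
    covered = 0.0
    unclaimed = {b: set(z.member_cells) for b, z in buffers.items()}
    while covered / total < target_coverage:
        best, best_area = None, 0.0
        for sid in sorted(unclaimed):
            if sid in selected:
                continue
            area = sum(area_of[c] for c in unclaimed[sid])
            if area > best_area:
                best, best_area = sid, area
        if best is None or best_area <= 0:
            warnings.warn(
                f"coverage target {target_coverage:.0%} unreachable; achieved "
                f"{covered / total:.1%} with all {len(selected)} productive stations",
                stacklevel=2,
            )
            break
        claimed = unclaimed[best]
        for c in claimed:
            assignment[c] = best
        covered += best_area
        selected.append(best)
        for sid in unclaimed:
            if sid != best:
                unclaimed[sid] -= claimed
        unclaimed[best] = set()
    return selected, covered / total, assignment
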