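"""Daily weather series container and CSV I/O.

A :class:`WeatherSeries` wraps a tidy pandas DataFrame with one row per
calendar day and the canonical columns used throughout the package::

    date (ISO-8601), tmax_C, tmin_C, srad_MJ_m2, rain_mm, wind_m_s, rh_pct
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COLUMNS = ["date", "tmax_C", "tmin_C", "srad_MJ_m2", "rain_mm", "wind_m_s", "rh_pct"]


@dataclass
class WeatherSeries:
    """Multi-year daily weather for one site.

    Invariants (checked on construction): dates strictly increasing and
    gap-free, tmax >= tmin, srad >= 0.  NaNs are permitted (QC handles
    them) but NaN rows are exempt from the value checks.
    """

    site_id: str
    latitude: float
    data: pd.DataFrame = field(repr=False)
    elevation: float = 0.0

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"weather data missing columns: {missing}")
        dates = pd.to_datetime(df["date"])
        if len(df) == 0:
            raise ValueError("empty weather series")
        deltas = dates.diff().dropna()
        if not (deltas == pd.Timedelta(days=1)).all():
            raise ValueError("weather dates must be strictly increasing and gap-free")
        ok = df[["tmax_C", "tmin_C", "srad_MJ_m2"]].notna().all(axis=1)
        if (df.loc[ok, "tmax_C"] < df.loc[ok, "tmin_C"]).any():
            raise ValueError("tmax < tmin in weather series")
        if (df.loc[ok, "srad_MJ_m2"] < 0).any():
            raise ValueError("negative solar radiation in weather series")
        df = df.copy()
        df["date"] = dates
        object.__setattr__(self, "data", df.reset_index(drop=True))

    # -- convenience accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def dates(self) -> pd.Series:
        return self.data["date"]

    @property
    def doy(self) -> np.ndarray:
        return self.data["date"].dt.dayofyear.to_numpy()

    @property
    def tmean(self) -> np.ndarray:
        return 0.5 * (self.data["tmax_C"] + self.data["tmin_C"]).to_numpy()

    def years(self) -> list[int]:
        return sorted(self.data["date"].dt.year.unique().tolist())

    def complete_years(self) -> list[int]:
        """Calendar years with a full record (365/366 days)."""
        g = self.data.groupby(self.data["date"].dt.year).size()
        out = []
        for year, n in g.items():
            n_expected = 366 if pd.Timestamp(year=year, month=12, day=31).is_leap_year else 365
            if n == n_expected:
                out.append(int(year))
        return out

    def slice(self, start, end) -> "WeatherSeries":
        """Sub-series covering [start, end] inclusive."""
        start = pd.Timestamp(start)
        end = pd.Timestamp(end)
        m = (self.data["date"] >= start) & (self.data["date"] <= end)
        return WeatherSeries(self.site_id, self.latitude, self.data.loc[m], self.elevation)

    # -- I/O -------------------------------------------------------------------
    def to_csv(self, path) -> None:
        out = self.data.copy()
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, site_id: str = "site", latitude: float = 0.0,
                 elevation: float = 0.0) -> "WeatherSeries":
        return cls(site_id, latitude, pd.read_csv(path), elevation)
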