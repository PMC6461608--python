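"""Solar geometry helpers shared by the weather generator, weather QC and PET.

Extraterrestrial radiation follows the standard FAO-56 closed form
(solar constant 0.0820 MJ m-2 min-1, circular-orbit eccentricity
correction, sunset hour angle from latitude and declination).
"""

from __future__ import annotations

import numpy as np

SOLAR_CONSTANT = 0.0820  # MJ m-2 min-1
#: Upper bound on atmospheric transmissivity of daily shortwave at the
#: surface; daily radiation above MAX_TRANSMISSIVITY * Ra is flagged by QC.
MAX_TRANSMISSIVITY = 0.75


def extraterrestrial_radiation(latitude_deg: float, doy) -> np.ndarray:
    """Daily extraterrestrial radiation Ra in MJ m-2 d-1.

    Parameters
    ----------
    latitude_deg : float
        Site latitude in decimal degrees (positive north).
    doy : array-like of int
        Day of year (1..366).
    """
    doy = np.asarray(doy, dtype=float)
    phi = np.deg2rad(latitude_deg)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi / 365.0 * doy)
    delta = 0.409 * np.sin(2.0 * np.pi / 365.0 * doy - 1.39)
    # sunset hour angle; clip handles polar day/night
    x = np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0)
    ws = np.arccos(x)
    ra = (24.0 * 60.0 / np.pi) * SOLAR_CONSTANT * dr * (
        ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws)
    )
    return np.maximum(ra, 0.0)


def clear_sky_envelope(latitude_deg: float, doy) -> np.ndarray:
    """Maximum plausible daily surface radiation (MJ m-2 d-1)."""
    return MAX_TRANSMISSIVITY * extraterrestrial_radiation(latitude_deg, doy)


def hargreaves_pet(tmax, tmin, ra) -> np.ndarray:
    """Daily reference evapotranspiration (mm d-1), Hargreaves-Samani form.

    PET = 0.0023 * (Ra/lambda) * (Tmean + 17.8) * sqrt(Tmax - Tmin),
    with Ra converted to mm-equivalent via 0.408 mm per MJ m-2.
    """
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    ra = np.asarray(ra, dtype=float)
    tmean = 0.5 * (tmax + tmin)
    trange = np.maximum(tmax - tmin, 0.0)
    return np.maximum(
        0.0023 * 0.408 * ra * (tmean + 17.8) * np.sqrt(trange), 0.0
    )
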