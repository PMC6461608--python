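"""County-yield reconciliation, area-weighted upscaling, and yield-gap
accounting.

Yields are t/ha per harvest throughout: double-rice values are
per-season, so the annual output of a double-rice field is the sum of
its two seasons.  Production totals use harvested (season-summed) area.
Reported numbers follow the package's reporting convention: yields to
0.1 t/ha, production to 0.1 MMT, totals and balances to whole MMT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: tolerance of the no-adjustment rule: county statistics within +/-5%
#: of the provincial official yield are left untouched
ADJUST_TOLERANCE = 0.05


# ---------------------------------------------------------------------------
# County yield reconciliation
# ---------------------------------------------------------------------------

def adjust_county_yields(counties: pd.DataFrame, provincial_yield: float) -> tuple:
    """Scale county yields of one province to match the official value.

    If the area-weighted county mean is within +/-5% of the provincial
    official yield, the records are returned unchanged (factor 1.0).
    Otherwise every county yield is multiplied by the single factor
    that makes the area-weighted mean equal the provincial value
    exactly.  Returns ``(adjusted_df, factor)``.  Idempotent.
    """
    if provincial_yield <= 0:
        raise ValueError("provincial yield must be > 0")
    areas = counties["rice_area_ha"].to_numpy(dtype=float)
    if np.any(areas < 0):
        raise ValueError("negative county area")
    if areas.sum() <= 0:
        raise ValueError("zero total county area")
    weighted = float(np.sum(counties["yield_t_ha"] * areas) / areas.sum())
    if abs(weighted / provincial_yield - 1.0) <= ADJUST_TOLERANCE:
        return counties.copy(), 1.0
    factor = provincial_yield / weighted
    out = counties.copy()
    out["yield_t_ha"] = out["yield_t_ha"] * factor
    return out, factor


def current_farm_yield(records: pd.DataFrame, window=range(2010, 2015)) -> float:
    """Current farm yield for one buffer: the unweighted mean across
    window years of the area-weighted county mean yield.

    Years of the window missing from the records are skipped with a
    warning; an empty intersection is an error.
    """
    window = list(window)
    if not window:
        raise ValueError("empty year window")
    present = [y for y in window if (records["year"] == y).any()]
    if not present:
        raise ValueError(f"no records in window {window}")
    if len(present) < len(window):
        warnings.warn(f"years missing from window: {sorted(set(window) - set(present))}",
                      stacklevel=2)
    per_year = []
    for y in present:
        g = records[records["year"] == y]
        a = g["rice_area_ha"].to_numpy(dtype=float)
        per_year.append(float(np.sum(g["yield_t_ha"] * a) / a.sum()))
    return float(np.mean(per_year))


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

@dataclass
class AggregatedYield:
    """Area-weighted yields for one spatial unit."""

    level: str            # buffer | climate_zone | province | system | national
    unit_id: str
    yp: float             # t/ha per harvest
    ya: float             # t/ha per harvest
    area_ha: float        # weight denominator, carried for further levels

    def __post_init__(self) -> None:
        if self.yp <= 0:
            raise ValueError("potential yield must be > 0")
        if self.ya > self.yp:
            warnings.warn(
                f"{self.level} {self.unit_id}: farm yield {self.ya:.2f} exceeds "
                f"potential {self.yp:.2f}", stacklevel=3,
            )

    @property
    def yg_abs(self) -> float:
        return self.yp - self.ya

    @property
    def ya_pct_of_yp(self) -> float:
        return self.ya / self.yp * 100.0


def aggregate(values, areas) -> float:
    """Area-weighted mean: sum(v_i * A_i) / sum(A_i)."""
    v = np.asarray(values, dtype=float)
    a = np.asarray(areas, dtype=float)
    if v.shape != a.shape:
        raise ValueError("values and areas must have equal length")
    if np.any(a < 0):
        raise ValueError("negative area weight")
    if a.sum() <= 0:
        raise ValueError("zero total area")
    return float(np.sum(v * a) / a.sum())


def aggregate_units(units: list, level: str, unit_id: str) -> AggregatedYield:
    """Aggregate a list of :class:`AggregatedYield` to a coarser level,
    carrying total area forward so staged aggregation is exact."""
    areas = [u.area_ha for u in units]
    return AggregatedYield(
        level=level,
        unit_id=unit_id,
        yp=aggregate([u.yp for u in units], areas),
        ya=aggregate([u.ya for u in units], areas),
        area_ha=float(sum(areas)),
    )


def yield_gap(agg: AggregatedYield) -> tuple:
    """(absolute gap t/ha, farm yield as % of potential)."""
    return agg.yg_abs, agg.ya_pct_of_yp


def double_rice_potential(yp_early: float, yp_late: float) -> tuple:
    """Per-season and annualized potential yield of a double-rice system.

    County statistics report one average yield for the two seasonal
    crops, so gaps use the arithmetic mean of the two potential yields;
    the annual field potential is their sum.
    """
    if yp_early <= 0 or yp_late <= 0:
        raise ValueError("seasonal potential yields must be > 0")
    return 0.5 * (yp_early + yp_late), yp_early + yp_late


# ---------------------------------------------------------------------------
# Exploitable gap and production accounting
# ---------------------------------------------------------------------------

def exploitable_gap(yp: float, ya: float, ceiling_fraction: float = 0.80) -> float:
    """Exploitable yield gap per season: max(0, ceiling * Yp - Ya).

    The ceiling (typically 0.75 or 0.80 of potential) is the practical
    level at which farm yields tend to stagnate.
    """
    if not 0.0 < ceiling_fraction <= 1.0:
        raise ValueError("ceiling_fraction must be in (0, 1]")
    if yp <= 0:
        raise ValueError("potential yield must be > 0")
    return max(0.0, ceiling_fraction * yp - ya)


def extra_production(gap_t_ha: float, area_ha: float, seasons_per_year: int = 1) -> float:
    """Annual production increase (MMT) from closing a per-season gap
    over a harvested area.

    ``area_ha`` is harvested area: for double-rice grids where both
    seasons are already pooled into the harvested area, keep
    ``seasons_per_year=1`` to avoid double counting.
    """
    if gap_t_ha < 0 or area_ha < 0 or seasons_per_year < 0:
        raise ValueError("inputs must be >= 0")
    return gap_t_ha * area_ha * seasons_per_year / 1e6  # t -> MMT


# ---------------------------------------------------------------------------
# Reporting convention
# ---------------------------------------------------------------------------

def report_yield(x: float) -> float:
    """Yields at 0.1 t/ha."""
    return float(np.round(x, 1))


def report_production(x: float) -> float:
    """Production at 0.1 MMT."""
    return float(np.round(x, 1))


def report_total(x: float) -> float:
    """Totals and balances at whole MMT."""
    return float(np.round(x, 0))


def national_summary(per_system: dict) -> pd.DataFrame:
    """National yield-gap table from per-system aggregates.

    ``per_system`` maps system label to an :class:`AggregatedYield`.
    Percentages are computed from report-precision (0.1 t/ha) yields,
    matching how published tables are read.
    """
    units = list(per_system.values())
    nat = aggregate_units(units, "national", "national")
    rows = []
    for label, u in list(per_system.items()) + [("national", nat)]:
        yp_r, ya_r = report_yield(u.yp), report_yield(u.ya)
        rows.append({
            "unit": label,
            "yp_t_ha": yp_r,
            "ya_t_ha": ya_r,
            "area_mha": u.area_ha / 1e6,
            "yg_t_ha": report_yield(yp_r - ya_r),
            "ya_pct_of_yp": float(np.round(ya_r / yp_r * 100.0)),
        })
    return pd.DataFrame(rows)
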