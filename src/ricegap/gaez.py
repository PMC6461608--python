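"""Comparison of two gridded potential-yield layers.

A top-down (agro-ecological-zone style) potential-yield raster and the
bottom-up station-based layer are overlaid on a shared harvested-area
grid and compared at climate-zone, province, system and national
levels.  The headline statistics are the area-weighted potential
yields per unit, their percent difference, and the relative yield gap
(bottom-up farm yield as a percent of top-down potential).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .yieldgap import aggregate


def overlay(yp_grid: pd.DataFrame, area_grid: pd.DataFrame,
            zone_map: pd.DataFrame | None = None,
            admin_map: pd.DataFrame | None = None,
            max_distance_deg: float | None = None) -> pd.DataFrame:
    """Join a potential-yield grid onto the harvested-area grid.

    Every area cell takes the yp of its nearest yp-grid cell (by
    cell-center distance); optional zone and admin maps contribute
    cz_id / province_id columns the same way.  Cells with zero rice
    area are retained but carry no weight in aggregation.  Disjoint
    extents (nearest-cell distance beyond ``max_distance_deg``,
    defaulting to the yp grid's span) are an error.
    """
    if len(yp_grid) == 0 or len(area_grid) == 0:
        raise ValueError("empty grid")
    out = area_grid.copy()
    pts = yp_grid[["lat", "lon"]].to_numpy(dtype=float)
    tree = cKDTree(pts)
    query = out[["lat", "lon"]].to_numpy(dtype=float)
    dist, idx = tree.query(query)
    if max_distance_deg is None:
        span = max(np.ptp(pts[:, 0]), np.ptp(pts[:, 1]))
        max_distance_deg = max(span, 1.0)
    if np.min(dist) > max_distance_deg:
        raise ValueError("yp grid and area grid extents are disjoint")
    out["yp_t_ha"] = yp_grid["yp_t_ha"].to_numpy()[idx]
    for extra, col in ((zone_map, "cz_id"), (admin_map, "province_id")):
        if extra is None:
            continue
        etree = cKDTree(extra[["lat", "lon"]].to_numpy(dtype=float))
        _, eidx = etree.query(query)
        out[col] = extra[col].to_numpy()[eidx]
    return out


def weighted_yp(layer: pd.DataFrame, by: str | None = None) -> pd.Series | float:
    """Area-weighted potential yield, nationally or per unit.

    ``by`` is a grouping column (e.g. cz_id, province_id, system);
    ``None`` gives the national value.  Shares the aggregation contract
    of the upscaling module (sum(Yp_i * A_i) / sum(A_i)).
    """
    if layer["rice_area_ha"].sum() <= 0:
        raise ValueError("layer has zero rice area; aggregation refused")
    if by is None:
        return aggregate(layer["yp_t_ha"], layer["rice_area_ha"])
    return layer.groupby(by).apply(
        lambda g: aggregate(g["yp_t_ha"], g["rice_area_ha"]),
        include_groups=False,
    ).rename("yp_t_ha")


def relative_gap(ya_bottom_up: float, yp_top_down: float) -> float:
    """Bottom-up farm yield as a percent of the top-down potential.

    The bottom-up farm yield is used on both sides of the comparison
    because top-down layers typically carry outdated farm yields.
    """
    if yp_top_down <= 0:
        raise ValueError("top-down potential yield must be > 0")
    return ya_bottom_up / yp_top_down * 100.0


def compare_levels(layer_a: pd.DataFrame, layer_b: pd.DataFrame,
                   levels: list, ya_by_unit: dict | None = None) -> pd.DataFrame:
    """Per-unit comparison of two potential-yield layers.

    ``layer_a`` is the top-down layer, ``layer_b`` the bottom-up
    reference (the percent-difference denominator, so pct_diff =
    (a - b) / b * 100).  ``levels`` lists grouping columns plus
    optionally "national".  ``ya_by_unit`` (unit id -> current farm
    yield) adds the relative-gap column and flags units whose top-down
    exploitable production (80% of potential) falls below current
    production.  Units missing from one layer are reported and
    excluded.
    """
    rows = []
    for level in levels:
        if level == "national":
            pairs = [("national", weighted_yp(layer_a), weighted_yp(layer_b),
                      float(layer_b["rice_area_ha"].sum()))]
        else:
            a = weighted_yp(layer_a, by=level)
            b = weighted_yp(layer_b, by=level)
            missing = set(a.index).symmetric_difference(b.index)
            if missing:
                import warnings
                warnings.warn(f"{level}: units missing from one layer excluded: "
                              f"{sorted(missing)}", stacklevel=2)
            shared = sorted(set(a.index) & set(b.index))
            area_b = layer_b.groupby(level)["rice_area_ha"].sum()
            pairs = [(u, float(a[u]), float(b[u]), float(area_b[u])) for u in shared]
        for unit, yp_a, yp_b, area in pairs:
            row = {
                "level": level,
                "unit_id": unit,
                "yp_top_down": yp_a,
                "yp_bottom_up": yp_b,
                "pct_diff": (yp_a - yp_b) / yp_b * 100.0,
            }
            if ya_by_unit is not None and unit in ya_by_unit:
                ya = ya_by_unit[unit]
                row["yg_pct"] = relative_gap(ya, yp_a)
                # exploitable production below current production is the
                # signature of a top-down layer underestimating potential
                row["flag_below_current"] = 0.80 * yp_a * area < ya * area
            rows.append(row)
    return pd.DataFrame(rows)
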