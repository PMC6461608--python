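"""Historical trend fitting and rice production scenarios to 2030.

Trends: ordinary least squares (``fit_linear``) and a continuous
two-linear-segment piecewise fit (``fit_piecewise``) whose integer
breakpoint is found by exhaustive grid search on SSE.  The piecewise
model is parameterized by its endpoint values: y equals ``a`` at the
first year, ``b`` at the breakpoint and ``c`` at the last year, with
linear interpolation inside each segment (continuity at the breakpoint
holds by construction).

Scenarios: per-system 2030 yields are an anchor yield at the base year
(2015) plus a growth rate times the 15-year horizon, optionally capped
at an exploitable ceiling (75 or 80% of potential yield); production
is yield times fixed harvested area, compared against projected demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml


# ---------------------------------------------------------------------------
# Trend fitting
# ---------------------------------------------------------------------------

@dataclass
class TrendFit:
    kind: str                  # "linear" | "piecewise2"
    t1: float
    t2: float
    r2: float
    sse: float
    slope: float | None = None       # linear
    intercept: float | None = None   # linear
    a: float | None = None           # piecewise: value at t1
    b: float | None = None           # piecewise: value at T1
    c: float | None = None           # piecewise: value at t2
    T1: int | None = None            # piecewise breakpoint year

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.kind == "linear":
            return self.slope * t + self.intercept
        left = (self.a * (self.T1 - t) + self.b * (t - self.t1)) / (self.T1 - self.t1)
        right = (self.b * (self.t2 - t) + self.c * (t - self.T1)) / (self.t2 - self.T1)
        return np.where(t <= self.T1, left, right)


def _r2_of(pred: np.ndarray, y: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return float("nan")
    return 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot


def fit_linear(years, values) -> TrendFit:
    """OLS fit y = slope * t + intercept."""
    t = np.asarray(years, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 3:
        raise ValueError("at least 3 points required")
    if np.ptp(t) == 0:
        raise ValueError("years are constant")
    slope, intercept = np.polyfit(t, y, 1)
    pred = slope * t + intercept
    return TrendFit(kind="linear", t1=float(t.min()), t2=float(t.max()),
                    r2=_r2_of(pred, y), sse=float(np.sum((y - pred) ** 2)),
                    slope=float(slope), intercept=float(intercept))


def fit_piecewise(years, values) -> TrendFit:
    """Two-segment continuous piecewise-linear fit with integer
    breakpoint chosen by exhaustive SSE search (ties -> earliest year).

    For each candidate breakpoint T1 strictly inside (t1, t2) the
    endpoint values (a, b, c) solve a linear least-squares problem;
    candidates leaving fewer than 2 points in either segment are
    skipped.
    """
    t = np.asarray(years, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 5:
        raise ValueError("at least 5 points required")
    order = np.argsort(t)
    t, y = t[order], y[order]
    t1, t2 = float(t.min()), float(t.max())

    best = None
    # integer breakpoints strictly inside (t1 + 1, t2 - 1)
    for T1 in range(int(np.ceil(t1)) + 2, int(np.floor(t2)) - 1):
        left = t <= T1
        right = t >= T1
        if left.sum() < 2 or right.sum() < 2:
            continue
        # design matrix in (a, b, c): piecewise basis, continuous at T1
        X = np.zeros((t.size, 3))
        X[left, 0] = (T1 - t[left]) / (T1 - t1)
        X[left, 1] = (t[left] - t1) / (T1 - t1)
        X[right & ~left, 1] = (t2 - t[right & ~left]) / (t2 - T1)
        X[right & ~left, 2] = (t[right & ~left] - T1) / (t2 - T1)
        # the point at exactly T1 (if any) belongs to the left rows above
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(np.sum((X @ coef - y) ** 2))
        if best is None or sse < best[0] - 1e-12:
            best = (sse, T1, coef)
    if best is None:
        raise ValueError("no admissible breakpoint (need >= 2 points per segment)")
    sse, T1, (a, b, c) = best
    fit = TrendFit(kind="piecewise2", t1=t1, t2=t2, r2=float("nan"), sse=sse,
                   a=float(a), b=float(b), c=float(c), T1=int(T1))
    fit.r2 = _r2_of(fit.predict(t), y)
    return fit


# ---------------------------------------------------------------------------
# Projection and scenarios
# ---------------------------------------------------------------------------

def project_yield(base_yield: float, rate: float, year: int,
                  base_year: int = 2015, ceiling: float | None = None) -> float:
    """Yield projected linearly from the base year, optionally capped."""
    if year < base_year:
        raise ValueError("projection year before base year")
    y = base_yield + rate * (year - base_year)
    if ceiling is not None:
        y = min(y, ceiling)
    return y


@dataclass
class SystemSpec:
    """One rice system inside a scenario."""

    label: str                 # "single" | "double"
    anchor_yield: float        # t/ha per season at base_year
    rate: float                # t/ha per year per season
    potential_yield: float     # t/ha per season
    area_mha: float            # harvested area, fixed over the horizon


@dataclass
class ScenarioSpec:
    id: str
    systems: list
    ceiling_fraction: float | None = None   # 0.75 | 0.80 | None
    base_year: int = 2015
    horizon_year: int = 2030
    demand_mmt: float = 217.0


@dataclass
class ScenarioResult:
    id: str
    per_system: pd.DataFrame   # label, yield_2030, production_mmt
    total_mmt: float
    balance_mmt: float


def run_scenario(spec: ScenarioSpec) -> ScenarioResult:
    """Project each system to the horizon and total production.

    Production per system is the 2030 per-season yield times the fixed
    harvested area (season-summed for double-rice, so no extra factor
    of two).  Rounding happens only at report time.
    """
    rows = []
    for sys in spec.systems:
        ceiling = None
        if spec.ceiling_fraction is not None:
            if sys.potential_yield is None or sys.potential_yield <= 0:
                raise ValueError(f"{sys.label}: ceiling requires a potential yield")
            ceiling = spec.ceiling_fraction * sys.potential_yield
        y2030 = project_yield(sys.anchor_yield, sys.rate, spec.horizon_year,
                              spec.base_year, ceiling)
        rows.append({
            "label": sys.label,
            "yield_2030_t_ha": y2030,
            "production_mmt": y2030 * sys.area_mha,  # t/ha * Mha = MMT
        })
    per_system = pd.DataFrame(rows)
    total = float(per_system["production_mmt"].sum())
    return ScenarioResult(spec.id, per_system, total, total - spec.demand_mmt)


def scenario_table(specs: list, rounded: bool = True) -> pd.DataFrame:
    """Report table over scenarios: one row per scenario and system,
    with totals and balance versus demand.

    With ``rounded`` (the default) yields print at 0.1 t/ha, production
    at 0.1 MMT, totals and balances at whole MMT.
    """
    from .yieldgap import report_production, report_total, report_yield

    rows = []
    for spec in specs:
        res = run_scenario(spec)
        for _, r in res.per_system.iterrows():
            rows.append({
                "scenario": spec.id,
                "system": r["label"],
                "yield_t_ha_season": report_yield(r["yield_2030_t_ha"]) if rounded
                else r["yield_2030_t_ha"],
                "production_mmt": report_production(r["production_mmt"]) if rounded
                else r["production_mmt"],
                "total_mmt": report_total(res.total_mmt) if rounded else res.total_mmt,
                "balance_mmt": report_total(res.balance_mmt) if rounded
                else res.balance_mmt,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Shipped configuration
# ---------------------------------------------------------------------------

def load_scenario_config(path=None) -> dict:
    """Load a scenario YAML config (default: the packaged China setup)."""
    if path is None:
        text = resources.files("ricegap").joinpath("data/scenarios_cn.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


def scenarios_from_config(cfg: dict) -> list:
    """Build the S1..S4 ScenarioSpecs from a config mapping.

    Each system carries a current yield (anchor for the stagnation
    scenario) and a fitted yield trend (slope/intercept versus calendar
    year); trend scenarios anchor at the trend value in the base year so
    that evaluating the trend at the horizon equals anchor + slope * dt.
    """
    base_year = int(cfg.get("base_year", 2015))
    horizon = int(cfg.get("horizon_year", 2030))
    demand = float(cfg.get("demand_mmt", 217.0))
    systems = cfg["systems"]

    def mk(label, mode, rate_override=None):
        s = systems[label]
        trend_at_base = s["trend_slope"] * base_year + s["trend_intercept"]
        if mode == "current":
            # current yield backed out of current production over fixed area
            anchor, rate = s["current_production_mmt"] / s["area_mha"], 0.0
        else:
            anchor = trend_at_base
            rate = s["trend_slope"] if rate_override is None else rate_override
        return SystemSpec(label=label, anchor_yield=float(anchor), rate=float(rate),
                          potential_yield=float(s["potential_yield_t_ha"]),
                          area_mha=float(s["area_mha"]))

    common = dict(base_year=base_year, horizon_year=horizon, demand_mmt=demand)
    s4_rate = float(cfg.get("s4_double_rate", systems["single"]["trend_slope"]))
    return [
        ScenarioSpec("S1", [mk("single", "current"), mk("double", "current")],
                     ceiling_fraction=None, **common),
        ScenarioSpec("S2", [mk("single", "trend"), mk("double", "trend")],
                     ceiling_fraction=0.80, **common),
        ScenarioSpec("S3", [mk("single", "trend"), mk("double", "trend")],
                     ceiling_fraction=0.75, **common),
        ScenarioSpec("S4", [mk("single", "trend"), mk("double", "trend", s4_rate)],
                     ceiling_fraction=0.75, **common),
    ]
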