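"""Daily-step rice potential-yield simulator and calibration utilities.

The model simulates one season of irrigated rice grown without water,
nutrient or pest limitation, so that temperature, radiation and growth
duration alone determine yield.  Structure:

phenology
    A development stage ``dvs`` runs from 0 (emergence) through 1
    (flowering) to 2 (maturity), advanced each day by a phase-specific
    development rate times daily thermal time.  Phases: juvenile
    (dvs 0-0.40, rate ``dvrj``), photoperiod-sensitive (0.40-0.65,
    ``dvri``, treated as a plain thermal phase since modern Chinese
    cultivars are essentially photoperiod-insensitive), panicle
    development (0.65-1.0, ``dvrp``), reproductive (1.0-2.0, ``dvrr``).
canopy and growth
    Green leaf area intercepts radiation by Beer's law
    (1 - exp(-k * LAI)); gross growth is radiation-use efficiency times
    intercepted radiation, scaled by a piecewise-linear temperature
    response (0 at tbase, 1 at topt, 0 at thigh).  Maintenance
    respiration is proportional to standing biomass with a Q10 of 2.
partitioning
    Net growth is split into leaf, stem and panicle pools by a
    stage-indexed partition table (step function over dvs intervals).
    A fixed share of stem mass is treated as remobilizable reserves
    credited to grain at harvest.
yield
    Panicle mass at maturity plus mobilized reserves, capped by a
    maximum-harvest-index bound.

This is a deliberately simple radiation-use-efficiency model in the
spirit of process models used for rice potential yield (ORYZA-inspired,
not ORYZA): it reproduces the phenology -> LAI -> assimilation ->
partitioning -> yield chain without canopy-layer photosynthesis,
nitrogen dynamics or stress physiology.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .solar import clear_sky_envelope
from .weather import WeatherSeries

# dvs at the phase boundaries; keys also name the observable stages
PHASE_BOUNDS = {
    "emergence": 0.0,
    "juvenile_end": 0.40,
    "panicle_initiation": 0.65,
    "flowering": 1.0,
    "maturity": 2.0,
}
#: Successive phases as (stage_start, stage_end, rate_attribute)
PHASES = [
    ("emergence", "juvenile_end", "dvrj"),
    ("juvenile_end", "panicle_initiation", "dvri"),
    ("panicle_initiation", "flowering", "dvrp"),
    ("flowering", "maturity", "dvrr"),
]

MAX_SEASON_DAYS = 250


class SeasonTooShortError(RuntimeError):
    """Maturity not reached: growing season too short or too cool."""


class WeatherQCError(ValueError):
    """Weather series rejected by quality control."""


@dataclass
class PartitionTable:
    """Shoot dry-matter partition fractions as a step function of dvs.

    ``edges`` are the interval boundaries (first 0.0, last 2.0);
    interval i spans [edges[i], edges[i+1]) and carries fractions
    (leaf, stem, panicle) that sum to 1.
    """

    edges: tuple = (0.0, 0.5, 0.75, 1.0, 1.2, 2.0)
    leaf: tuple = (0.55, 0.40, 0.15, 0.0, 0.0)
    stem: tuple = (0.45, 0.60, 0.60, 0.20, 0.0)
    panicle: tuple = (0.0, 0.0, 0.25, 0.80, 1.0)

    def __post_init__(self) -> None:
        n = len(self.edges) - 1
        if not (len(self.leaf) == len(self.stem) == len(self.panicle) == n):
            raise ValueError("partition table: fractions must have len(edges)-1 entries")
        if self.edges[0] != 0.0 or self.edges[-1] != 2.0:
            raise ValueError("partition table must span dvs 0..2")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("partition table edges must be strictly increasing")
        for i in range(n):
            s = self.leaf[i] + self.stem[i] + self.panicle[i]
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"partition fractions must sum to 1 (interval {i}: {s})")

    def fractions(self, dvs: float) -> tuple:
        i = int(np.searchsorted(self.edges, dvs, side="right") - 1)
        i = min(max(i, 0), len(self.leaf) - 1)
        return self.leaf[i], self.stem[i], self.panicle[i]


@dataclass
class CultivarParameters:
    """Genotype of the simulator.

    Development rates are in (degree-day)^-1; defaults are typical of a
    ~120-day indica cultivar.  ``rue`` is gross radiation-use efficiency
    (g dry matter per MJ intercepted shortwave), ``sla`` specific leaf
    area (m2 per g leaf), ``spikelet_to_yield`` the maximum harvest
    index bound.
    """

    dvrj: float = 0.000773
    dvri: float = 0.000749
    dvrp: float = 0.000564
    dvrr: float = 0.001904
    tbase: float = 8.0
    topt: float = 30.0
    thigh: float = 42.0
    rue: float = 2.2
    k_ext: float = 0.5
    sla: float = 0.014
    partition_table: PartitionTable = field(default_factory=PartitionTable)
    spikelet_to_yield: float = 0.55
    tt_emergence: float = 75.0     # degree days, sowing to emergence
    maint_coeff: float = 0.004     # d-1, maintenance respiration at 25 C
    stem_reserve_frac: float = 0.20
    reserve_mobilization: float = 0.75
    green_frac_maturity: float = 0.30  # green LAI fraction left at dvs 2

    def __post_init__(self) -> None:
        for name in ("dvrj", "dvri", "dvrp", "dvrr", "rue", "k_ext", "sla"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (self.tbase < self.topt < self.thigh):
            raise ValueError("cardinal temperatures must satisfy tbase < topt < thigh")
        if not 0.0 < self.spikelet_to_yield <= 0.65:
            raise ValueError("maximum harvest index must be in (0, 0.65]")

    def rate_at(self, dvs: float) -> float:
        for start, end, attr in PHASES:
            if dvs < PHASE_BOUNDS[end]:
                return getattr(self, attr)
        return self.dvrr

    def advance_dvs(self, dvs: float, dtt_day: float):
        """Advance dvs by one day of thermal time, switching phase rates
        at the exact sub-daily boundary crossings.

        Returns (new_dvs, crossings) where crossings is a list of
        (stage_name, fraction_of_day) for each boundary passed.
        """
        crossings = []
        remaining = float(dtt_day)
        used = 0.0
        if dtt_day <= 0:
            return dvs, crossings
        bounds = [(PHASE_BOUNDS[end], end) for _, end, _ in PHASES]
        while remaining > 0:
            rate = self.rate_at(dvs)
            nxt = next(((b, name) for b, name in bounds if b > dvs), None)
            if nxt is None:
                break
            bound, name = nxt
            tt_need = (bound - dvs) / rate
            if tt_need <= remaining:
                used += tt_need
                remaining -= tt_need
                dvs = bound
                crossings.append((name, used / dtt_day))
                if bound >= 2.0:
                    break
            else:
                dvs += rate * remaining
                remaining = 0.0
        return dvs, crossings

    def replace(self, **kwargs) -> "CultivarParameters":
        return dataclasses.replace(self, **kwargs)


def thermal_time(tmean, tbase: float, thigh: float) -> np.ndarray:
    """Daily thermal time: mean temperature clipped to [tbase, thigh], minus tbase."""
    return np.clip(np.asarray(tmean, dtype=float), tbase, thigh) - tbase


def temperature_response(tmean, tbase: float, topt: float, thigh: float) -> np.ndarray:
    """Piecewise-linear growth multiplier: 0 at tbase, 1 at topt, 0 at thigh."""
    t = np.asarray(tmean, dtype=float)
    up = (t - tbase) / (topt - tbase)
    down = (thigh - t) / (thigh - topt)
    return np.clip(np.minimum(up, down), 0.0, 1.0)


# ---------------------------------------------------------------------------
# Weather quality control
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Outcome of weather screening: per-day flags and the usable series."""

    flags: pd.DataFrame            # columns: index, date, reason
    n_imputed: int
    cleaned: WeatherSeries

    @property
    def n_flagged(self) -> int:
        return self.flags["index"].nunique()


def qc_weather(series: WeatherSeries, max_flag_frac: float = 0.10) -> QCReport:
    """Screen a daily weather series for physically impossible records.

    Flags (never silently altering valid data): tmax < tmin, daily
    radiation above the clear-sky envelope for the site latitude and
    day of year, negative rainfall, and missing values.  In the
    returned ``cleaned`` series the offending values are masked, and
    isolated single-day gaps (a missing value between two valid days
    of the same variable) are imputed by neighbour interpolation.  If
    more than ``max_flag_frac`` of days carry flags the series is
    rejected.
    """
    df = series.data
    n = len(df)
    if n == 0:
        raise ValueError("empty weather series")
    value_cols = ["tmax_C", "tmin_C", "srad_MJ_m2", "rain_mm"]
    isnan = df[value_cols].isna().any(axis=1).to_numpy()
    envelope = clear_sky_envelope(series.latitude, df["date"].dt.dayofyear)

    flags = []
    cleaned = df.copy()
    for i in range(n):
        if isnan[i]:
            flags.append((i, df["date"].iloc[i], "missing"))
            continue
        if df["tmax_C"].iloc[i] < df["tmin_C"].iloc[i]:
            flags.append((i, df["date"].iloc[i], "tmax_lt_tmin"))
            cleaned.loc[cleaned.index[i], ["tmax_C", "tmin_C"]] = np.nan
        if df["srad_MJ_m2"].iloc[i] > envelope[i] * (1 + 1e-9):
            flags.append((i, df["date"].iloc[i], "srad_above_envelope"))
            cleaned.loc[cleaned.index[i], "srad_MJ_m2"] = np.nan
        if df["rain_mm"].iloc[i] < 0:
            flags.append((i, df["date"].iloc[i], "negative_rain"))
            cleaned.loc[cleaned.index[i], "rain_mm"] = np.nan

    flag_df = pd.DataFrame(flags, columns=["index", "date", "reason"])
    if flag_df["index"].nunique() > max_flag_frac * n:
        raise WeatherQCError(
            f"weather series rejected: {flag_df['index'].nunique()} of {n} days "
            f"flagged (> {max_flag_frac:.0%}); reasons: "
            f"{flag_df['reason'].value_counts().to_dict()}"
        )

    # impute isolated single-day gaps per variable by neighbour means
    imputed_days: set = set()
    for c in value_cols + ["wind_m_s", "rh_pct"]:
        col = cleaned[c].to_numpy(dtype=float)
        gap = np.isnan(col)
        for i in np.flatnonzero(gap):
            if 0 < i < n - 1 and not gap[i - 1] and not gap[i + 1]:
                col[i] = 0.5 * (col[i - 1] + col[i + 1])
                imputed_days.add(int(i))
        cleaned[c] = col
    n_imputed = len(imputed_days)
    out = WeatherSeries(series.site_id, series.latitude, cleaned, series.elevation)
    return QCReport(flags=flag_df, n_imputed=n_imputed, cleaned=out)


# ---------------------------------------------------------------------------
# Season simulation
# ---------------------------------------------------------------------------

@dataclass
class SeasonResult:
    """One simulated season."""

    yield_t_ha: float
    total_biomass_t_ha: float
    duration_days: float            # sowing to maturity
    sowing: pd.Timestamp
    flowering_date: pd.Timestamp
    maturity_date: pd.Timestamp
    stage_days: dict                # stage -> fractional days after sowing
    trajectory: pd.DataFrame = field(repr=False)
    mass_balance_error: float = 0.0


def simulate_crop(weather: WeatherSeries, cultivar: CultivarParameters,
                  sowing, density: float = 28.0,
                  keep_trajectory: bool = True) -> SeasonResult:
    """Simulate one rice season under potential (unstressed) conditions.

    ``sowing`` is a date within the weather record; ``density`` (hills
    per m2) only scales initial leaf mass, consistent with potential
    production where the canopy closes well before flowering.
    Raises :class:`SeasonTooShortError` if maturity is not reached
    within 250 days (or the weather record ends first).
    """
    sowing = pd.Timestamp(sowing)
    dates = weather.data["date"]
    if sowing < dates.iloc[0] or sowing > dates.iloc[-1]:
        raise ValueError(f"sowing date {sowing.date()} outside weather coverage")
    i0 = int((dates == sowing).idxmax())

    sub = weather.data.iloc[i0:].reset_index(drop=True)
    tmean = 0.5 * (sub["tmax_C"] + sub["tmin_C"]).to_numpy()
    srad = sub["srad_MJ_m2"].to_numpy()
    if np.isnan(tmean).any() or np.isnan(srad).any():
        raise ValueError("weather contains missing values; run qc_weather first")
    dtt = thermal_time(tmean, cultivar.tbase, cultivar.thigh)
    ftemp = temperature_response(tmean, cultivar.tbase, cultivar.topt, cultivar.thigh)

    # sowing -> emergence at a fixed thermal-time cost
    cum = np.cumsum(dtt)
    idx = np.searchsorted(cum, cultivar.tt_emergence)
    if idx >= len(cum):
        raise SeasonTooShortError("crop never emerged within the weather record")
    day_e = int(idx)

    # initial leaf mass from planting density: 2.5 plants/hill, 0.3 g DM each
    leaf = density * 2.5 * 0.3 / 100.0 / 10.0  # g/m2 -> t/ha is /100; tiny pool
    stem = 0.0
    panicle = 0.0
    dvs = 0.0
    total = leaf
    assim_cum = total  # initial seedling mass counted as external input
    stem_at_flowering = None
    stage_days: dict = {"emergence": float(day_e + 1)}
    rows = []  # start-of-day state: date, dvs, lai, leaf, stem, panicle
    n = len(sub)
    day = day_e + 1
    matured = False
    while day < n and day - day_e <= MAX_SEASON_DAYS:
        # canopy and growth use start-of-day state
        green_frac = 1.0 if dvs <= 1.0 else max(
            cultivar.green_frac_maturity,
            1.0 - (1.0 - cultivar.green_frac_maturity) * (dvs - 1.0),
        )
        lai = cultivar.sla * leaf * 100.0 * green_frac  # t/ha -> g/m2 is *100
        if keep_trajectory:
            rows.append((sub["date"].iloc[day], dvs, lai, leaf, stem, panicle))
        fint = 1.0 - np.exp(-cultivar.k_ext * lai)
        gross = cultivar.rue * srad[day] * fint * ftemp[day] * 0.01  # t/ha/d
        maint = cultivar.maint_coeff * (leaf + stem + panicle) * 2.0 ** ((tmean[day] - 25.0) / 10.0)
        net = gross - maint
        fl, fs, fp = cultivar.partition_table.fractions(dvs)
        leaf = max(leaf + fl * net, 0.0)
        stem = max(stem + fs * net, 0.0)
        panicle = max(panicle + fp * net, 0.0)
        assim_cum += net
        total = leaf + stem + panicle

        dvs_new, crossings = cultivar.advance_dvs(dvs, dtt[day])
        for stage, frac in crossings:
            stage_days[stage] = day + frac
            if stage == "flowering":
                stem_at_flowering = stem
        dvs = dvs_new
        if dvs >= 2.0:
            matured = True
            break
        day += 1
    if not matured:
        raise SeasonTooShortError(
            f"maturity not reached (dvs={dvs:.2f}) within "
            f"{min(n - day_e - 1, MAX_SEASON_DAYS)} days after emergence"
        )
    if keep_trajectory:
        # terminal state after the last growth day
        green_frac = max(cultivar.green_frac_maturity,
                         1.0 - (1.0 - cultivar.green_frac_maturity) * (dvs - 1.0))
        rows.append((sub["date"].iloc[day] + pd.Timedelta(days=1), dvs,
                     cultivar.sla * leaf * 100.0 * green_frac, leaf, stem, panicle))

    if stem_at_flowering is None:
        stem_at_flowering = stem
    reserves = cultivar.stem_reserve_frac * stem_at_flowering
    yld = panicle + cultivar.reserve_mobilization * reserves
    yld = min(yld, cultivar.spikelet_to_yield * total)

    traj = pd.DataFrame(rows, columns=["date", "dvs", "lai", "leaf", "stem", "panicle"])
    flowering_day = stage_days.get("flowering")
    maturity_day = stage_days.get("maturity", float(day))
    return SeasonResult(
        yield_t_ha=float(yld),
        total_biomass_t_ha=float(total),
        duration_days=float(maturity_day),
        sowing=sowing,
        flowering_date=sowing + pd.Timedelta(days=float(np.floor(flowering_day))),
        maturity_date=sowing + pd.Timedelta(days=float(np.floor(maturity_day))),
        stage_days=stage_days,
        trajectory=traj,
        mass_balance_error=float(abs(total - assim_cum)),
    )


@dataclass
class SimulationResult:
    """Multi-year potential-yield summary for one site and sowing rule."""

    site_id: str
    seasons: pd.DataFrame   # year, yield_t_ha, biomass_t_ha, duration_d, flowering, maturity
    failures: list          # (year, reason)

    @property
    def mean_yield(self) -> float:
        return float(self.seasons["yield_t_ha"].mean())

    @property
    def cv_pct(self) -> float:
        m = self.mean_yield
        if m == 0:
            return float("nan")
        return float(self.seasons["yield_t_ha"].std(ddof=1) / m * 100.0)


def simulate_potential(weather: WeatherSeries, cultivar: CultivarParameters,
                       sowing_rule: str = "05-10") -> SimulationResult:
    """Year-by-year potential yield with mean and temporal CV.

    ``sowing_rule`` is a fixed MM-DD sowing date applied to every
    calendar year of the record for which a season can be attempted.
    Failed years (e.g. maturity not reached) are reported in
    ``failures``, never silently dropped.
    """
    years = weather.years()
    rows, failures = [], []
    for year in years:
        try:
            sow = pd.Timestamp(f"{year}-{sowing_rule}")
        except ValueError as e:
            raise ValueError(f"bad sowing rule {sowing_rule!r}") from e
        if sow < weather.dates.iloc[0] or sow > weather.dates.iloc[-1]:
            continue
        try:
            res = simulate_crop(weather, cultivar, sow, keep_trajectory=False)
        except SeasonTooShortError as e:
            failures.append((year, str(e)))
            continue
        rows.append(
            (year, res.yield_t_ha, res.total_biomass_t_ha, res.duration_days,
             res.flowering_date, res.maturity_date)
        )
    if len(rows) < 2:
        raise ValueError(
            f"fewer than 2 complete seasons simulable "
            f"({len(rows)} ok, {len(failures)} failed)"
        )
    seasons = pd.DataFrame(
        rows, columns=["year", "yield_t_ha", "biomass_t_ha", "duration_d",
                       "flowering", "maturity"]
    )
    return SimulationResult(weather.site_id, seasons, failures)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass
class PhenologyObservation:
    """Observed phase-boundary dates for one site-year.

    ``stage_days`` maps stage name (see PHASE_BOUNDS) to fractional
    days after sowing.
    """

    weather: WeatherSeries
    sowing: pd.Timestamp
    stage_days: dict


def _cum_tt(dtt: np.ndarray) -> np.ndarray:
    """Cumulative thermal time with C[0]=0; C[i] = TT accrued by day i (start of day i)."""
    return np.concatenate([[0.0], np.cumsum(dtt)])


def _tt_between(cum: np.ndarray, a: float, b: float) -> float:
    """Thermal time accrued between fractional days a and b (a <= b)."""
    def at(t: float) -> float:
        i = int(np.floor(t))
        i = min(max(i, 0), len(cum) - 2)
        return cum[i] + (t - i) * (cum[i + 1] - cum[i])
    return at(b) - at(a)


def _crossing_day(cum: np.ndarray, start: float, tt_target: float) -> float:
    """Fractional day at which TT accrued since ``start`` reaches ``tt_target``."""
    i0 = int(np.floor(start))
    i0 = min(max(i0, 0), len(cum) - 2)
    c_start = cum[i0] + (start - i0) * (cum[i0 + 1] - cum[i0])
    target = c_start + tt_target
    if target > cum[-1]:
        raise SeasonTooShortError("thermal-time target beyond weather record")
    i = int(np.searchsorted(cum, target, side="left"))
    i = min(max(i - 1, 0), len(cum) - 2)
    dstep = cum[i + 1] - cum[i]
    frac = 0.0 if dstep <= 0 else (target - cum[i]) / dstep
    return i + frac


def calibrate_phenology(observations: list, cultivar: CultivarParameters,
                        ) -> CultivarParameters:
    """Fit the four development rates from observed phase-boundary dates.

    Cardinal temperatures are held fixed at the template cultivar's
    values.  For each phase in fixed order (dvrj, dvri, dvrp, dvrr) the
    rate minimizing the squared error between predicted and observed
    boundary dates across site-years is found; each phase is predicted
    from the observed start of that phase, so the four one-dimensional
    problems are independent and the procedure is deterministic.
    """
    if not observations:
        raise ValueError("at least one site-year of observations required")
    # per site-year: cumulative thermal time and the current phase start
    # day, which is chained forward from the fitted earlier phases (so
    # each observed date enters the objective exactly once, as a target)
    state = []
    for obs in observations:
        if "emergence" not in obs.stage_days:
            raise ValueError("each site-year must observe emergence")
        sow_idx = int((obs.weather.data["date"] == pd.Timestamp(obs.sowing)).idxmax())
        sub = obs.weather.data.iloc[sow_idx:]
        tmean = 0.5 * (sub["tmax_C"] + sub["tmin_C"]).to_numpy()
        dtt = thermal_time(tmean, cultivar.tbase, cultivar.thigh)
        state.append({
            "cum": _cum_tt(dtt),
            "start": float(obs.stage_days["emergence"]),
            "obs": obs.stage_days,
        })

    rates = {}
    for start, end, attr in PHASES:
        span = PHASE_BOUNDS[end] - PHASE_BOUNDS[start]
        implied, fitting = [], []
        for st in state:
            if end not in st["obs"]:
                continue
            tt = _tt_between(st["cum"], st["start"], st["obs"][end])
            if tt <= 0:
                raise ValueError(
                    f"phase {start}->{end}: no thermal time accrues before the "
                    f"observed date (unreachable under this weather)"
                )
            implied.append(span / tt)
            fitting.append(st)
        if not implied:
            raise ValueError(f"no site-year observes {end}")

        def sse(rate: float) -> float:
            total = 0.0
            for st in fitting:
                try:
                    pred = _crossing_day(st["cum"], st["start"], span / rate)
                except SeasonTooShortError:
                    return 1e12
                total += (pred - st["obs"][end]) ** 2
            return total

        res = optimize.minimize_scalar(
            sse, bounds=(0.25 * min(implied), 4.0 * max(implied)),
            method="bounded", options={"xatol": 1e-12 * max(implied)},
        )
        rates[attr] = float(res.x)
        for st in state:  # chain the fitted phase forward
            try:
                st["start"] = _crossing_day(st["cum"], st["start"], span / rates[attr])
            except SeasonTooShortError:
                st["start"] = float(len(st["cum"]) - 1)
    return cultivar.replace(**rates)


def calibrate_partitioning(samples: pd.DataFrame,
                           cultivar: CultivarParameters) -> CultivarParameters:
    """Fit the partition table and specific leaf area from organ samples.

    ``samples`` needs columns dvs, leaf, stem, panicle (t/ha) and lai,
    sampled at increasing dvs spanning 0..2 with at least 3 dates.
    Fractions for each table interval are the organ increments between
    the bracketing samples divided by the shoot increment, clipped to
    [0, 1] and renormalized; sla is the green-leaf regression of lai on
    leaf mass over the vegetative phase.
    """
    df = samples.sort_index()
    if len(df) < 3:
        raise ValueError("at least 3 sampling dates spanning dvs 0..2 required")
    dvs = df["dvs"].to_numpy(dtype=float)
    if not np.all(np.diff(dvs) > 0):
        raise ValueError("dvs timeline must be strictly increasing")
    if dvs[0] > 0.1 or dvs[-1] < 1.9:
        raise ValueError("samples must span dvs 0..2")

    # Pool increments between consecutive samples are assigned to the
    # table interval containing the midpoint dvs of the sampling span;
    # increments landing in the same interval are pooled (growth-weighted).
    edges = cultivar.partition_table.edges
    n_int = len(edges) - 1
    sums = np.zeros((n_int, 4))  # d_leaf, d_stem, d_panicle, d_total
    for i in range(len(df) - 1):
        mid = 0.5 * (dvs[i] + dvs[i + 1])
        k = min(max(int(np.searchsorted(edges, mid, side="right") - 1), 0), n_int - 1)
        d = [float(df[c].iloc[i + 1] - df[c].iloc[i]) for c in ("leaf", "stem", "panicle")]
        sums[k, :3] += d
        sums[k, 3] += sum(d)

    leaf_f, stem_f, pan_f = [], [], []
    for k in range(n_int):
        if sums[k, 3] <= 0:
            # no observed growth in this interval: keep template fractions
            leaf_f.append(cultivar.partition_table.leaf[k])
            stem_f.append(cultivar.partition_table.stem[k])
            pan_f.append(cultivar.partition_table.panicle[k])
            continue
        fr = np.clip(sums[k, :3] / sums[k, 3], 0.0, 1.0)
        fr = fr / fr.sum()
        leaf_f.append(float(fr[0]))
        stem_f.append(float(fr[1]))
        pan_f.append(float(fr[2]))

    veg = df[df["dvs"] < 1.0]
    leaf_mass = veg["leaf"].to_numpy(dtype=float) * 100.0  # t/ha -> g/m2
    lai = veg["lai"].to_numpy(dtype=float)
    good = leaf_mass > 0
    if good.sum() == 0:
        sla = cultivar.sla
    else:
        sla = float(np.sum(lai[good] * leaf_mass[good]) / np.sum(leaf_mass[good] ** 2))
    table = PartitionTable(edges, tuple(leaf_f), tuple(stem_f), tuple(pan_f))
    return cultivar.replace(partition_table=table, sla=sla)


# ---------------------------------------------------------------------------
# Fit metrics
# ---------------------------------------------------------------------------

@dataclass
class FitMetrics:
    """Agreement between simulated (x) and observed (y) values."""

    r2: float
    rmse: float
    rmse_n: float  # RMSE as % of the observed mean
    n: int


def fit_metrics(simulated, observed) -> FitMetrics:
    """Coefficient of determination (squared Pearson), RMSE and
    normalized RMSE (% of observed mean) between paired vectors.

    If either vector has zero variance, r2 is undefined and returned as
    NaN (with a warning); RMSE is still computed.  rmse_n is NaN when
    the observed mean is zero.
    """
    x = np.asarray(simulated, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.shape != y.shape:
        raise ValueError("simulated and observed must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("at least 2 paired values required")
    rmse = float(np.sqrt(np.mean((x - y) ** 2)))
    sx = n * np.sum(x * x) - np.sum(x) ** 2
    sy = n * np.sum(y * y) - np.sum(y) ** 2
    if sx <= 0 or sy <= 0:
        warnings.warn("zero variance: r2 undefined", RuntimeWarning, stacklevel=2)
        r2 = float("nan")
    else:
        num = n * np.sum(x * y) - np.sum(x) * np.sum(y)
        r2 = float(num * num / (sx * sy))
    m = float(np.mean(y))
    rmse_n = float("nan") if m == 0 else rmse / m * 100.0
    return FitMetrics(r2=r2, rmse=rmse, rmse_n=rmse_n, n=int(n))
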