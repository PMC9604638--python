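"""Personal exposure estimation from sensor streams and activity diaries.

The accumulated dose of an airborne pollutant over an activity is the
product of the ambient concentration and the inhalation rate:

    E_j = Conc × Inh.Rate / 60          (per-minute exposure, activity j)
    f   = Σ_j E_j · T_j                 (accumulated daily exposure)

where T_j is the minutes spent on activity j in the aggregation window and
the concentration is taken minute-by-minute from the sensor record nearest
in time within the activity's space.  Daily exposure to CO2, temperature
and relative humidity uses the plain 24 h mean instead of a dose.  The
aggregation window for day d is the half-open 24 h interval between the
morning PEFR measurements of day d−1 and day d, so no feature of a row can
use information at or after that row's own measurement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "AirQualityRecord",
    "ActivityInterval",
    "InhalationTable",
    "FeatureTableReport",
    "activity_exposure_rate",
    "mean_exposure",
    "accumulate_daily_exposure",
    "build_feature_table",
    "FEATURE_COLUMNS",
]

log = logging.getLogger(__name__)

#: feature columns of a daily row, in stable output order
FEATURE_COLUMNS = [
    "pm25_exposure",
    "co2_mean",
    "temp_mean",
    "rh_mean",
    "yesterday_am_pefr",
    "yesterday_pm_pefr",
    "cooking_level",
    "road_level",
    "income_level",
]

#: activity types treated as exertion (inhalation rate scaled up)
EXERTION_ACTIVITIES = frozenset({"cooking", "housework", "exercise"})

#: resting adult inhalation rate, m³/min
DEFAULT_REST_RATE = 0.012


@dataclass(frozen=True)
class AirQualityRecord:
    """One timestamped multi-pollutant sensor reading in a space."""

    timestamp: pd.Timestamp
    space_id: str
    pm25: float  # µg/m³
    co2: float  # ppm
    temperature: float  # °C
    humidity: float  # % RH

    def __post_init__(self) -> None:
        if self.pm25 < 0 or self.co2 <= 0 or not 0 <= self.humidity <= 100:
            raise ValueError("air-quality record outside physical range")


@dataclass(frozen=True)
class ActivityInterval:
    """A diary entry: one activity in one space over [start, end)."""

    start: pd.Timestamp
    end: pd.Timestamp
    activity_type: str
    space_id: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("activity interval must have end > start")


@dataclass(frozen=True)
class InhalationTable:
    """Inhalation rates (m³/min) by activity type.

    Published age-by-activity tables are an external input; the default
    ships a single adult resting rate with a ×2 multiplier for
    exertion-class activities.  ``rates`` overrides take precedence.
    """

    rest_rate: float = DEFAULT_REST_RATE
    exertion_factor: float = 2.0
    rates: Mapping[str, float] = field(default_factory=dict)

    def rate(self, activity_type: str) -> float:
        if activity_type in self.rates:
            r = float(self.rates[activity_type])
        elif activity_type in EXERTION_ACTIVITIES:
            r = self.rest_rate * self.exertion_factor
        else:
            r = self.rest_rate
        if r <= 0:
            raise ValueError(f"inhalation rate for {activity_type!r} must be > 0")
        return r


@dataclass
class FeatureTableReport:
    """Bookkeeping of rows dropped while building a feature table."""

    n_days: int = 0
    n_rows: int = 0
    dropped_missing_pefr: int = 0
    dropped_incomplete_exposure: int = 0
    skipped_activities: int = 0


def activity_exposure_rate(conc: float, inh_rate: float) -> float:
    """Per-minute exposure E_j = conc × inh_rate / 60."""
    if conc < 0:
        raise ValueError(f"concentration must be >= 0, got {conc}")
    if inh_rate <= 0:
        raise ValueError(f"inhalation rate must be > 0, got {inh_rate}")
    return conc * inh_rate / 60.0


def mean_exposure(
    records: pd.DataFrame,
    variable: str,
    window: Tuple[pd.Timestamp, pd.Timestamp],
) -> Optional[float]:
    """Arithmetic mean of one sensor variable over in-window records.

    Window is half-open [t0, t1).  Returns ``None`` when no record falls in
    the window (the caller flags the row).
    """
    t0, t1 = window
    ts = records["timestamp"]
    sel = records.loc[(ts >= t0) & (ts < t1), variable]
    if sel.empty:
        return None
    return float(sel.mean())


def _minute_concentrations(
    times: np.ndarray,
    values: np.ndarray,
    minutes: np.ndarray,
    max_gap_s: float,
) -> np.ndarray:
    """Nearest-record concentration per minute; NaN where gap > max_gap_s.

    ``times`` must be sorted int64 nanoseconds for one space.
    """
    out = np.full(minutes.shape, np.nan)
    if times.size == 0:
        return out
    pos = np.searchsorted(times, minutes)
    left = np.clip(pos - 1, 0, times.size - 1)
    right = np.clip(pos, 0, times.size - 1)
    dl = np.abs(minutes - times[left])
    dr = np.abs(times[right] - minutes)
    nearest = np.where(dl <= dr, left, right)
    gap = np.minimum(dl, dr) / 1e9
    ok = gap <= max_gap_s
    out[ok] = values[nearest[ok]]
    return out


def accumulate_daily_exposure(
    records: pd.DataFrame,
    activities: Sequence[ActivityInterval] | pd.DataFrame,
    inh: InhalationTable,
    window: Tuple[pd.Timestamp, pd.Timestamp],
    *,
    variable: str = "pm25",
    max_gap_minutes: float = 10.0,
) -> Tuple[float, int]:
    """Accumulated dose f = Σ_j E_j · T_j over the window.

    Each activity interval is clipped to the half-open window and walked in
    one-minute steps; every minute contributes conc × rate / 60 where conc
    is the nearest-in-time record in the activity's space (skipped, and
    logged, beyond ``max_gap_minutes``).  Returns (dose, skipped_minutes).
    Activities referencing spaces with no sensor records are skipped.
    """
    t0, t1 = window
    if isinstance(activities, pd.DataFrame):
        acts = [
            ActivityInterval(row.start, row.end, row.activity_type, row.space_id)
            for row in activities.itertuples(index=False)
        ]
    else:
        acts = list(activities)
    if t1 <= t0:
        log.warning("empty exposure window %s..%s", t0, t1)
        return 0.0, 0

    by_space: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for space, grp in records.groupby("space_id"):
        grp = grp.sort_values("timestamp")
        by_space[str(space)] = (
            grp["timestamp"].to_numpy(dtype="datetime64[ns]").astype(np.int64),
            grp[variable].to_numpy(dtype=float),
        )

    dose = 0.0
    skipped = 0
    max_gap_s = max_gap_minutes * 60.0
    minute_ns = 60 * 1_000_000_000
    for act in acts:
        lo = max(act.start, t0)
        hi = min(act.end, t1)
        if hi <= lo:
            continue
        if act.space_id not in by_space:
            log.warning("activity in unknown space %r skipped", act.space_id)
            skipped += int((hi - lo).total_seconds() // 60)
            continue
        n_min = int((hi - lo).total_seconds() // 60)
        if n_min == 0:
            continue
        # minute midpoints, so the nearest record represents that minute
        start_ns = lo.value + minute_ns // 2
        minutes = start_ns + minute_ns * np.arange(n_min, dtype=np.int64)
        times, values = by_space[act.space_id]
        conc = _minute_concentrations(times, values, minutes, max_gap_s)
        miss = int(np.isnan(conc).sum())
        if miss:
            log.debug("%d minutes without sensor coverage in %s", miss, act.space_id)
            skipped += miss
        rate = inh.rate(act.activity_type)
        dose += float(np.nansum(conc)) * rate / 60.0
    return dose, skipped


def _am_timestamp(date: pd.Timestamp, am_time: str) -> pd.Timestamp:
    return pd.Timestamp(f"{pd.Timestamp(date).date()} {am_time}")


def build_feature_table(
    air_quality: pd.DataFrame,
    pefr_diary: pd.DataFrame,
    activities: pd.DataFrame,
    covariates: Mapping[str, float],
    inh: Optional[InhalationTable] = None,
    *,
    am_time: str = "07:00",
    pm25_as_mean: bool = False,
    max_gap_minutes: float = 10.0,
) -> Tuple[pd.DataFrame, FeatureTableReport]:
    """Build one daily feature row per patient-day with a valid morning PEFR.

    Row d aggregates the 24 h window [AM time of day d−1, AM time of day d):
    PM2.5 as an inhaled dose (or a plain mean with ``pm25_as_mean``), CO2 /
    temperature / humidity as means, plus yesterday's AM and PM PEFR and the
    static covariates.  Rows missing the AM PEFR on day d or d−1, or with an
    exposure window empty of sensor data, are dropped and counted.  The
    returned frame is indexed by date and also carries ``am_pefr`` (that
    day's observed value — the response for zoning and quantile modelling,
    never a feature).
    """
    inh = inh or InhalationTable()
    diary = pefr_diary.copy()
    diary["date"] = pd.to_datetime(diary["date"])
    diary = diary.sort_values("date").set_index("date")
    report = FeatureTableReport(n_days=len(diary))

    # per-space sorted arrays with cumulative sums: O(1) window means and
    # cheap nearest-record lookups, identical in value to the per-window ops
    spaces: Dict[str, dict] = {}
    aq = air_quality
    ts_all = pd.to_datetime(aq["timestamp"]).to_numpy(dtype="datetime64[ns]")
    for space in aq["space_id"].unique():
        mask = (aq["space_id"] == space).to_numpy()
        t = ts_all[mask]
        order = np.argsort(t, kind="stable")
        entry = {"t": t[order].astype(np.int64)}
        for var in ("pm25", "co2", "temperature", "humidity"):
            v = aq[var].to_numpy(dtype=float)[mask][order]
            entry[var] = v
            entry["cum_" + var] = np.concatenate([[0.0], np.cumsum(v)])
        spaces[str(space)] = entry

    acts = activities.copy()
    acts["start"] = pd.to_datetime(acts["start"])
    acts["end"] = pd.to_datetime(acts["end"])
    acts = acts.sort_values("start", kind="stable")
    act_start = acts["start"].to_numpy(dtype="datetime64[ns]").astype(np.int64)
    act_end = acts["end"].to_numpy(dtype="datetime64[ns]").astype(np.int64)
    act_space = acts["space_id"].astype(str).to_numpy()
    act_rate = np.array([inh.rate(a) for a in acts["activity_type"]])
    # dose only depends on (space, rate): merge back-to-back equal intervals
    if len(acts) > 1:
        new_run = (
            (act_start[1:] != act_end[:-1])
            | (act_space[1:] != act_space[:-1])
            | (act_rate[1:] != act_rate[:-1])
        )
        firsts = np.concatenate([[True], new_run])
        lasts = np.concatenate([new_run, [True]])
        act_start = act_start[firsts]
        act_end = act_end[lasts]
        act_space = act_space[firsts]
        act_rate = act_rate[firsts]

    def window_mean(var: str, lo_ns: int, hi_ns: int) -> Optional[float]:
        total, count = 0.0, 0
        for entry in spaces.values():
            i0 = int(np.searchsorted(entry["t"], lo_ns, side="left"))
            i1 = int(np.searchsorted(entry["t"], hi_ns, side="left"))
            total += entry["cum_" + var][i1] - entry["cum_" + var][i0]
            count += i1 - i0
        return total / count if count else None

    minute_ns = 60 * 1_000_000_000
    max_gap_s = max_gap_minutes * 60.0

    def window_dose(lo_ns: int, hi_ns: int) -> Tuple[Optional[float], int]:
        a_lo = int(np.searchsorted(act_end, lo_ns, side="right"))
        a_hi = int(np.searchsorted(act_start, hi_ns, side="left"))
        if a_hi <= a_lo:
            return None, 0
        dose, skipped, any_minutes = 0.0, 0, False
        for j in range(a_lo, a_hi):
            lo = max(act_start[j], lo_ns)
            hi = min(act_end[j], hi_ns)
            n_min = int((hi - lo) // minute_ns)
            if n_min <= 0:
                continue
            entry = spaces.get(act_space[j])
            if entry is None:
                log.warning("activity in unknown space %r skipped", act_space[j])
                skipped += n_min
                continue
            minutes = lo + minute_ns // 2 + minute_ns * np.arange(n_min, dtype=np.int64)
            i0 = int(np.searchsorted(entry["t"], lo_ns, side="left"))
            i1 = int(np.searchsorted(entry["t"], hi_ns, side="left"))
            conc = _minute_concentrations(
                entry["t"][i0:i1], entry["pm25"][i0:i1], minutes, max_gap_s
            )
            miss = int(np.isnan(conc).sum())
            skipped += miss
            if miss < n_min:
                any_minutes = True
            dose += float(np.nansum(conc)) * act_rate[j] / 60.0
        return (dose if any_minutes else None), skipped

    rows = []
    dates = diary.index
    for prev_date, date in zip(dates[:-1], dates[1:]):
        if (date - prev_date).days != 1:
            report.dropped_missing_pefr += 1
            continue
        am_today = diary.at[date, "am_pefr"]
        am_prev = diary.at[prev_date, "am_pefr"]
        if pd.isna(am_today) or pd.isna(am_prev):
            report.dropped_missing_pefr += 1
            continue
        t0 = _am_timestamp(prev_date, am_time)
        t1 = _am_timestamp(date, am_time)
        lo_ns, hi_ns = np.datetime64(t0).astype("datetime64[ns]").astype(np.int64), np.datetime64(
            t1
        ).astype("datetime64[ns]").astype(np.int64)
        co2 = window_mean("co2", lo_ns, hi_ns)
        temp = window_mean("temperature", lo_ns, hi_ns)
        rh = window_mean("humidity", lo_ns, hi_ns)
        if pm25_as_mean:
            pm = window_mean("pm25", lo_ns, hi_ns)
            skipped = 0
        else:
            pm, skipped = window_dose(lo_ns, hi_ns)
        report.skipped_activities += skipped
        if any(v is None for v in (pm, co2, temp, rh)):
            report.dropped_incomplete_exposure += 1
            continue
        rows.append(
            {
                "date": date,
                "pm25_exposure": pm,
                "co2_mean": co2,
                "temp_mean": temp,
                "rh_mean": rh,
                "yesterday_am_pefr": float(am_prev),
                # a missing evening value falls back to the same day's AM
                "yesterday_pm_pefr": float(
                    diary.at[prev_date, "pm_pefr"]
                    if pd.notna(diary.at[prev_date, "pm_pefr"])
                    else am_prev
                ),
                "cooking_level": float(covariates["cooking_level"]),
                "road_level": float(covariates["road_level"]),
                "income_level": float(covariates["income_level"]),
                "am_pefr": float(am_today),
            }
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        table = table.set_index("date")[FEATURE_COLUMNS + ["am_pefr"]]
    report.n_rows = len(table)
    return table, report
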