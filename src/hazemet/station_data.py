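"""Hourly station data: QC screening, gap-filling, and daily aggregation.

Hourly observations (PM2.5, PM10, temperature, wind, humidity, rain, global
radiation) are screened against physically plausible ranges, optionally
gap-filled by linear regression against a reference station, and aggregated
to daily values under a minimum-valid-fraction rule.

Hour convention: the timestamp with clock hour ``H`` (0..23) carries the
local-time hour label ``H + 1`` and covers the interval ``(H, H+1]`` LT, so
labels 1..24 span exactly one calendar day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FULL_DAY_HOURS = frozenset(range(1, 25))
#: Late-morning-to-mid-afternoon window used for global radiation.
GR_HOURS = frozenset(range(11, 17))


class Variable(str, Enum):
    PM25 = "PM25"
    PM10 = "PM10"
    T = "T"
    WS = "WS"
    WD = "WD"
    RH = "RH"
    RN = "RN"
    GR = "GR"
    P = "P"  # surface pressure (input column for the stability solver)


class QCFlag(str, Enum):
    VALID = "valid"
    OUT_OF_RANGE = "out_of_range"
    VISUALLY_FLAGGED = "visually_flagged"
    MISSING = "missing"
    FILLED = "filled"


#: Detectable limits / probable ranges per variable, closed intervals.
DEFAULT_QC_RANGES: dict[Variable, tuple[float, float]] = {
    Variable.PM25: (3.0, 1000.0),
    Variable.PM10: (3.0, 1000.0),
    Variable.T: (-5.0, 50.0),
    Variable.RH: (0.0, 100.0),
    Variable.WS: (0.0, 50.0),
    Variable.WD: (0.0, 360.0),
    Variable.RN: (0.0, 1000.0),
    Variable.GR: (0.0, 1000.0),
    Variable.P: (800.0, 1100.0),
}

VALID_LIKE = (QCFlag.VALID, QCFlag.FILLED)


@dataclass
class QCRanges:
    """Per-variable closed screening intervals."""

    ranges: dict[Variable, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_QC_RANGES)
    )

    def __post_init__(self) -> None:
        for var, (lo, hi) in self.ranges.items():
            if lo > hi:
                raise ValueError(f"range for {var}: lower {lo} > upper {hi}")

    def interval(self, variable: Variable) -> tuple[float, float]:
        try:
            return self.ranges[Variable(variable)]
        except KeyError:
            raise KeyError(f"no QC range configured for variable {variable!r}")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Iterable[float]]) -> "QCRanges":
        return cls({Variable(k): (float(v[0]), float(v[1]))  # type: ignore[index]
                    for k, v in mapping.items()})


@dataclass
class StationSeries:
    """Hourly observations of one variable at one station.

    ``values`` is a float Series on a strictly increasing hourly
    DatetimeIndex (local time); ``qc_flags`` is an aligned Series of
    :class:`QCFlag`. Out-of-range values are retained but flagged, never
    dropped.
    """

    station_id: str
    variable: Variable
    height_m: float
    values: pd.Series
    qc_flags: pd.Series

    def __post_init__(self) -> None:
        self.variable = Variable(self.variable)
        idx = self.values.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise TypeError("values must be indexed by a DatetimeIndex")
        if len(idx) > 1:
            steps = np.diff(idx.asi8)
            if not (steps > 0).all():
                raise ValueError("timestamps must be strictly increasing")
            if not (steps % 3_600_000_000_000 == 0).all():
                raise ValueError("timestamps must be hourly spaced")
        if not self.qc_flags.index.equals(idx):
            raise ValueError("qc_flags must share the values index")

    @classmethod
    def from_values(cls, station_id: str, variable: Variable | str,
                    height_m: float, values: pd.Series) -> "StationSeries":
        """Build a series, flagging NaNs missing and everything else valid."""
        values = values.astype(float)
        flags = pd.Series(
            np.where(values.isna(), QCFlag.MISSING.value, QCFlag.VALID.value),
            index=values.index, dtype=object)
        return cls(station_id, Variable(variable), height_m, values, flags)

    @property
    def valid_mask(self) -> pd.Series:
        return self.qc_flags.isin(VALID_LIKE) & self.values.notna()

    def valid_values(self) -> pd.Series:
        return self.values[self.valid_mask]


@dataclass
class DailySeries:
    """Daily aggregates with the fraction of valid hours behind each value.

    A day's value is NaN exactly when its valid fraction fell below the
    aggregation threshold.
    """

    station_id: str
    variable: Variable
    values: pd.Series          # indexed by normalized daily DatetimeIndex
    valid_fraction: pd.Series


def screen_ranges(series: StationSeries, ranges: QCRanges | None = None) -> StationSeries:
    """Flag values outside the variable's closed screening interval.

    In-range values are flagged valid; out-of-range values are kept but
    flagged ``out_of_range``; NaNs stay missing. Previously applied
    ``visually_flagged`` marks are preserved. Idempotent.
    """
    ranges = ranges or QCRanges()
    lo, hi = ranges.interval(series.variable)
    vals = series.values
    flags = series.qc_flags.copy()
    keep = flags == QCFlag.VISUALLY_FLAGGED
    in_range = (vals >= lo) & (vals <= hi)
    new = np.where(vals.isna(), QCFlag.MISSING.value,
                   np.where(in_range, QCFlag.VALID.value, QCFlag.OUT_OF_RANGE.value))
    flags = pd.Series(np.where(keep, flags, new), index=vals.index, dtype=object)
    counts = flags.value_counts()
    logger.info("screen_ranges %s/%s [%g, %g]: %s", series.station_id,
                series.variable.value, lo, hi,
                {getattr(k, "value", k): int(v) for k, v in counts.items()})
    return replace(series, qc_flags=flags)


def apply_exclusions(series: StationSeries,
                     exclusions: Iterable[pd.Timestamp]) -> StationSeries:
    """Mark listed timestamps ``visually_flagged`` (manual erratic-value list)."""
    flags = series.qc_flags.copy()
    ts = pd.DatetimeIndex(list(exclusions))
    hit = series.values.index.isin(ts)
    flags[hit] = QCFlag.VISUALLY_FLAGGED.value
    return replace(series, qc_flags=flags)


def _hour_labels(index: pd.DatetimeIndex) -> np.ndarray:
    # clock hour H covers (H, H+1] LT and carries label H+1
    return index.hour.to_numpy() + 1


def aggregate_daily(series: StationSeries,
                    window_hours: Iterable[int] = FULL_DAY_HOURS,
                    min_valid_fraction: float = 0.5) -> DailySeries:
    """Daily mean over valid values within a set of local-time hour labels.

    A day is reported missing when the count of valid in-window hours is
    below ``min_valid_fraction`` times the window size (the threshold itself
    is attainable: 12 of 24 valid hours computes a mean). Wind direction is
    averaged as unit vectors, other variables arithmetically.
    """
    window = frozenset(int(h) for h in window_hours)
    if not window:
        raise ValueError("window_hours must be non-empty")
    if not window <= FULL_DAY_HOURS:
        raise ValueError("window_hours must be a subset of 1..24")
    wsize = len(window)

    idx = series.values.index
    in_window = np.isin(_hour_labels(idx), list(window))
    days = idx.normalize()
    vals = series.values.to_numpy(float)
    ok = series.valid_mask.to_numpy() & in_window

    frame = pd.DataFrame({"day": days, "val": vals, "ok": ok, "inw": in_window})
    grouped = frame.groupby("day", sort=True)

    def _mean(g: pd.DataFrame) -> float:
        v = g.loc[g["ok"], "val"].to_numpy()
        if series.variable is Variable.WD:
            rad = np.deg2rad(v)
            ang = np.rad2deg(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean()))
            ang = float(ang % 360.0)
            return 0.0 if ang >= 360.0 else ang  # guard against round-off at the wrap
        return float(v.mean())

    out_days, out_vals, out_frac = [], [], []
    for day, g in grouped:
        if not g["inw"].any():
            continue
        n_ok = int(g["ok"].sum())
        frac = n_ok / wsize
        out_days.append(day)
        out_frac.append(frac)
        out_vals.append(_mean(g) if frac >= min_valid_fraction else np.nan)

    didx = pd.DatetimeIndex(out_days)
    return DailySeries(series.station_id, series.variable,
                       pd.Series(out_vals, index=didx, dtype=float),
                       pd.Series(out_frac, index=didx, dtype=float))


def gap_fill_linear(target: StationSeries, reference: StationSeries,
                    min_pairs: int = 100) -> StationSeries:
    """Fill missing target hours from a reference station by OLS regression.

    Fits ``target = a + b * reference`` on hours where both are valid, then
    replaces missing target hours that have a valid reference value with the
    fitted prediction, flagged ``filled``. Originally valid hours are never
    altered. Refuses (with a warning) when fewer than ``min_pairs`` paired
    valid hours exist.
    """
    common = target.values.index.intersection(reference.values.index)
    t_ok = target.valid_mask.reindex(common, fill_value=False)
    r_ok = reference.valid_mask.reindex(common, fill_value=False)
    pair = (t_ok & r_ok).to_numpy()
    if int(pair.sum()) < min_pairs:
        logger.warning("gap_fill_linear: only %d paired valid hours (< %d); not filling",
                       int(pair.sum()), min_pairs)
        return target

    x = reference.values.reindex(common).to_numpy(float)[pair]
    y = target.values.reindex(common).to_numpy(float)[pair]
    b, a = np.polyfit(x, y, 1)
    resid = y - (a + b * x)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    logger.info("gap_fill_linear %s/%s ~ %s: a=%.4g b=%.4g R2=%.4f n=%d",
                target.station_id, target.variable.value,
                reference.station_id, a, b, r2, int(pair.sum()))

    fillable = common[(~t_ok & r_ok).to_numpy()]
    values = target.values.copy()
    flags = target.qc_flags.copy()
    values.loc[fillable] = a + b * reference.values.reindex(common).loc[fillable]
    flags.loc[fillable] = QCFlag.FILLED.value
    return replace(target, values=values, qc_flags=flags)


def daily_ratio(pm25: StationSeries, pm10: StationSeries,
                min_valid_fraction: float = 0.5) -> DailySeries:
    """Daily mean of the hourly PM2.5/PM10 ratio (not the ratio of means).

    The ratio is formed only for hours where both series are valid and
    PM10 > 0; the daily mean then follows the standard valid-fraction rule
    against the full 24-hour window.
    """
    common = pm25.values.index.intersection(pm10.values.index)
    num = pm25.values.reindex(common)
    den = pm10.values.reindex(common)
    ok = (pm25.valid_mask.reindex(common, fill_value=False)
          & pm10.valid_mask.reindex(common, fill_value=False)
          & (den > 0))
    ratio = pd.Series(np.where(ok, num / den, np.nan), index=common, dtype=float)
    rser = StationSeries.from_values(pm25.station_id, Variable.PM25, pm25.height_m, ratio)
    out = aggregate_daily(rser, FULL_DAY_HOURS, min_valid_fraction)
    out.variable = Variable.PM25  # ratio series carried under the PM2.5 label
    return out


# ---------------------------------------------------------------------------
# long-format hourly CSV: timestamp, station, variable, height_m, value

def read_hourly_csv(path, missing_token: str = "NA") -> dict[tuple[str, str, float], StationSeries]:
    """Read long-format hourly CSV into StationSeries keyed by
    (station, variable, height_m)."""
    df = pd.read_csv(path, na_values=[missing_token], keep_default_na=False,
                     parse_dates=["timestamp"])
    required = {"timestamp", "station", "variable", "height_m", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"hourly CSV must have columns {sorted(required)}")
    out: dict[tuple[str, str, float], StationSeries] = {}
    for (st, var, h), g in df.groupby(["station", "variable", "height_m"]):
        vals = pd.Series(g["value"].to_numpy(float),
                         index=pd.DatetimeIndex(g["timestamp"])).sort_index()
        out[(st, var, float(h))] = StationSeries.from_values(st, Variable(var), float(h), vals)
    return out


def write_hourly_csv(series_list: Iterable[StationSeries], path,
                     missing_token: str = "NA") -> None:
    frames = []
    for s in series_list:
        frames.append(pd.DataFrame({
            "timestamp": s.values.index,
            "station": s.station_id,
            "variable": s.variable.value,
            "height_m": s.height_m,
            "value": s.values.to_numpy(),
            "qc_flag": [getattr(f, "value", f) for f in s.qc_flags],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, na_rep=missing_token)


def write_daily_csv(daily_list: Iterable[DailySeries], path,
                    missing_token: str = "NA") -> None:
    frames = []
    for d in daily_list:
        frames.append(pd.DataFrame({
            "date": d.values.index.date,
            "station": d.station_id,
            "variable": d.variable.value,
            "value": d.values.to_numpy(),
            "valid_fraction": d.valid_fraction.to_numpy(),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, na_rep=missing_token)
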