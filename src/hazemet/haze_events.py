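"""Haze-day detection and event segmentation from daily PM2.5.

A haze day is a calendar day whose daily PM2.5 reaches the exceedance
threshold (inclusive, default 50 ug m-3, the Thai daily standard) at one
station at least. A haze event is a maximal run of consecutive haze days;
episode windows tag fixed-length pre/post periods around an event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .station_data import DailySeries

HAZE_THRESHOLD = 50.0  # ug m-3 daily PM2.5


@dataclass
class HazeCalendar:
    """Per-date haze flags over one or more stations.

    ``pm25`` holds the daily PM2.5 per station (columns) on a contiguous
    daily index; ``haze_day`` is True where at least one station's
    non-missing value meets the threshold; ``indeterminate`` marks days
    where every station is missing (never counted as haze).
    """

    pm25: pd.DataFrame
    haze_day: pd.Series
    indeterminate: pd.Series
    threshold: float = HAZE_THRESHOLD


@dataclass
class HazeEvent:
    start_date: pd.Timestamp
    end_date: pd.Timestamp
    n_days: int
    peak_value: float
    peak_date: pd.Timestamp

    def __post_init__(self) -> None:
        if self.n_days != (self.end_date - self.start_date).days + 1:
            raise ValueError("n_days inconsistent with start/end dates")


@dataclass
class EpisodeWindows:
    """Pre/haze/post period labels around one event (calendar arithmetic)."""

    event: HazeEvent
    pre_days: int
    post_days: int

    @property
    def pre(self) -> pd.DatetimeIndex:
        if self.pre_days == 0:
            return pd.DatetimeIndex([])
        start = self.event.start_date - pd.Timedelta(days=self.pre_days)
        return pd.date_range(start, periods=self.pre_days, freq="D")

    @property
    def haze(self) -> pd.DatetimeIndex:
        return pd.date_range(self.event.start_date, self.event.end_date, freq="D")

    @property
    def post(self) -> pd.DatetimeIndex:
        if self.post_days == 0:
            return pd.DatetimeIndex([])
        return pd.date_range(self.event.end_date + pd.Timedelta(days=1),
                             periods=self.post_days, freq="D")

    def period_of(self, date: pd.Timestamp) -> str | None:
        date = pd.Timestamp(date).normalize()
        if date in self.pre:
            return "pre"
        if date in self.haze:
            return "haze"
        if date in self.post:
            return "post"
        return None


def detect_haze_days(daily: Sequence[DailySeries] | dict[str, DailySeries],
                     threshold: float = HAZE_THRESHOLD) -> HazeCalendar:
    """Build the haze calendar from per-station daily PM2.5.

    The exceedance is inclusive (a daily value of exactly the threshold is a
    haze day) and one exceeding station suffices. Days where all stations
    are missing are indeterminate: not haze, but distinguishable from a
    measured clean day.
    """
    if isinstance(daily, dict):
        items = list(daily.items())
    else:
        items = [(d.station_id, d) for d in daily]
    if not items:
        raise ValueError("at least one station series is required")
    pm = pd.DataFrame({name: d.values for name, d in items}).sort_index()
    pm = pm.asfreq("D") if pm.index.inferred_freq is None else pm
    haze = (pm >= threshold).any(axis=1)
    indeterminate = pm.isna().all(axis=1)
    return HazeCalendar(pm, haze, indeterminate, threshold)


def segment_events(calendar: HazeCalendar, min_length_days: int = 1,
                   bridge_indeterminate: bool = False) -> list[HazeEvent]:
    """Maximal runs of consecutive haze days, chronologically ordered.

    By default an all-missing (indeterminate) day breaks a run, which is the
    conservative reading; ``bridge_indeterminate=True`` lets indeterminate
    days inside a run connect the haze days on either side (the event then
    spans them).
    """
    if calendar.haze_day.empty:
        raise ValueError("calendar is empty")
    haze = calendar.haze_day
    dates = haze.index
    connect = haze | (calendar.indeterminate if bridge_indeterminate else False)

    events: list[HazeEvent] = []
    i, n = 0, len(dates)
    arr_haze = haze.to_numpy(bool)
    arr_conn = np.asarray(connect, bool)
    while i < n:
        if not arr_haze[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and arr_conn[j + 1]:
            j += 1
        # trim trailing bridged days: an event ends on a haze day
        while not arr_haze[j]:
            j -= 1
        run = slice(i, j + 1)
        span = pd.Series(arr_haze[run], index=dates[run])
        n_days = (dates[j] - dates[i]).days + 1
        if n_days >= min_length_days:
            pm_run = calendar.pm25.iloc[run]
            peak_per_day = pm_run.max(axis=1)
            if peak_per_day.notna().any():
                peak_date = peak_per_day.idxmax()
                peak_val = float(peak_per_day.max())
            else:
                peak_date, peak_val = dates[i], float("nan")
            events.append(HazeEvent(dates[i], dates[j], n_days, peak_val, peak_date))
        i = j + 1
    return events


def attach_windows(event: HazeEvent, pre_days: int, post_days: int) -> EpisodeWindows:
    """Label fixed-length pre and post windows adjoining the event."""
    if pre_days < 0 or post_days < 0:
        raise ValueError("pre_days and post_days must be non-negative")
    return EpisodeWindows(event, pre_days, post_days)


def events_to_frame(events: Iterable[HazeEvent]) -> pd.DataFrame:
    return pd.DataFrame([{
        "start_date": e.start_date.date(), "end_date": e.end_date.date(),
        "n_days": e.n_days, "peak_value": e.peak_value,
        "peak_date": e.peak_date.date() if pd.notna(e.peak_value) else None,
    } for e in events])
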