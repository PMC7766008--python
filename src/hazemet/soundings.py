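"""Radiosonde profiles: inversion-layer detection, scoring, classification.

A temperature inversion is a layer in which temperature increases with
height, suppressing vertical dilution of pollutants. Layers are detected as
maximal runs of consecutive sounding levels with strictly increasing
temperature below 4 km, scored by intensity

    IV = (T_top - T_bottom) / (z_top - z_bottom) * 100   [deg C per 100 m]

and kept only when IV exceeds 0.1 deg C / 100 m with the layer bottom at or
above 100 m (shallower inversions are ordinarily radiative surface cooling,
not haze-relevant). Band classification by the layer bottom: low for
100-1500 m (within the boundary layer), upper for 1500-4000 m (typically
large-scale subsidence inversions aloft).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

MAX_HEIGHT_M = 4000.0
IV_MIN = 0.1                      # deg C per 100 m, strict
LOW_BAND = (100.0, 1500.0)        # m AGL
UPPER_BAND = (1500.0, 4000.0)


@dataclass
class SoundingProfile:
    """One radiosonde ascent truncated to the lowest 4 km.

    ``levels`` has columns height_m (AGL), pressure_hPa, temperature_C and
    optionally dewpoint_C, with strictly increasing heights.
    """

    station_id: str
    valid_time: pd.Timestamp
    levels: pd.DataFrame
    elevation_m: float = 0.0     # station elevation used for MSL->AGL

    def __post_init__(self) -> None:
        req = {"height_m", "pressure_hPa", "temperature_C"}
        if not req <= set(self.levels.columns):
            raise ValueError(f"levels must have columns {sorted(req)}")
        h = self.levels["height_m"].to_numpy(float)
        if len(h) > 1 and not (np.diff(h) > 0).all():
            raise ValueError("level heights must be strictly increasing")


@dataclass
class InversionLayer:
    z_bottom: float
    z_top: float
    T_bottom: float
    T_top: float
    band: str | None = None       # "low" | "upper" after classification

    def __post_init__(self) -> None:
        if self.z_top <= self.z_bottom:
            raise ValueError("z_top must exceed z_bottom")
        if self.T_top <= self.T_bottom:
            raise ValueError("an inversion layer must warm with height")

    @property
    def depth(self) -> float:
        return self.z_top - self.z_bottom

    @property
    def iv(self) -> float:
        """Intensity in deg C per 100 m of depth."""
        return (self.T_top - self.T_bottom) / self.depth * 100.0


def detect_inversions(profile: SoundingProfile,
                      max_height_m: float = MAX_HEIGHT_M) -> list[InversionLayer]:
    """All maximal strictly-warming runs of consecutive levels below 4 km.

    An isothermal step terminates a run ("monotonically increasing" is read
    strictly; an isothermal layer has IV = 0 and would be filtered anyway).
    Returns unfiltered layers in ascending height order.
    """
    lv = profile.levels[profile.levels["height_m"] <= max_height_m]
    z = lv["height_m"].to_numpy(float)
    t = lv["temperature_C"].to_numpy(float)
    n = len(z)
    if n < 2:
        return []
    layers: list[InversionLayer] = []
    i = 0
    while i < n - 1:
        if t[i + 1] > t[i]:
            j = i + 1
            while j + 1 < n and t[j + 1] > t[j]:
                j += 1
            layers.append(InversionLayer(z[i], z[j], t[i], t[j]))
            i = j
        else:
            i += 1
    return layers


def classify_and_filter(layers: Iterable[InversionLayer],
                        iv_min: float = IV_MIN,
                        low_band: tuple[float, float] = LOW_BAND,
                        upper_band: tuple[float, float] = UPPER_BAND,
                        ) -> list[InversionLayer]:
    """Apply the intensity threshold and band classification.

    Keeps layers with IV strictly above ``iv_min`` whose bottom lies at or
    above the low band's floor; the band is assigned by the layer bottom
    (a layer straddling 1500 m is not split).
    """
    out: list[InversionLayer] = []
    for lay in layers:
        if lay.iv <= iv_min:
            continue
        if lay.z_bottom < low_band[0]:
            continue  # surface-radiative inversion, excluded
        if lay.z_bottom >= upper_band[1]:
            continue
        band = "low" if lay.z_bottom < low_band[1] else "upper"
        out.append(InversionLayer(lay.z_bottom, lay.z_top,
                                  lay.T_bottom, lay.T_top, band=band))
    return out


def episode_inversion_summary(profiles: Mapping[pd.Timestamp, SoundingProfile | None],
                              windows,
                              iv_min: float = IV_MIN) -> pd.DataFrame:
    """Per-period inversion statistics over daily (7 LT) soundings.

    For each of the pre/haze/post periods: days with at least one low-band
    layer, days with multiple low-band layers, min/max/mean IV among
    low-band layers, days with an upper-band layer, and missing-sounding
    days. ``windows`` is an :class:`~hazemet.haze_events.EpisodeWindows`.
    """
    periods = {"pre": windows.pre, "haze": windows.haze, "post": windows.post}
    rows = []
    for name, dates in periods.items():
        low_ivs: list[float] = []
        days_low = days_multi_low = days_upper = n_missing = 0
        for d in dates:
            prof = profiles.get(pd.Timestamp(d).normalize())
            if prof is None:
                n_missing += 1
                continue
            layers = classify_and_filter(detect_inversions(prof), iv_min=iv_min)
            low = [l for l in layers if l.band == "low"]
            if low:
                days_low += 1
                low_ivs.extend(l.iv for l in low)
            if len(low) > 1:
                days_multi_low += 1
            if any(l.band == "upper" for l in layers):
                days_upper += 1
        rows.append({
            "period": name,
            "n_days": len(dates),
            "n_missing": n_missing,
            "days_with_low_inversion": days_low,
            "days_with_multiple_low": days_multi_low,
            "iv_min": float(np.min(low_ivs)) if low_ivs else np.nan,
            "iv_max": float(np.max(low_ivs)) if low_ivs else np.nan,
            "iv_mean": float(np.mean(low_ivs)) if low_ivs else np.nan,
            "days_with_upper_inversion": days_upper,
        })
    return pd.DataFrame(rows).set_index("period")


# ---------------------------------------------------------------------------
# readers

_WYO_NUMERIC = ("pressure_hPa", "height_m", "temperature_C", "dewpoint_C")


def read_wyoming(text: str, station_id: str = "", valid_time=None,
                 elevation_m: float = 0.0) -> SoundingProfile:
    """Parse a Wyoming-archive-style sounding text block.

    Expects the fixed-width data table whose first four columns are
    PRES (hPa), HGHT (m MSL), TEMP (C), DWPT (C); blank fields are missing.
    Heights are converted to AGL by subtracting ``elevation_m``. Levels
    missing height or temperature are dropped.
    """
    rows = []
    in_table = False
    for line in text.splitlines():
        if line.strip() and set(line.strip()) == {"-"}:
            continue
        if line.strip().startswith("PRES") or line.strip().startswith("hPa"):
            in_table = True
            continue
        if not in_table or not line.strip():
            continue
        fields = [line[i:i + 7].strip() for i in range(0, min(len(line), 28), 7)]
        try:
            vals = [float(f) if f else np.nan for f in fields]
        except ValueError:
            continue   # station-info footer etc.
        if len(vals) < 3:
            continue
        while len(vals) < 4:
            vals.append(np.nan)
        rows.append(dict(zip(_WYO_NUMERIC, vals[:4])))
    df = pd.DataFrame(rows).dropna(subset=["height_m", "temperature_C"])
    df["height_m"] = df["height_m"] - elevation_m
    df = df[df["height_m"] >= 0].drop_duplicates(subset="height_m")
    df = df.sort_values("height_m").reset_index(drop=True)
    return SoundingProfile(station_id, pd.Timestamp(valid_time) if valid_time else pd.NaT,
                           df, elevation_m=elevation_m)


def read_sounding_csv(path, station_id: str = "", valid_time=None,
                      elevation_m: float = 0.0) -> SoundingProfile:
    """Read a simple CSV with columns height_m, pressure_hPa, temperature_C
    (dewpoint_C optional); heights AGL."""
    df = pd.read_csv(path)
    df = df.dropna(subset=["height_m", "temperature_C"])
    df = df.sort_values("height_m").reset_index(drop=True)
    return SoundingProfile(station_id, pd.Timestamp(valid_time) if valid_time else pd.NaT,
                           df, elevation_m=elevation_m)


def layers_to_frame(layers_by_day: Mapping[pd.Timestamp, Iterable[InversionLayer]]
                    ) -> pd.DataFrame:
    rows = []
    for day, layers in layers_by_day.items():
        for lay in layers:
            rows.append({"date": pd.Timestamp(day).date(),
                         "z_bottom_m": lay.z_bottom, "z_top_m": lay.z_top,
                         "T_bottom_C": lay.T_bottom, "T_top_C": lay.T_top,
                         "depth_m": lay.depth, "iv_C_per_100m": lay.iv,
                         "band": lay.band})
    return pd.DataFrame(rows)
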