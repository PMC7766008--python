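"""Synthetic inputs with the structure the haze analysis assumes.

The study's station/tower records are not publicly deposited, so every
pipeline stage is exercised on generated data that reproduces the relevant
phenomenology: a wintertime cold surge (abrupt temperature and humidity
drop, a wind-speed peak, gradual recovery) superimposed on diurnal cycles;
PM2.5 elevated above the 50 ug m-3 haze threshold during a configured haze
phase with a night/early-morning diurnal peak; sounding profiles with
implanted inversion layers of known bounds and intensity; and hotspot point
clouds. Generators are deterministic under a fixed seed and return their
ground truth alongside the data, for use as test oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import surface_layer as sl
from .soundings import SoundingProfile
from .station_data import StationSeries, Variable

HOURS_PER_DAY = 24


@dataclass
class EpisodeScenario:
    """Parameters of one synthetic haze episode.

    Defaults emulate the January 2015 Greater Bangkok episode: a 7-day
    pre-haze period, a 16-day haze event and a 4-day post period, with the
    cold surge arriving on the last pre-haze day, temperature dropping by
    ~6 C (28 -> 22 C daily mean) and humidity by ~15 % before both recover,
    and daily PM2.5 rising from ~30 to ~65 ug m-3 during the haze phase at a
    PM2.5/PM10 ratio of 0.55.
    """

    start_date: str = "2015-01-07"
    n_pre: int = 7
    n_haze: int = 16
    n_post: int = 4
    surge_day: int | None = None        # day index; default last pre day
    surge_ramp_days: int = 2
    surge_recovery_days: float = 8.0

    baseline_T: float = 28.0            # deg C daily mean
    baseline_RH: float = 65.0           # %
    baseline_WS: float = 2.0            # m s-1
    diurnal_T_amp: float = 4.0          # deg C half-range
    diurnal_RH_amp: float = 12.0
    diurnal_WS_amp: float = 0.8
    surge_dT: float = 6.0               # drop magnitude, deg C
    surge_dRH: float = 15.0             # drop magnitude, %
    surge_WS_mult: float = 1.8
    gr_peak: float = 850.0              # W m-2 clear-sky noon peak
    gr_cloud_factor: float = 0.5        # pre-surge cloudy-day scaling
    p_sfc: float = 1010.0               # hPa

    pm_baseline: float = 30.0           # ug m-3 daily mean outside haze
    pm_haze_elevation: float = 35.0     # added during the haze phase
    pm_diurnal_frac: float = 0.35       # night/morning peak amplitude
    pm_ratio: float = 0.55              # target PM2.5/PM10
    pm_stations: Sequence[str] = ("P61", "P27")
    pm_missing_blocks: Mapping[str, Sequence[tuple[int, int]]] = field(
        default_factory=dict)           # station -> [(start hour idx, length)]

    noise_T: float = 0.3
    noise_RH: float = 2.0
    noise_WS: float = 0.3
    noise_PM: float = 4.0
    noise_ratio: float = 0.03           # relative noise on PM10

    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pre, self.n_haze, self.n_post) < 1:
            raise ValueError("every phase must span at least one day")
        for name in ("noise_T", "noise_RH", "noise_WS", "noise_PM", "noise_ratio"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.surge_day is None:
            self.surge_day = self.n_pre - 1

    @property
    def n_days(self) -> int:
        return self.n_pre + self.n_haze + self.n_post

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=self.n_days, freq="D")

    @property
    def haze_dates(self) -> pd.DatetimeIndex:
        return self.dates[self.n_pre:self.n_pre + self.n_haze]

    @property
    def hourly_index(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=self.n_days * HOURS_PER_DAY,
                             freq="h")


def _surge_trend(scn: EpisodeScenario, day_frac: np.ndarray) -> np.ndarray:
    """Unit-amplitude surge signal: 0 before arrival, linear ramp to -1 over
    the ramp, then exponential relaxation back toward 0."""
    d = day_frac - scn.surge_day
    ramp = np.clip(d / scn.surge_ramp_days, 0.0, 1.0)
    rec = np.where(d > scn.surge_ramp_days,
                   np.exp(-(d - scn.surge_ramp_days) / scn.surge_recovery_days), 1.0)
    return -ramp * rec


def _surge_ws(scn: EpisodeScenario, day_frac: np.ndarray) -> np.ndarray:
    """Wind enhancement factor, peaking while the surge is active."""
    d = day_frac - scn.surge_day
    active = np.clip(d / scn.surge_ramp_days, 0.0, 1.0) * np.where(
        d > scn.surge_ramp_days,
        np.exp(-(d - scn.surge_ramp_days) / (0.5 * scn.surge_recovery_days)), 1.0)
    return 1.0 + (scn.surge_WS_mult - 1.0) * active


def gen_tower_series(scenario: EpisodeScenario
                     ) -> tuple[dict[str, StationSeries], dict]:
    """Hourly tower series: T2, T50, WS50, WS100, RH, GR, RN, P.

    Diurnal cycles (T and GR peaking mid-day, RH anti-phased) ride on the
    cold-surge step-and-recovery trend plus independent Gaussian noise. The
    2 m - 50 m temperature offset flips sign between day and night so both
    stability branches are exercised downstream. GR is a clear-sky half-sine
    over 06-18 LT, scaled down on cloudy pre-surge days.
    """
    scn = scenario
    rng = np.random.default_rng(scn.seed)
    idx = scn.hourly_index
    n = len(idx)
    hour = idx.hour.to_numpy() + 1                       # LT labels 1..24
    day_frac = np.arange(n) / HOURS_PER_DAY

    trend = _surge_trend(scn, day_frac)
    t_diurnal = scn.diurnal_T_amp * np.cos(2 * np.pi * (hour - 14) / 24)
    T2 = (scn.baseline_T + t_diurnal + scn.surge_dT * trend
          + rng.normal(0, scn.noise_T, n))
    # daytime superadiabatic (T50 < T2, unstable), nocturnal inversion
    day_mask = (hour >= 8) & (hour <= 18)
    lapse_offset = np.where(day_mask, 0.5, -0.6)
    T50 = T2 - lapse_offset + rng.normal(0, scn.noise_T, n)

    RH = np.clip(scn.baseline_RH - scn.diurnal_RH_amp *
                 np.cos(2 * np.pi * (hour - 14) / 24)
                 + scn.surge_dRH * trend + rng.normal(0, scn.noise_RH, n),
                 1.0, 100.0)

    ws_base = np.clip(scn.baseline_WS + scn.diurnal_WS_amp *
                      np.cos(2 * np.pi * (hour - 15) / 24)
                      + rng.normal(0, scn.noise_WS, n), 0.2, None)
    WS50 = ws_base * _surge_ws(scn, day_frac)
    WS100 = WS50 * 1.15 + rng.normal(0, 0.5 * scn.noise_WS, n)

    solar = np.sin(np.pi * np.clip((hour - 6) / 12, 0, 1))
    cloudy = day_frac < scn.surge_day
    GR = scn.gr_peak * solar * np.where(cloudy, scn.gr_cloud_factor, 1.0)
    RN = np.zeros(n)
    P = scn.p_sfc + 1.5 * np.cos(2 * np.pi * (hour - 10) / 12)

    def mk(name: str, var: Variable, height: float, vals: np.ndarray) -> StationSeries:
        return StationSeries.from_values("M6", var, height,
                                         pd.Series(vals, index=idx))

    data = {
        "T2": mk("T2", Variable.T, 2, T2),
        "T50": mk("T50", Variable.T, 50, T50),
        "WS50": mk("WS50", Variable.WS, 50, WS50),
        "WS100": mk("WS100", Variable.WS, 100, WS100),
        "RH": mk("RH", Variable.RH, 2, RH),
        "GR": mk("GR", Variable.GR, 2, GR),
        "RN": mk("RN", Variable.RN, 2, RN),
        "P": mk("P", Variable.P, 2, P),
    }
    truth = {
        "surge_trend_daily": scn.surge_dT *
            _surge_trend(scn, day_frac).reshape(scn.n_days, HOURS_PER_DAY).mean(axis=1),
        "dates": scn.dates,
        "surge_day": scn.surge_day,
    }
    return data, truth


def gen_pm_series(scenario: EpisodeScenario
                  ) -> tuple[dict[str, tuple[StationSeries, StationSeries]], dict]:
    """Hourly PM2.5 and PM10 per station.

    Daily-mean PM2.5 sits at the baseline outside the haze phase and at
    baseline + elevation within it; a multiplicative diurnal factor peaks at
    night/early morning (04 LT) and dips in the afternoon. PM10 follows
    PM2.5 through the target ratio with relative noise. Missing-data blocks
    (consecutive-hour outages) are applied per station if configured.
    """
    scn = scenario
    rng = np.random.default_rng(scn.seed + 1)
    idx = scn.hourly_index
    n = len(idx)
    hour = idx.hour.to_numpy() + 1
    haze_mask = idx.normalize().isin(scn.haze_dates)

    day_mean = np.where(haze_mask, scn.pm_baseline + scn.pm_haze_elevation,
                        scn.pm_baseline)
    diurnal = 1.0 + scn.pm_diurnal_frac * np.cos(2 * np.pi * (hour - 4) / 24)

    out: dict[str, tuple[StationSeries, StationSeries]] = {}
    for st in scn.pm_stations:
        pm25 = np.clip(day_mean * diurnal + rng.normal(0, scn.noise_PM, n), 3.0, None)
        pm10 = pm25 / scn.pm_ratio * (1.0 + rng.normal(0, scn.noise_ratio, n))
        pm25_s = pd.Series(pm25, index=idx)
        pm10_s = pd.Series(pm10, index=idx)
        for start, length in scn.pm_missing_blocks.get(st, ()):
            pm25_s.iloc[start:start + length] = np.nan
            pm10_s.iloc[start:start + length] = np.nan
        out[st] = (StationSeries.from_values(st, Variable.PM25, 3, pm25_s),
                   StationSeries.from_values(st, Variable.PM10, 3, pm10_s))
    truth = {
        "haze_dates": scn.haze_dates,
        "daily_pm25_mean": pd.Series(
            np.where(scn.dates.isin(scn.haze_dates),
                     scn.pm_baseline + scn.pm_haze_elevation, scn.pm_baseline),
            index=scn.dates),
        "ratio": scn.pm_ratio,
    }
    return out, truth


@dataclass
class SoundingScenario:
    """Implanted inversion layers per day over a piecewise-linear profile.

    ``layers_by_day`` maps a day index to (z_bottom, z_top, IV) triples in
    meters AGL and deg C per 100 m; outside the implants temperature falls
    at ``lapse_C_per_m``. Implants must be strictly disjoint (a shared
    boundary would merge two warming runs into one).
    """

    layers_by_day: Mapping[int, Sequence[tuple[float, float, float]]] = field(
        default_factory=dict)
    lapse_C_per_m: float = 0.0065
    level_spacing_m: float = 150.0
    surface_T: float = 26.0
    top_m: float = 4000.0
    surface_pressure: float = 1010.0
    seed: int = 0

    def __post_init__(self) -> None:
        for day, layers in self.layers_by_day.items():
            prev_top = -math.inf
            for zb, zt, iv in sorted(layers):
                if iv <= 0:
                    raise ValueError("implanted IV must be positive")
                if not 0 <= zb < zt <= self.top_m:
                    raise ValueError(f"layer ({zb}, {zt}) outside 0..{self.top_m}")
                if zb <= prev_top:
                    raise ValueError("implanted layers overlap or touch")
                prev_top = zt


def gen_sounding(scenario: SoundingScenario, day: int) -> SoundingProfile:
    """One synthetic 7 LT sounding with the day's implanted layers.

    Levels sit on the regular spacing grid plus the exact layer endpoints;
    temperature falls at the background lapse rate except inside implants,
    where it rises at the implanted intensity. With no implants the profile
    cools strictly monotonically.
    """
    scn = scenario
    layers = sorted(scn.layers_by_day.get(day, ()))
    grid = np.arange(0.0, scn.top_m + 0.5 * scn.level_spacing_m, scn.level_spacing_m)
    z = np.unique(np.concatenate([grid, [b for b, _, _ in layers],
                                  [t for _, t, _ in layers]]))
    z = z[z <= scn.top_m]

    temps = np.empty_like(z)
    T = scn.surface_T
    prev = 0.0
    temps_list = []
    for zi in z:
        seg = zi - prev
        slope = -scn.lapse_C_per_m
        for zb, zt, iv in layers:
            if zb <= prev and zi <= zt:
                slope = iv / 100.0
                break
        T = T + slope * seg
        temps_list.append(T)
        prev = zi
    temps = np.array(temps_list)

    T_mean_K = np.mean(temps) + 273.15
    pres = sl.pressure_at_height(scn.surface_pressure, z, T_mean_K)
    df = pd.DataFrame({"height_m": z, "pressure_hPa": pres,
                       "temperature_C": temps})
    return SoundingProfile("SYNTH", pd.NaT, df)


def gen_hotspots(n: int, domain: tuple[float, float, float, float],
                 dates: pd.DatetimeIndex, seed: int = 0) -> pd.DataFrame:
    """Uniform random hotspot points over a lat/lon box and a date range."""
    rng = np.random.default_rng(seed)
    lat_min, lat_max, lon_min, lon_max = domain
    return pd.DataFrame({
        "latitude": rng.uniform(lat_min, lat_max, n),
        "longitude": rng.uniform(lon_min, lon_max, n),
        "acq_date": pd.DatetimeIndex(rng.choice(dates.normalize(), n)),
        "confidence": rng.integers(0, 101, n),
    })


_ZETA_UNSTABLE_MIN = -10.0


def gen_most_consistent_sample(L_true: float, U_scale: float = 3.0,
                               const: sl.Constants | None = None,
                               z_u: float = 50.0, z_t1: float = 2.0,
                               z_t2: float = 50.0, T1: float = 25.0,
                               p_sfc: float = 1010.0) -> sl.TowerSample:
    """Invert the similarity relations: emit a dry tower sample whose exact
    Obukhov length is ``L_true``.

    With U fixed at ``U_scale``, u* follows from the wind profile relation
    at zeta = z_u/L_true, theta* from the defining relation of L, and the
    virtual-potential-temperature difference from the temperature profile
    relation; the implied 50 m temperature is emitted (RH = 0, so virtual
    temperatures equal air temperatures). Used for parameter-recovery
    checks: the forward solver applied to the sample must return L_true.
    """
    if abs(L_true) <= 1.0:
        raise ValueError("|L_true| must exceed 1 m")
    const = const or sl.Constants()
    zeta = z_u / L_true
    if not _ZETA_UNSTABLE_MIN <= zeta <= sl.ZETA_MAX:
        raise ValueError(f"zeta = {zeta:.3g} outside similarity validity")

    inv_L = 1.0 / L_true
    T1_K = T1 + 273.15
    T2_C = T1  # initial guess, refined below
    for _ in range(8):
        T_mean = 0.5 * (T1 + T2_C) + 273.15
        p1 = sl.pressure_at_height(p_sfc, z_t1, T_mean)
        p2 = sl.pressure_at_height(p_sfc, z_t2, T_mean)
        Tv1 = T1_K                       # dry air
        thv1 = sl.potential_from(Tv1, p1, const.p_ref)
        # u* from the wind profile, theta* from the definition of L
        denom_m = (math.log(z_u / const.z0)
                   - sl.psi_m(z_u * inv_L) + sl.psi_m(const.z0 * inv_L))
        u_star = const.k * U_scale / denom_m
        Tv2_guess = (T2_C + 273.15)
        Tv_mean = 0.5 * (Tv1 + Tv2_guess)
        theta_star = Tv_mean * u_star * u_star / (const.k * const.g * L_true)
        denom_h = (math.log(z_t2 / z_t1)
                   - sl.psi_h(z_t2 * inv_L) + sl.psi_h(z_t1 * inv_L))
        dthv = theta_star * denom_h / const.k
        thv2 = thv1 + dthv
        Tv2 = thv2 / (const.p_ref / p2) ** sl.KAPPA_P
        T2_new = Tv2 - 273.15
        if abs(T2_new - T2_C) < 1e-12:
            T2_C = T2_new
            break
        T2_C = T2_new
    return sl.TowerSample(U=U_scale, T1=T1, T2=T2_C, RH=0.0, p_sfc=p_sfc,
                          z_u=z_u, z_t1=z_t1, z_t2=z_t2)
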