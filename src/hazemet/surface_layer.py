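"""Obukhov length from two-level tower data via Monin-Obukhov similarity.

The surface layer's dynamic stability is summarised by the Obukhov length

    L = (1/2)(Tv1 + Tv2) u*^2 / (k g theta*)

with the friction velocity u* and temperature scale theta* given by the
integrated flux-profile relations

    u*     = k U(z_u)      / [ln(z_u/z0)  - Psi_M(z_u/L) + Psi_M(z0/L)]
    theta* = k (thv2-thv1) / [ln(z_t2/z_t1) - Psi_H(z_t2/L) + Psi_H(z_t1/L)]

where Tv and theta_v are virtual and virtual potential temperatures at the
two temperature heights, and Psi_M/Psi_H are the Businger-Dyer stability
corrections. L > 0 is stable, L < 0 unstable, |1/L| -> 0 neutral. The three
relations are mutually implicit in L and are solved by damped fixed-point
iteration from the neutral start.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

R_D = 287.05          # J kg-1 K-1, dry air gas constant
KAPPA_P = 0.2854      # R_d / c_p exponent for potential temperature
EPS_W = 0.622         # molecular weight ratio water/dry air
CELSIUS_OFFSET = 273.15

#: sentinel 1/L magnitude below which the hour is declared neutral
NEUTRAL_INV_L = 1e-6
#: calm-wind cutoff (anemometer sensitivity scale), m s-1
U_MIN = 0.1
#: stable-branch similarity validity cap on zeta = z_u/L
ZETA_MAX = 5.0


@dataclass
class Constants:
    """Physical and site constants for the similarity solver.

    ``z0`` defaults to 0.25 m — Davenport roughness class 5 ("sparsely
    built" local climate zone typical of a suburban tower site).
    """

    k: float = 0.4
    g: float = 9.81
    z0: float = 0.25
    p_ref: float = 1000.0

    def __post_init__(self) -> None:
        if min(self.k, self.g, self.z0) <= 0:
            raise ValueError("k, g, z0 must all be positive")


@dataclass
class TowerSample:
    """One hour of tower input: one-level wind, two-level temperature."""

    U: float            # m s-1 at z_u
    T1: float           # deg C at z_t1
    T2: float           # deg C at z_t2
    RH: float           # % near surface (applied at both levels)
    p_sfc: float = 1010.0  # hPa
    z_u: float = 50.0
    z_t1: float = 2.0
    z_t2: float = 50.0
    timestamp: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        if not self.z_t1 < self.z_t2:
            raise ValueError("z_t1 must be below z_t2")
        if self.U < 0:
            raise ValueError("wind speed must be non-negative")


@dataclass
class ThermoState:
    Tv1: float
    Tv2: float
    thv1: float
    thv2: float
    p1: float
    p2: float


@dataclass
class StabilityResult:
    """Solver output for one hour.

    ``L`` is +/-inf for neutral hours (the |1/L| sentinel) and NaN when no
    result exists (calm wind). ``flag`` is one of "ok", "neutral", "calm",
    "not_converged", "very_stable".
    """

    L: float
    u_star: float
    theta_star: float
    zeta: float
    converged: bool
    n_iter: int
    flag: str = "ok"

    @property
    def neutral(self) -> bool:
        return math.isinf(self.L)

    @property
    def stable(self) -> bool:
        return math.isfinite(self.L) and self.L > 0


def saturation_vapor_pressure(T: float) -> float:
    """Saturation vapor pressure over water, hPa (Bolton form), T in deg C."""
    return 6.112 * np.exp(17.67 * T / (T + 243.5))


def specific_humidity(T: float, RH: float, p: float) -> float:
    """Specific humidity (kg/kg) from T (deg C), RH (%), pressure p (hPa)."""
    e = (RH / 100.0) * saturation_vapor_pressure(T)
    if np.any(p <= e):
        raise ValueError("vapor pressure exceeds total pressure (non-physical)")
    return EPS_W * e / (p - (1.0 - EPS_W) * e)


def virtual_temperature(T: float, RH: float, p: float) -> float:
    """Virtual temperature in K from T (deg C), RH (%), p (hPa).

    Tv = T_K (1 + 0.608 q); for dry air (RH = 0) this is exactly T_K.
    """
    q = specific_humidity(T, RH, p)
    return (T + CELSIUS_OFFSET) * (1.0 + 0.608 * q)


def pressure_at_height(p_sfc: float, z: float, T_mean: float) -> float:
    """Hydrostatic pressure at height z (m) above the surface.

    p(z) = p_sfc exp(-g z / (R_d T_mean)), with T_mean the layer-mean
    temperature in K.
    """
    if np.any(np.asarray(z) < 0):
        raise ValueError("height must be non-negative")
    return p_sfc * np.exp(-9.81 * z / (R_D * T_mean))


def potential_from(Tv: float, p: float, p_ref: float = 1000.0) -> float:
    """Virtual potential temperature: theta_v = Tv (p_ref/p)^0.2854."""
    return Tv * (p_ref / p) ** KAPPA_P


def psi_m(zeta):
    """Integrated Businger-Dyer stability correction for momentum.

    Unstable (zeta < 0), Paulson form with gamma = 16; stable, linear -5 zeta.
    """
    zeta = np.asarray(zeta, dtype=float)
    out = np.where(zeta >= 0, -5.0 * zeta, 0.0)
    neg = zeta < 0
    if np.any(neg):
        x = (1.0 - 16.0 * zeta[neg]) ** 0.25
        out = out.astype(float)
        out[neg] = (2.0 * np.log((1.0 + x) / 2.0) + np.log((1.0 + x * x) / 2.0)
                    - 2.0 * np.arctan(x) + np.pi / 2.0)
    return out if out.ndim else float(out)


def psi_h(zeta):
    """Integrated Businger-Dyer stability correction for heat."""
    zeta = np.asarray(zeta, dtype=float)
    out = np.where(zeta >= 0, -5.0 * zeta, 0.0)
    neg = zeta < 0
    if np.any(neg):
        x2 = np.sqrt(1.0 - 16.0 * zeta[neg])
        out = out.astype(float)
        out[neg] = 2.0 * np.log((1.0 + x2) / 2.0)
    return out if out.ndim else float(out)


def thermo_state(sample: TowerSample, const: Constants | None = None) -> ThermoState:
    """Virtual (potential) temperatures and pressures at the two heights.

    The surface pressure is adjusted hydrostatically to each measurement
    height; the near-surface RH is applied at both levels (single-level
    humidity measurement).
    """
    const = const or Constants()
    T_mean = 0.5 * (sample.T1 + sample.T2) + CELSIUS_OFFSET
    p1 = pressure_at_height(sample.p_sfc, sample.z_t1, T_mean)
    p2 = pressure_at_height(sample.p_sfc, sample.z_t2, T_mean)
    Tv1 = virtual_temperature(sample.T1, sample.RH, p1)
    Tv2 = virtual_temperature(sample.T2, sample.RH, p2)
    return ThermoState(Tv1, Tv2,
                       potential_from(Tv1, p1, const.p_ref),
                       potential_from(Tv2, p2, const.p_ref), p1, p2)


def _u_star(U: float, z_u: float, z0: float, k: float, inv_L: float) -> float:
    denom = math.log(z_u / z0) - psi_m(z_u * inv_L) + psi_m(z0 * inv_L)
    return k * U / denom


def _theta_star(dthv: float, z1: float, z2: float, k: float, inv_L: float) -> float:
    denom = math.log(z2 / z1) - psi_h(z2 * inv_L) + psi_h(z1 * inv_L)
    return k * dthv / denom


def obukhov_from_scales(Tv_mean: float, u_star: float, theta_star: float,
                        const: Constants) -> float:
    """L from the defining relation given u* and theta*."""
    return Tv_mean * u_star * u_star / (const.k * const.g * theta_star)


def solve_obukhov(sample: TowerSample, const: Constants | None = None,
                  tol: float = 1e-4, max_iter: int = 50) -> StabilityResult:
    """Iteratively solve the coupled similarity relations for one hour.

    Damped fixed-point iteration on 1/L from the neutral start: with the
    current 1/L, evaluate u* and theta* from the profile relations, update
    1/L from the defining relation, and repeat until the relative change in
    L is below ``tol``. A sign flip of successive updates triggers 0.5
    damping on 1/L (the stable-branch linear correction can overshoot).

    Near-neutral short circuits: |thv2 - thv1| < 0.001 K, or the iterate
    reaching |1/L| < 1e-6 m-1, return the neutral closed form
    u* = k U / ln(z_u/z0). Calm hours (U < 0.1 m s-1) return no result.
    Converged stable hours with zeta = z_u/L > 5 are flagged "very_stable"
    (outside similarity validity) and should be excluded from statistics.
    """
    const = const or Constants()
    if sample.U < U_MIN:
        return StabilityResult(math.nan, math.nan, math.nan, math.nan,
                               False, 0, flag="calm")
    state = thermo_state(sample, const)
    dthv = state.thv2 - state.thv1
    Tv_mean = 0.5 * (state.Tv1 + state.Tv2)
    u_star_neutral = const.k * sample.U / math.log(sample.z_u / const.z0)

    def neutral(n_iter: int) -> StabilityResult:
        L = math.copysign(math.inf, dthv) if dthv != 0 else math.inf
        return StabilityResult(L, u_star_neutral, 0.0, 0.0, True, n_iter,
                               flag="neutral")

    if abs(dthv) < 1e-3:
        return neutral(0)

    x = 0.0                 # iterate on 1/L
    prev_dx = 0.0
    for it in range(1, max_iter + 1):
        us = _u_star(sample.U, sample.z_u, const.z0, const.k, x)
        ts = _theta_star(dthv, sample.z_t1, sample.z_t2, const.k, x)
        L_new = obukhov_from_scales(Tv_mean, us, ts, const)
        x_new = 1.0 / L_new
        dx = x_new - x
        if prev_dx != 0.0 and dx * prev_dx < 0:
            x_new = x + 0.5 * dx   # damp oscillation
            dx = x_new - x
        if abs(x_new) < NEUTRAL_INV_L:
            return neutral(it)
        rel = abs(dx) / abs(x_new)
        x, prev_dx = x_new, dx
        if rel < tol:
            us = _u_star(sample.U, sample.z_u, const.z0, const.k, x)
            ts = _theta_star(dthv, sample.z_t1, sample.z_t2, const.k, x)
            zeta = sample.z_u * x
            flag = "very_stable" if zeta > ZETA_MAX else "ok"
            return StabilityResult(1.0 / x, us, ts, zeta, True, it, flag=flag)

    zeta = sample.z_u * x
    return StabilityResult(math.nan, math.nan, math.nan, zeta, False, max_iter,
                           flag="not_converged")


def solve_hourly(samples: Iterable[TowerSample],
                 const: Constants | None = None, **kw) -> pd.DataFrame:
    """Solve a sequence of hourly samples into a tidy result frame."""
    rows = []
    for s in samples:
        r = solve_obukhov(s, const, **kw)
        rows.append({"timestamp": s.timestamp, "L": r.L, "u_star": r.u_star,
                     "theta_star": r.theta_star, "zeta": r.zeta,
                     "converged": r.converged, "n_iter": r.n_iter, "flag": r.flag})
    df = pd.DataFrame(rows)
    if df["timestamp"].notna().any():
        df = df.set_index("timestamp")
    return df


def combine_dual_heights(L50: pd.Series, L100: pd.Series
                         ) -> tuple[pd.Series, float]:
    """Average per-hour L from the two wind heights; report their agreement.

    The Pearson correlation is computed over hours where both solutions are
    finite (neutral sentinels and failures excluded). The combined value is
    the per-hour mean over the finite members; an hour with one finite
    member takes that member; a neutral pair stays neutral.
    """
    idx = L50.index.union(L100.index)
    a = L50.reindex(idx).astype(float)
    b = L100.reindex(idx).astype(float)
    fin_a, fin_b = np.isfinite(a), np.isfinite(b)
    both = fin_a & fin_b
    if int(both.sum()) >= 2:
        corr = float(np.corrcoef(a[both], b[both])[0, 1])
    else:
        logger.warning("combine_dual_heights: <2 paired finite hours; "
                       "correlation undefined")
        corr = math.nan

    combined = pd.Series(np.nan, index=idx, dtype=float)
    combined[both] = 0.5 * (a[both] + b[both])
    only_a = fin_a & ~fin_b
    only_b = fin_b & ~fin_a
    combined[only_a] = a[only_a]
    combined[only_b] = b[only_b]
    combined[np.isinf(a) & np.isinf(b)] = np.inf
    combined[np.isinf(a) & b.isna()] = np.inf
    combined[np.isinf(b) & a.isna()] = np.inf
    return combined, corr


def daytime_unstable_fraction(results: pd.DataFrame,
                              hours: Iterable[int] = range(10, 17)) -> pd.Series:
    """Per-day fraction of converged daytime hours (default 10-16 LT) that
    are unstable (L < 0)."""
    if not isinstance(results.index, pd.DatetimeIndex):
        raise TypeError("results must be indexed by timestamp")
    hrs = set(int(h) for h in hours)
    day_mask = results.index.hour.isin(hrs)
    sub = results[day_mask & results["converged"]]
    finite = np.isfinite(sub["L"])
    grp = sub[finite].groupby(sub.index[finite].normalize())
    return grp["L"].apply(lambda s: float((s < 0).mean()))
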