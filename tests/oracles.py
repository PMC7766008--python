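"""Independent oracles used by the test suite.

Deliberately naive implementations (dense scans, per-point loops,
quadrature) kept separate from the library code paths they check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from hazemet import surface_layer as sl


def scan_obukhov(sample: sl.TowerSample, const: sl.Constants | None = None,
                 n_grid: int = 40001):
    """Obukhov length by dense residual scan over 1/L in [-1, 1] m^-1.

    Evaluates the self-consistency residual r(x) = x - 1/L_implied(x) of the
    defining relation on a dense grid restricted to the physically
    consistent sign (sign(L) = sign(dtheta_v)), refines the best bracket
    with Brent's method. Returns +/-inf (neutral) when the temperature
    difference is negligible, NaN when no root exists in the scan range.
    """
    const = const or sl.Constants()
    state = sl.thermo_state(sample, const)
    dthv = state.thv2 - state.thv1
    Tv_mean = 0.5 * (state.Tv1 + state.Tv2)
    if abs(dthv) < 1e-3:
        return math.inf

    def inv_L_implied(x):
        us = const.k * sample.U / (np.log(sample.z_u / const.z0)
                                   - sl.psi_m(sample.z_u * x)
                                   + sl.psi_m(const.z0 * x))
        ts = const.k * dthv / (np.log(sample.z_t2 / sample.z_t1)
                               - sl.psi_h(sample.z_t2 * x)
                               + sl.psi_h(sample.z_t1 * x))
        return const.k * const.g * ts / (Tv_mean * us * us)

    def resid(x):
        return x - inv_L_implied(x)

    if dthv > 0:
        grid = np.linspace(1e-9, 1.0, n_grid)
    else:
        grid = np.linspace(-1.0, -1e-9, n_grid)
    r = resid(grid)
    finite = np.isfinite(r)
    grid, r = grid[finite], r[finite]
    sign_change = np.nonzero(np.diff(np.sign(r)) != 0)[0]
    if len(sign_change) == 0:
        return math.nan
    # bracket with the smallest residual magnitude
    best = sign_change[np.argmin(np.abs(r[sign_change]))]
    root = brentq(resid, grid[best], grid[best + 1], xtol=1e-14)
    if abs(root) < sl.NEUTRAL_INV_L:
        return math.inf
    return 1.0 / root


def psi_m_quadrature(zeta: float) -> float:
    """Psi_M by numerical integration of the Businger-Dyer phi_m.

    Psi(zeta) = int_0^zeta [1 - phi_m(x)] / x dx, phi_m = (1-16x)^(-1/4)
    unstable, 1 + 5x stable.
    """
    def integrand(x):
        if x == 0:
            return -4.0 if zeta < 0 else -5.0
        phi = (1 - 16 * x) ** -0.25 if x < 0 else 1 + 5 * x
        return (1 - phi) / x
    val, _ = quad(integrand, 0, zeta, limit=200)
    return val


def psi_h_quadrature(zeta: float) -> float:
    """Psi_H by quadrature of phi_h = (1-16x)^(-1/2) unstable, 1+5x stable."""
    def integrand(x):
        if x == 0:
            return -8.0 if zeta < 0 else -5.0
        phi = (1 - 16 * x) ** -0.5 if x < 0 else 1 + 5 * x
        return (1 - phi) / x
    val, _ = quad(integrand, 0, zeta, limit=200)
    return val


def naive_segment(haze: np.ndarray) -> list[tuple[int, int]]:
    """Day-by-day scan for maximal runs of True; (start, end) index pairs."""
    runs = []
    start = None
    for i, h in enumerate(haze):
        if h and start is None:
            start = i
        elif not h and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(haze) - 1))
    return runs


def brute_grid_count(lats, lons, lat0, lon0, cell, nlat, nlon) -> np.ndarray:
    """Per-point loop gridding with explicit half-open interval tests."""
    counts = np.zeros((nlat, nlon), dtype=int)
    for lat, lon in zip(lats, lons):
        for i in range(nlat):
            if not (lat0 + i * cell <= lat < lat0 + (i + 1) * cell):
                continue
            for j in range(nlon):
                if lon0 + j * cell <= lon < lon0 + (j + 1) * cell:
                    counts[i, j] += 1
    return counts


def sample_from_dthv(U: float, dthv: float, T1: float = 25.0,
                     p_sfc: float = 1010.0,
                     const: sl.Constants | None = None) -> sl.TowerSample:
    """Dry tower sample with a prescribed virtual-potential-temperature
    difference between the two heights (inverts the potential-temperature
    conversion for the upper level)."""
    const = const or sl.Constants()
    z1, z2 = 2.0, 50.0
    T2 = T1  # refine: p depends weakly on T2
    for _ in range(6):
        T_mean = 0.5 * (T1 + T2) + 273.15
        p1 = sl.pressure_at_height(p_sfc, z1, T_mean)
        p2 = sl.pressure_at_height(p_sfc, z2, T_mean)
        thv1 = sl.potential_from(T1 + 273.15, p1, const.p_ref)
        Tv2 = (thv1 + dthv) / (const.p_ref / p2) ** sl.KAPPA_P
        T2 = Tv2 - 273.15
    return sl.TowerSample(U=U, T1=T1, T2=T2, RH=0.0, p_sfc=p_sfc)
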