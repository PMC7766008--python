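"""Gridding of satellite active-fire hotspots by episode period.

Daily MODIS-style hotspot detections (point latitude/longitude/date) are
summed onto a regular 0.5-degree grid separately for the pre-haze, haze and
post-haze periods of an episode. Cells are half-open ([edge, edge + cell))
with edges anchored at multiples of the cell size, so every in-domain point
lands in exactly one cell and the grid sum equals the in-domain point count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_CELL_DEG = 0.5


@dataclass
class GriddedCounts:
    """Per-cell hotspot counts for one episode period.

    ``counts[i, j]`` covers latitudes [lat0 + i*cell, lat0 + (i+1)*cell) and
    longitudes [lon0 + j*cell, lon0 + (j+1)*cell).
    """

    period: str
    lat0: float
    lon0: float
    cell: float
    counts: np.ndarray    # (nlat, nlon) int

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        ii, jj = np.nonzero(self.counts)
        return pd.DataFrame({
            "period": self.period,
            "lat_edge": self.lat0 + ii * self.cell,
            "lon_edge": self.lon0 + jj * self.cell,
            "count": self.counts[ii, jj],
        })


def read_hotspot_csv(path) -> pd.DataFrame:
    """Read an MCD14ML-style CSV with latitude, longitude, acq_date columns."""
    df = pd.read_csv(path, parse_dates=["acq_date"])
    req = {"latitude", "longitude", "acq_date"}
    if not req <= set(df.columns):
        raise ValueError(f"hotspot CSV must have columns {sorted(req)}")
    bad = (~df["latitude"].between(-90, 90)) | (~df["longitude"].between(-180, 180))
    if bad.any():
        raise ValueError(f"{int(bad.sum())} hotspot(s) with out-of-range coordinates")
    return df


def grid_hotspots(points: pd.DataFrame, windows,
                  domain: tuple[float, float, float, float],
                  cell: float = DEFAULT_CELL_DEG) -> dict[str, GriddedCounts]:
    """Count hotspots per 0.5-degree cell per episode period.

    ``domain`` is (lat_min, lat_max, lon_min, lon_max); ``windows`` an
    :class:`~hazemet.haze_events.EpisodeWindows`. Points outside the domain
    or outside all three periods are dropped (counts logged).
    """
    if cell <= 0:
        raise ValueError("cell size must be positive")
    lat_min, lat_max, lon_min, lon_max = domain
    if not (lat_min < lat_max and lon_min < lon_max):
        raise ValueError("domain box is empty or inverted")

    lat0 = math.floor(lat_min / cell) * cell
    lon0 = math.floor(lon_min / cell) * cell
    nlat = max(1, math.ceil((lat_max - lat0) / cell))
    nlon = max(1, math.ceil((lon_max - lon0) / cell))

    lat = points["latitude"].to_numpy(float)
    lon = points["longitude"].to_numpy(float)
    dates = pd.DatetimeIndex(points["acq_date"]).normalize()

    i = np.floor((lat - lat0) / cell).astype(int)
    j = np.floor((lon - lon0) / cell).astype(int)
    in_dom = (i >= 0) & (i < nlat) & (j >= 0) & (j < nlon)

    out: dict[str, GriddedCounts] = {}
    n_out_period = 0
    periods = {"pre": windows.pre, "haze": windows.haze, "post": windows.post}
    assigned = np.zeros(len(points), dtype=bool)
    for name, pdates in periods.items():
        in_period = dates.isin(pdates)
        assigned |= np.asarray(in_period)
        sel = in_dom & in_period
        counts = np.zeros((nlat, nlon), dtype=int)
        np.add.at(counts, (i[sel], j[sel]), 1)
        out[name] = GriddedCounts(name, lat0, lon0, cell, counts)
    n_out_period = int((~assigned).sum())
    logger.info("grid_hotspots: %d points, %d out-of-domain, %d outside all periods",
                len(points), int((~in_dom).sum()), n_out_period)
    return out
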