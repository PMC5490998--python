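"""Combine geolocation confidence ellipses with surface-association probability.

Each light-based position estimate carries an axis-aligned 95% confidence
ellipse (axes along meridians/parallels).  Every ellipse inherits the
surface-association probability of the temporally closest 3-hour bin, is
discretised onto a 0.1-degree grid by cell-centre containment, and all
(ellipse, cell) observations are averaged per map cell with equal weight
per observation — not per fish.

The grid is registered with cell edges at multiples of the cell size from
the 0-degree meridian/equator; longitudes are normalised to [0, 360) so the
study region around the antimeridian stays contiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import SurfaceAssociationSeries

logger = logging.getLogger("surfassoc")


@dataclass
class ProbabilityEllipse:
    """Axis-aligned confidence ellipse carrying one probability value."""

    fish_id: str
    time: pd.Timestamp
    lon: float                  # centre, degrees in [0, 360)
    lat: float
    semi_lon: float             # semi-axis, degrees (> 0)
    semi_lat: float
    probability: float

    def __post_init__(self) -> None:
        if self.semi_lon <= 0 or self.semi_lat <= 0:
            raise ValueError("ellipse semi-axes must be positive")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability outside [0, 1]")
        self.lon = float(np.mod(self.lon, 360.0))

    def contains(self, lon: float | np.ndarray,
                 lat: float | np.ndarray) -> np.ndarray:
        """Point-in-ellipse test (boundary inclusive)."""
        return (((np.asarray(lon) - self.lon) / self.semi_lon) ** 2
                + ((np.asarray(lat) - self.lat) / self.semi_lat) ** 2) <= 1.0


@dataclass
class RasterizedEllipse:
    """Grid cells claimed by one ellipse (cell-centre containment)."""

    ix: np.ndarray              # integer cell column indices (lon / cell)
    iy: np.ndarray
    probability: float


def attach_probability(estimates: pd.DataFrame, sa: SurfaceAssociationSeries,
                       *, bin_hours: float = 3.0) -> list[ProbabilityEllipse]:
    """Pair each geolocation estimate with the nearest defined bin's probability.

    ``estimates`` needs columns time, lon, lat, ci_lon, ci_lat (full 95% CI
    widths, degrees).  Ties between two equidistant bin centres resolve to
    the earlier bin.  Estimates farther than ``bin_hours``/2 outside the
    span of defined bins are dropped with a warning; no overlap at all is
    an error.
    """
    defined = np.flatnonzero(sa.defined)
    if len(defined) == 0:
        raise ValueError("surface-association series has no defined bins")
    half_bin_ns = sa.bin_hours / 2.0 * 3.6e12
    centers = (sa.bin_starts[defined].asi8.astype(np.float64) + half_bin_ns)
    # span of defined bins, padded by half a bin
    lo = centers[0] - half_bin_ns
    hi = centers[-1] + half_bin_ns
    out: list[ProbabilityEllipse] = []
    n_dropped = 0
    for row in estimates.itertuples(index=False):
        t = pd.Timestamp(row.time).value
        if t < lo - half_bin_ns or t > hi + half_bin_ns:  # > bin/2 outside span
            n_dropped += 1
            continue
        # earlier bin wins ties: searchsorted on midpoints between centres
        pos = int(np.searchsorted((centers[:-1] + centers[1:]) / 2.0, t,
                                  side="left"))
        prob = float(sa.values[defined[pos]])
        out.append(ProbabilityEllipse(
            fish_id=str(row.fish_id) if hasattr(row, "fish_id") else sa.fish_id,
            time=pd.Timestamp(row.time),
            lon=float(row.lon), lat=float(row.lat),
            semi_lon=float(row.ci_lon) / 2.0,
            semi_lat=float(row.ci_lat) / 2.0,
            probability=prob,
        ))
    if n_dropped:
        logger.warning("dropped %d estimate(s) outside the defined "
                       "surface-association span", n_dropped)
    if not out:
        raise ValueError("no temporal overlap between estimates and "
                         "surface-association series")
    return out


def rasterize(ellipse: ProbabilityEllipse, cell_deg: float = 0.1,
              *, full_width: bool = True) -> RasterizedEllipse:
    """Cells whose centre lies inside or on the ellipse.

    ``full_width=False`` treats the stored semi-axes as full axis lengths
    instead (i.e. halves them), for the alternative reading of CI widths.
    An ellipse smaller than one cell still claims the cell containing its
    centre.
    """
    a, b = ellipse.semi_lon, ellipse.semi_lat
    if not full_width:
        a, b = a / 2.0, b / 2.0
    ix_min = int(np.floor((ellipse.lon - a) / cell_deg))
    ix_max = int(np.floor((ellipse.lon + a) / cell_deg))
    iy_min = int(np.floor((ellipse.lat - b) / cell_deg))
    iy_max = int(np.floor((ellipse.lat + b) / cell_deg))
    ix = np.arange(ix_min, ix_max + 1)
    iy = np.arange(iy_min, iy_max + 1)
    cx = (ix + 0.5) * cell_deg
    cy = (iy + 0.5) * cell_deg
    inside = (((cx[:, None] - ellipse.lon) / a) ** 2
              + ((cy[None, :] - ellipse.lat) / b) ** 2) <= 1.0
    gx, gy = np.nonzero(inside)
    if len(gx) == 0:
        gx = np.array([int(np.floor(ellipse.lon / cell_deg)) - ix_min])
        gy = np.array([int(np.floor(ellipse.lat / cell_deg)) - iy_min])
    return RasterizedEllipse(ix=ix[gx], iy=iy[gy],
                             probability=ellipse.probability)


@dataclass
class ProbabilityRaster:
    """Per-cell running sum/count of probabilities and their mean."""

    cell_deg: float
    ix: np.ndarray
    iy: np.ndarray
    prob_sum: np.ndarray
    count: np.ndarray

    @property
    def mean(self) -> np.ndarray:
        return self.prob_sum / self.count

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy gridded table: cell-centre lon/lat, mean probability, count."""
        df = pd.DataFrame({
            "lon": (self.ix + 0.5) * self.cell_deg,
            "lat": (self.iy + 0.5) * self.cell_deg,
            "mean_probability": self.mean,
            "n_obs": self.count,
        })
        return df.sort_values(["lon", "lat"], ignore_index=True)


def combine(cells: list[RasterizedEllipse],
            cell_deg: float = 0.1) -> ProbabilityRaster:
    """Average all (ellipse, cell) observations per map cell.

    Every observation has equal weight regardless of which fish it came
    from; per-cell counts are retained so low-support cells can be masked
    downstream.  Accumulation is streaming (sum, count) and exactly
    conserves total probability mass: sum(mean * count) equals the summed
    probability of all contributing observations.
    """
    if not cells:
        raise ValueError("no rasterized ellipses to combine")
    acc: dict[tuple[int, int], tuple[float, int]] = {}
    for rc in cells:
        p = rc.probability
        for x, y in zip(rc.ix.tolist(), rc.iy.tolist()):
            s, c = acc.get((x, y), (0.0, 0))
            acc[(x, y)] = (s + p, c + 1)
    keys = sorted(acc)
    ix = np.array([k[0] for k in keys], dtype=np.int64)
    iy = np.array([k[1] for k in keys], dtype=np.int64)
    sums = np.array([acc[k][0] for k in keys])
    counts = np.array([acc[k][1] for k in keys], dtype=np.int64)
    return ProbabilityRaster(cell_deg=cell_deg, ix=ix, iy=iy,
                             prob_sum=sums, count=counts)
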