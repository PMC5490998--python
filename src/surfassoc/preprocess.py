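"""Eligibility screening and 3-hour binning of raw tag series.

The behavioural observation model is bivariate: within each 3-hour period
the standard deviation of depth measures diving amplitude and the mean
ambient water temperature measures thermal habitat.  Bins are laid on a
contiguous grid anchored at 00:00 UTC of the release day; under-covered
bins are kept on the grid but flagged invalid so downstream smoothing can
bridge them as missing observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tags import TagRecordSeries


@dataclass
class EligibilityResult:
    eligible: bool
    reasons: list[str]
    span_days: float
    max_gap_hours: float


def screen_eligibility(series: TagRecordSeries, min_days: float = 30.0,
                       max_gap_hours: float = 1.0) -> EligibilityResult:
    """Check a series against the deployment-quality rules.

    A series is eligible when it spans at least ``min_days`` and contains no
    inter-sample gap longer than ``max_gap_hours``.
    """
    ts = series.samples["timestamp"]
    if len(ts) == 0:
        raise ValueError("empty series")
    span = series.span_days
    gaps = ts.diff().dropna().dt.total_seconds().to_numpy() / 3600.0
    worst = float(gaps.max()) if len(gaps) else 0.0
    reasons = []
    if span < min_days:
        reasons.append(f"span < {min_days:g} days ({span:.2f} d)")
    if worst > max_gap_hours:
        reasons.append(f"gap > {max_gap_hours:g} h ({worst:.2f} h)")
    return EligibilityResult(not reasons, reasons, span, worst)


@dataclass
class BinnedSeries:
    """Contiguous fixed-width bins of (diving amplitude, thermal habitat)."""

    fish_id: str
    bin_starts: pd.DatetimeIndex     # contiguous, bin_hours apart
    depth_sd: np.ndarray             # m, NaN where invalid
    temp_mean: np.ndarray            # degC, NaN where invalid
    n_samples: np.ndarray
    valid: np.ndarray                # bool mask
    bin_hours: float = 3.0

    def __post_init__(self) -> None:
        n = len(self.bin_starts)
        if not (len(self.depth_sd) == len(self.temp_mean)
                == len(self.n_samples) == len(self.valid) == n):
            raise ValueError("binned arrays must share one length")
        if n > 1:
            step = pd.Timedelta(hours=self.bin_hours)
            if not (self.bin_starts[1:] - self.bin_starts[:-1] == step).all():
                raise ValueError("bin grid is not contiguous")
        if np.any(self.depth_sd[self.valid] < 0):
            raise ValueError("negative depth SD")

    def __len__(self) -> int:
        return len(self.bin_starts)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def observations(self) -> np.ndarray:
        """(T, 2) array of (depth_sd, temp_mean); NaN rows where invalid."""
        return np.column_stack([self.depth_sd, self.temp_mean])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "fish_id": self.fish_id,
            "bin_start": self.bin_starts,
            "depth_sd": self.depth_sd,
            "temp_mean": self.temp_mean,
            "n_samples": self.n_samples,
            "valid": self.valid,
        })


def bin_series(series: TagRecordSeries, bin_hours: float = 3.0,
               coverage_floor: float = 0.5,
               anchor: pd.Timestamp | None = None) -> BinnedSeries:
    """Reduce a raw series to the bivariate binned observation model.

    Parameters
    ----------
    bin_hours
        Bin width; the default 3 h gives eight bins per day.
    coverage_floor
        Minimum fraction of the expected per-bin sample count (from the
        series' median sampling interval) for a bin to count as valid.
        Bins with fewer than two samples are always invalid because the
        sample standard deviation (n-1 denominator) is undefined.
    anchor
        Grid origin; defaults to 00:00 UTC on the release day (or the
        first sample's day when release metadata is absent).
    """
    df = series.samples
    ts = df["timestamp"]
    if anchor is None:
        ref = series.metadata.release_time
        if ref is None:
            ref = ts.iloc[0]
        anchor = pd.Timestamp(ref).floor("D")

    width = pd.Timedelta(hours=bin_hours)
    idx = ((ts - anchor) // width).astype(np.int64)
    first, last = int(idx.iloc[0]), int(idx.iloc[-1])
    n_bins = last - first + 1

    depth_sd = np.full(n_bins, np.nan)
    temp_mean = np.full(n_bins, np.nan)
    n_samples = np.zeros(n_bins, dtype=np.int64)

    grouped = df.groupby((idx - first).to_numpy())
    counts = grouped.size()
    n_samples[counts.index.to_numpy()] = counts.to_numpy()
    sd = grouped["depth_m"].std(ddof=1)          # NaN for n<2
    tm = grouped["temp_c"].mean()
    depth_sd[sd.index.to_numpy()] = sd.to_numpy()
    temp_mean[tm.index.to_numpy()] = tm.to_numpy()

    expected = bin_hours * 3600.0 / series.median_interval_s()
    valid = (n_samples >= max(2, int(np.ceil(coverage_floor * expected))))
    valid &= ~np.isnan(depth_sd) & ~np.isnan(temp_mean)
    depth_sd[~valid] = np.nan
    temp_mean[~valid] = np.nan

    starts = anchor + width * np.arange(first, last + 1)
    return BinnedSeries(series.fish_id, pd.DatetimeIndex(starts), depth_sd,
                        temp_mean, n_samples, valid, bin_hours=bin_hours)
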