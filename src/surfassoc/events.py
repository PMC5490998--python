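"""Surface-association probability, events, and per-fish summary metrics.

The surface-association probability is a 24-hour (eight-bin) running mean
of the smoothed shallow-state probability.  Sustained intervals with this
probability above a threshold (default 0.75) are surface-association
events; diel vertical switching (12 h shallow / 12 h deep) sits at 0.5 and
therefore never triggers the default threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hmm import StatePosteriors
from .io_tags import TagMetadata

HOURS_PER_DAY = 24.0


# ---------------------------------------------------------------------------
# Surface-association probability
# ---------------------------------------------------------------------------

@dataclass
class SurfaceAssociationSeries:
    """Running-mean shallow-state probability on the contiguous bin grid.

    ``values`` is NaN where the running window does not fully lie inside
    the series (the first ``window_bins - 1`` bins for the default trailing
    alignment).  The underlying smoothed posterior is retained.
    """

    fish_id: str
    bin_starts: pd.DatetimeIndex
    values: np.ndarray
    p_shallow: np.ndarray
    window_bins: int
    bin_hours: float
    centered: bool = False

    def __post_init__(self) -> None:
        vals = self.values[~np.isnan(self.values)]
        if np.any((vals < -1e-12) | (vals > 1 + 1e-12)):
            raise ValueError("surface-association probabilities outside [0, 1]")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def bin_end(self, i: int) -> pd.Timestamp:
        return self.bin_starts[i] + pd.Timedelta(hours=self.bin_hours)


def surface_association(posteriors: StatePosteriors, window_bins: int = 8,
                        *, centered: bool = False,
                        fish_id: str = "") -> SurfaceAssociationSeries:
    """Running mean of P(shallow) over ``window_bins`` bins.

    The default trailing alignment assigns to bin t the mean over the
    window *ending* at t (bins t-window_bins+1 .. t), so an event is
    declared only after a full day of accumulated shallow behaviour.  With
    ``centered=True`` the window covers t-ceil(w/2)+1 .. t+floor(w/2).
    """
    p = np.asarray(posteriors.p_shallow, dtype=float)
    T = len(p)
    if T < window_bins:
        raise ValueError(f"series of {T} bins shorter than window {window_bins}")
    sliding = np.lib.stride_tricks.sliding_window_view(p, window_bins).mean(axis=1)
    values = np.full(T, np.nan)
    if centered:
        lead = (window_bins - 1) // 2 + (window_bins - 1) % 2  # ceil((w-1)/2)
        values[lead:lead + len(sliding)] = sliding
    else:
        values[window_bins - 1:] = sliding

    starts = pd.DatetimeIndex(posteriors.bin_starts)
    bin_hours = 3.0
    if len(starts) > 1:
        bin_hours = (starts[1] - starts[0]).total_seconds() / 3600.0
    return SurfaceAssociationSeries(
        fish_id=fish_id, bin_starts=starts, values=values, p_shallow=p,
        window_bins=window_bins, bin_hours=bin_hours, centered=centered)


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------

@dataclass
class SurfaceEvent:
    """Maximal run of bins with surface-association probability above threshold."""

    fish_id: str
    start_bin: int                   # inclusive indices on the bin grid
    end_bin: int
    start_time: pd.Timestamp
    end_time: pd.Timestamp           # end of the last bin
    duration_days: float
    is_release_event: bool = False
    is_recapture_event: bool = False
    is_outlier: bool = False

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin + 1

    def to_dict(self) -> dict:
        return {
            "fish_id": self.fish_id,
            "start_bin": self.start_bin,
            "end_bin": self.end_bin,
            "start_time": self.start_time,
            "end_time": self.end_time,
            "duration_days": self.duration_days,
            "is_release_event": self.is_release_event,
            "is_recapture_event": self.is_recapture_event,
            "is_outlier": self.is_outlier,
        }


EVENT_COLUMNS = ("fish_id", "start_bin", "end_bin", "start_time", "end_time",
                 "duration_days", "is_release_event", "is_recapture_event",
                 "is_outlier")


def empty_events_frame() -> pd.DataFrame:
    return pd.DataFrame(columns=list(EVENT_COLUMNS))


def detect_events(sa: SurfaceAssociationSeries, threshold: float = 0.75,
                  *, min_run_bins: int = 1) -> list[SurfaceEvent]:
    """Extract maximal runs of bins with ``sa > threshold`` (strict).

    Runs shorter than ``min_run_bins`` bins are discarded; adjacent events
    are separated by at least one sub-threshold (or undefined) bin.
    Events are returned ordered and non-overlapping.
    """
    above = np.zeros(len(sa), dtype=bool)
    d = sa.defined
    above[d] = sa.values[d] > threshold
    padded = np.concatenate([[False], above, [False]]).astype(np.int8)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1
    out = []
    for s, e in zip(starts, ends):
        n = e - s + 1
        if n < min_run_bins:
            continue
        out.append(SurfaceEvent(
            fish_id=sa.fish_id,
            start_bin=int(s), end_bin=int(e),
            start_time=sa.bin_starts[s], end_time=sa.bin_end(int(e)),
            duration_days=n * sa.bin_hours / HOURS_PER_DAY,
        ))
    return out


def threshold_sweep(sa: SurfaceAssociationSeries, lo: float = 0.01,
                    hi: float = 0.99, step: float = 0.02,
                    *, min_run_bins: int = 1) -> pd.DataFrame:
    """Proportion of the series inside events for each threshold in a sweep.

    The proportion (event bins over defined bins) is non-increasing in the
    threshold: raising the threshold can only shrink the above-threshold
    set.
    """
    if lo >= hi:
        raise ValueError("sweep lower bound must be below upper bound")
    n_steps = int(np.floor((hi - lo) / step + 1e-9)) + 1
    thresholds = np.round(lo + step * np.arange(n_steps), 10)
    n_bins = len(sa)
    rows = []
    for thr in thresholds:
        events = detect_events(sa, float(thr), min_run_bins=min_run_bins)
        covered = sum(e.n_bins for e in events)
        rows.append({"threshold": float(thr),
                     "proportion": covered / n_bins if n_bins else np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Per-fish summary metrics
# ---------------------------------------------------------------------------

@dataclass
class FishSummary:
    fish_id: str
    species: str
    days_at_liberty: float
    n_bins_defined: int
    sa_mean_start: float
    sa_mean_end: float | None            # None for truncated series
    sa_mean_overall: float
    prop_surface_associated: float
    prop_excl_release: float
    n_events: int
    events_per_month: float
    events_per_month_excl_release: float
    first_event_days: float | None
    last_event_days: float | None
    max_event_days: float | None
    total_event_days: float
    has_release_event: bool
    release_event_days: float | None
    has_recapture_event: bool | None     # None for truncated series
    final24_mean_sa: float | None
    final_week_daily_sa: list = field(default_factory=list)  # d1=last day .. d7

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "final_week_daily_sa"}
        for i in range(7):
            v = (self.final_week_daily_sa[i]
                 if i < len(self.final_week_daily_sa) else None)
            d[f"final_week_sa_d{i + 1}"] = v
        return d


def summarize_fish(events: list[SurfaceEvent], sa: SurfaceAssociationSeries,
                   metadata: TagMetadata,
                   month_days: float = 30.4375) -> FishSummary:
    """Per-fish surface-association summary metrics.

    Also stamps ``is_release_event`` (event starting within 24 h of
    release) and ``is_recapture_event`` (event overlapping the final 24 h
    before recapture) on the supplied events.  Recapture-window metrics are
    skipped for truncated series (tag malfunction before recapture).
    """
    release = metadata.release_time
    if release is None:
        release = sa.bin_starts[0]
    truncated = metadata.truncated
    recapture = metadata.recapture_time
    if recapture is None:
        if not truncated:
            raise ValueError(
                f"{metadata.fish_id}: recapture time required unless truncated")
        recapture = sa.bin_end(len(sa) - 1)

    days_at_liberty = (recapture - release).total_seconds() / 86400.0
    defined = sa.defined
    vals = sa.values[defined]
    w = sa.window_bins

    for e in events:
        e.is_release_event = e.start_time <= release + pd.Timedelta(hours=24)
        if not truncated:
            e.is_recapture_event = e.end_time > recapture - pd.Timedelta(hours=24)

    n_defined = len(vals)
    n_bins = len(sa)
    event_mask = np.zeros(n_bins, dtype=bool)
    release_mask = np.zeros(n_bins, dtype=bool)
    for e in events:
        event_mask[e.start_bin:e.end_bin + 1] = True
        if e.is_release_event:
            release_mask[e.start_bin:e.end_bin + 1] = True
    # proportions are of the whole series (full bin grid), not only of the
    # bins where the running mean is defined
    prop = event_mask.sum() / n_bins if n_bins else np.nan
    prop_excl = ((event_mask & ~release_mask).sum() / n_bins
                 if n_bins else np.nan)

    months = days_at_liberty / month_days
    n_release = sum(e.is_release_event for e in events)
    durations = [e.duration_days for e in events]
    release_events = [e for e in events if e.is_release_event]

    final24 = None
    has_recap = None
    weekly: list[float | None] = []
    if not truncated:
        final24 = float(np.mean(vals[-w:])) if n_defined >= 1 else None
        has_recap = any(e.is_recapture_event for e in events)
        for day in range(1, 8):
            t1 = recapture - pd.Timedelta(hours=24 * (day - 1))
            t0 = recapture - pd.Timedelta(hours=24 * day)
            in_block = (sa.bin_starts >= t0) & (sa.bin_starts < t1) & defined
            weekly.append(float(sa.values[in_block].mean())
                          if in_block.any() else None)

    return FishSummary(
        fish_id=metadata.fish_id,
        species=metadata.species,
        days_at_liberty=days_at_liberty,
        n_bins_defined=n_defined,
        sa_mean_start=float(np.mean(vals[:w])) if n_defined else np.nan,
        sa_mean_end=final24,
        sa_mean_overall=float(np.mean(vals)) if n_defined else np.nan,
        prop_surface_associated=float(prop),
        prop_excl_release=float(prop_excl),
        n_events=len(events),
        events_per_month=len(events) / months if months > 0 else np.nan,
        events_per_month_excl_release=((len(events) - n_release) / months
                                       if months > 0 else np.nan),
        first_event_days=durations[0] if durations else None,
        last_event_days=durations[-1] if durations else None,
        max_event_days=max(durations) if durations else None,
        total_event_days=float(sum(durations)),
        has_release_event=bool(release_events),
        release_event_days=(release_events[0].duration_days
                            if release_events else None),
        has_recapture_event=has_recap,
        final24_mean_sa=final24,
        final_week_daily_sa=weekly,
    )


# ---------------------------------------------------------------------------
# Cohort outlier flagging (1.5 x IQR rule on event durations)
# ---------------------------------------------------------------------------

def outlier_duration_threshold(durations: np.ndarray) -> float:
    """Upper Tukey fence Q3 + 1.5*IQR with linear-interpolation quartiles."""
    q1, q3 = np.percentile(durations, [25, 75])  # linear interpolation
    return float(q3 + 1.5 * (q3 - q1))


def flag_outliers(events: pd.DataFrame, *,
                  exclude_release: bool = False) -> pd.DataFrame:
    """Flag unusually long events: duration strictly above Q3 + 1.5*IQR.

    With ``exclude_release=True`` the fence is computed from, and flags
    applied to, non-release events only.  Fewer than four contributing
    events leaves everything unflagged with a warning.
    """
    out = events.copy()
    out["is_outlier"] = False
    pool = out if not exclude_release else out[~out["is_release_event"]]
    if len(pool) < 4:
        warnings.warn("fewer than 4 events: outlier fences undefined",
                      stacklevel=2)
        return out
    fence = outlier_duration_threshold(pool["duration_days"].to_numpy())
    mask = out["duration_days"] > fence
    if exclude_release:
        mask &= ~out["is_release_event"]
    out.loc[mask, "is_outlier"] = True
    return out


@dataclass
class OutlierSummary:
    n_events: int
    n_outliers: int
    fraction: float
    n_fish_with_outliers: int
    fence_days: float


def outlier_summary(events: pd.DataFrame, *,
                    exclude_release: bool = False) -> OutlierSummary:
    flagged = flag_outliers(events, exclude_release=exclude_release)
    pool = (flagged if not exclude_release
            else flagged[~flagged["is_release_event"]])
    n = len(pool)
    outl = pool[pool["is_outlier"]]
    fence = (outlier_duration_threshold(pool["duration_days"].to_numpy())
             if n >= 4 else np.nan)
    return OutlierSummary(
        n_events=n,
        n_outliers=len(outl),
        fraction=len(outl) / n if n else np.nan,
        n_fish_with_outliers=outl["fish_id"].nunique(),
        fence_days=fence,
    )


# ---------------------------------------------------------------------------
# Hartigan's dip test of unimodality
# ---------------------------------------------------------------------------

def _half_deviations(v: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Left-side dip deviations for every candidate modal point.

    For mode at v[j], a convex CDF branch must run beneath the lower ECDF
    corners lo[0..j] (the jump at the mode itself is absorbed by the modal
    atom); the required band half-width is the maximal gap between the
    upper corners hi[k] (k < j) and the greatest convex minorant of those
    lower corners.  Returns D[j] = that maximal gap (nondecreasing in j).
    """
    m = len(v)
    D = np.zeros(m)
    stack = np.zeros(m, dtype=np.int64)  # lower-convex-hull vertex indices
    top = 0
    for j in range(m):
        while top >= 2:
            a = stack[top - 2]
            b = stack[top - 1]
            # pop b when slope(a,b) >= slope(b,j): not strictly convex
            if (lo[b] - lo[a]) * (v[j] - v[b]) >= (lo[j] - lo[b]) * (v[b] - v[a]):
                top -= 1
            else:
                break
        stack[top] = j
        top += 1
        best = 0.0
        si = 0
        for k in range(j):
            while si < top - 1 and v[stack[si + 1]] <= v[k]:
                si += 1
            a = stack[si]
            if si < top - 1:
                b = stack[si + 1]
                hull = lo[a] + (lo[b] - lo[a]) * (v[k] - v[a]) / (v[b] - v[a])
            else:
                hull = lo[a]
            d = hi[k] - hull
            if d > best:
                best = d
        D[j] = best
    return D


def _dip_feasible(v: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                  Dl: np.ndarray, Dr: np.ndarray, d: float) -> bool:
    """Can a unimodal CDF fit within sup-band d of the ECDF?

    Checks every candidate modal point v[j]: both side corridors must admit
    a convex (left) / concave (right) branch (precomputed hull deviations
    Dl, Dr <= 2d), and the branches must join monotonically at the mode.
    The junction bounds come from chord extrapolation: convexity forces the
    left branch at the mode to at least the extension of any chord from an
    upper ECDF-corner (lo[k'] + d) to a later lower corner (hi[k] - d),
    and symmetrically for the concave branch.
    """
    m = len(v)
    eps = 1e-13
    # steepest feasible slope into each left-branch anchor (v[k], hi[k] - d)
    s_left = np.empty(m)
    for k in range(m):
        best = -1e300
        yk = hi[k] - d
        for kp in range(k):
            sl = (yk - (lo[kp] + d)) / (v[k] - v[kp])
            if sl > best:
                best = sl
        s_left[k] = best
    # steepest feasible slope out of each right-branch anchor (v[k], lo[k] + d)
    s_right = np.empty(m)
    for k in range(m):
        best = -1e300
        yk = lo[k] + d
        for kp in range(k + 1, m):
            sl = ((hi[kp] - d) - yk) / (v[kp] - v[k])
            if sl > best:
                best = sl
        s_right[k] = best

    for j in range(m):
        if Dl[j] > 2.0 * d + eps or Dr[j] > 2.0 * d + eps:
            continue
        lmin = lo[j] - d                 # left-branch value entering the mode
        for k in range(j):
            if s_left[k] > -1e300:
                val = (hi[k] - d) + s_left[k] * (v[j] - v[k])
                if val > lmin:
                    lmin = val
        rmax = hi[j] + d                 # right-branch value at the mode
        for k in range(j + 1, m):
            if s_right[k] > -1e300:
                val = (lo[k] + d) - s_right[k] * (v[k] - v[j])
                if val < rmax:
                    rmax = val
        if lmin <= rmax + eps:
            return True
    return False


def _dip_impl(v: np.ndarray, lo: np.ndarray, hi: np.ndarray,
              Dl: np.ndarray, Dr: np.ndarray) -> float:
    d_lo = 0.0
    d_hi = 0.3                           # the dip never exceeds 1/4
    for _ in range(52):
        mid = 0.5 * (d_lo + d_hi)
        if _dip_feasible(v, lo, hi, Dl, Dr, mid):
            d_hi = mid
        else:
            d_lo = mid
    return 0.5 * (d_lo + d_hi)


try:  # pragma: no cover - plain-Python fallback is exercised when numba absent
    from numba import njit

    _half_deviations_fast = njit(cache=True)(_half_deviations)
    _dip_feasible = njit(cache=True)(_dip_feasible)
    _dip_impl_fast = njit(cache=True)(_dip_impl)
except Exception:  # pragma: no cover
    _half_deviations_fast = _half_deviations
    _dip_impl_fast = _dip_impl


def dip_statistic(values: np.ndarray) -> float:
    """Hartigan's dip: sup-distance from the ECDF to the closest unimodal CDF.

    Computed from the definition: a unimodal CDF is convex left of its mode
    and concave right of it (with an atom allowed only at the mode); the
    dip is the smallest sup-band admitting such a fit, located by bisection
    over the band width with an exact feasibility test per candidate mode.
    Equals 1/(2n) for perfectly regular (equally spaced) samples and 0.25
    for an even half-and-half two-point sample.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 2 or x[0] == x[-1]:
        return 0.0
    v, counts = np.unique(x, return_counts=True)
    cum = np.cumsum(counts) / n
    hi = cum                                 # F at each distinct value
    lo = np.concatenate([[0.0], cum[:-1]])   # left limit of F
    Dl = _half_deviations_fast(v, lo, hi)
    Dr = _half_deviations_fast(-v[::-1], (1.0 - hi)[::-1], (1.0 - lo)[::-1])[::-1]
    return float(_dip_impl_fast(v, lo, hi, np.ascontiguousarray(Dl),
                                np.ascontiguousarray(Dr)))


@dataclass
class DipResult:
    dip: float
    p_value: float
    n: int
    n_boot: int


def dip_test(values: np.ndarray, n_boot: int = 2000,
             seed: int | None = None) -> DipResult:
    """Dip statistic with a uniform-null bootstrap p-value.

    The p-value is the fraction of ``n_boot`` uniform(0, 1) samples of the
    same size whose dip is at least the observed dip.  Requires at least
    four values; a constant sample has dip 0 and p-value 1.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 4:
        raise ValueError("dip test needs at least 4 values")
    d_obs = dip_statistic(x)
    if d_obs == 0.0:
        return DipResult(0.0, 1.0, len(x), n_boot)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = dip_statistic(rng.uniform(size=len(x)))
    p = float(np.mean(boots >= d_obs))
    return DipResult(d_obs, p, len(x), n_boot)
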