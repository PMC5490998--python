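"""Synthetic archival-tag data with full generator truth.

Emulates the statistical structure the analysis assumes: two behavioural
states (warm-shallow with low diving amplitude vs cool-deep with high
amplitude), baseline diel switching on a 12 h / 12 h cycle, sustained
surface-association bouts (including an optional bout starting at release),
thermally stratified temperatures, optional short data gaps, and bounded
random-walk geolocation tracks with axis-aligned confidence ellipses.

Every simulated fish carries a :class:`GeneratorTruth` bundle holding the
true per-bin states, the planted bout schedule, and the event schedule the
surface-association definition implies for those true states — the oracle
for recovery tests.  All randomness flows from one scenario seed; a given
(seed, fish_index) pair always regenerates identical data.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .events import detect_events, surface_association
from .hmm import StatePosteriors
from .io_tags import (TagMetadata, TagRecordSeries, write_metadata,
                      write_tag_series, write_tracks)
from .preprocess import BinnedSeries

BINS_PER_DAY = 8  # 3-hour bins


@dataclass
class StateEmission:
    """Per-state distribution of the binned observations.

    ``depth_sd_mean``/``depth_sd_sd`` describe the across-bin distribution
    of diving amplitude (the within-bin depth SD); ``temp_mean``/``temp_sd``
    the across-bin thermal habitat.  ``depth_level`` is the state's typical
    swimming depth used to synthesise raw samples.
    """

    depth_level: float
    depth_sd_mean: float
    depth_sd_sd: float
    temp_mean: float
    temp_sd: float
    corr: float = 0.0          # depth_sd / temp correlation across bins


@dataclass
class SimScenario:
    """Study conditions for a synthetic cohort.

    Defaults mirror the scale of real bigeye/yellowfin deployments: warm
    shallow state near 28 degC with ~5 m diving amplitude, deep state near
    16 degC with ~45 m amplitude, 40-60 day deployments sampled every
    2 minutes, bouts with a ~2-day median duration at ~2.5 per month, and
    a release-associated bout in a bit over half of fish.
    """

    n_fish: int = 10
    seed: int = 0
    duration_days_range: tuple[float, float] = (40.0, 60.0)
    sampling_interval_s: float = 120.0
    bin_hours: float = 3.0
    shallow: StateEmission = field(default_factory=lambda: StateEmission(
        depth_level=15.0, depth_sd_mean=5.0, depth_sd_sd=1.5,
        temp_mean=28.0, temp_sd=0.8))
    deep: StateEmission = field(default_factory=lambda: StateEmission(
        depth_level=150.0, depth_sd_mean=45.0, depth_sd_sd=8.0,
        temp_mean=16.0, temp_sd=1.2))
    within_bin_temp_sd: float = 0.3
    # behavioural schedule
    diel_shallow_start_hour: float = 18.0   # shallow 18:00-06:00 UTC
    bouts_per_month: float = 2.5
    bout_days_log_mean: float = math.log(2.0)   # lognormal, median 2 d
    bout_days_log_sd: float = 0.6
    bout_days_max: float = 14.0
    min_bout_gap_days: float = 2.0
    release_bout_prob: float = 0.6
    release_bout_days_mean: float = 7.5
    release_bout_days_sd: float = 4.0
    #: explicit (start_day, duration_days) bouts; overrides the random
    #: schedule (including the release bout) when set
    fixed_bouts: tuple[tuple[float, float], ...] | None = None
    # data gaps (each shorter than the 1-hour eligibility limit by default)
    n_gaps: int = 0
    gap_minutes: float = 45.0
    # geolocation tracks
    estimates_per_day: int = 3
    track_step_deg: float = 0.08
    ci_lon_deg: float = 0.5
    ci_lat_deg: float = 1.2                 # latitude error exceeds longitude
    lon0: float = 160.0
    lat0: float = -5.0
    track_bound_deg: float = 3.0
    month_days: float = 30.4375
    species_cycle: tuple[str, ...] = ("bigeye", "yellowfin")
    release_base: str = "2010-01-01T06:00:00+00:00"


@dataclass
class GeneratorTruth:
    """Ground truth for one simulated fish."""

    fish_id: str
    bin_starts: pd.DatetimeIndex
    states: np.ndarray                     # 1 = shallow, 0 = deep, per bin
    bouts: list[tuple[int, int]]           # planted shallow bouts, bin indices
    expected_events: list[tuple[int, int]]  # events implied by the definition
    expected_event_days: list[float]
    expected_proportion: float             # of defined bins inside events
    expected_events_per_month: float
    shallow: StateEmission
    deep: StateEmission
    track_lon: np.ndarray = field(default_factory=lambda: np.empty(0))
    track_lat: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_json_dict(self) -> dict:
        return {
            "fish_id": self.fish_id,
            "bin_starts": [t.isoformat() for t in self.bin_starts],
            "states": self.states.astype(int).tolist(),
            "bouts": [list(b) for b in self.bouts],
            "expected_events": [list(e) for e in self.expected_events],
            "expected_event_days": self.expected_event_days,
            "expected_proportion": self.expected_proportion,
            "expected_events_per_month": self.expected_events_per_month,
            "shallow": dataclasses.asdict(self.shallow),
            "deep": dataclasses.asdict(self.deep),
            "track_lon": self.track_lon.tolist(),
            "track_lat": self.track_lat.tolist(),
        }


def posteriors_from_states(states: np.ndarray,
                           bin_starts: pd.DatetimeIndex) -> StatePosteriors:
    """Hard 0/1 posteriors encoding a known state sequence."""
    return StatePosteriors(bin_starts=bin_starts,
                           p_shallow=np.asarray(states, dtype=float),
                           log_likelihood=0.0)


def implied_events(states: np.ndarray, bin_starts: pd.DatetimeIndex,
                   window_bins: int = 8,
                   threshold: float = 0.75) -> list[tuple[int, int]]:
    """Event schedule the surface-association definition implies for a
    known state sequence (running mean of the hard indicator, thresholded)."""
    sa = surface_association(posteriors_from_states(states, bin_starts),
                             window_bins)
    return [(e.start_bin, e.end_bin) for e in detect_events(sa, threshold)]


def _fish_rng(scenario: SimScenario, fish_index: int,
              stream: int = 0) -> np.random.Generator:
    return np.random.default_rng([scenario.seed, fish_index, stream])


def _schedule_states(scenario: SimScenario, rng: np.random.Generator,
                     n_bins: int, release: pd.Timestamp
                     ) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Per-bin true states: diel baseline overridden by planted bouts."""
    bpd = int(round(24.0 / scenario.bin_hours))
    starts_h = (release.hour + scenario.bin_hours * np.arange(n_bins)) % 24.0
    h0 = scenario.diel_shallow_start_hour
    h1 = (h0 + 12.0) % 24.0
    if h0 < h1:
        shallow_night = (starts_h >= h0) & (starts_h < h1)
    else:
        shallow_night = (starts_h >= h0) | (starts_h < h1)
    states = shallow_night.astype(np.int8)

    bouts: list[tuple[int, int]] = []
    occupied = np.zeros(n_bins, dtype=bool)
    gap = int(round(scenario.min_bout_gap_days * bpd))

    def _claim(s: int, e: int) -> None:
        bouts.append((s, e))
        occupied[max(0, s - gap):min(n_bins, e + 1 + gap)] = True

    if scenario.fixed_bouts is not None:
        for start_day, dur_day in scenario.fixed_bouts:
            s = int(round(start_day * bpd))
            e = min(n_bins - 1, s + int(round(dur_day * bpd)) - 1)
            _claim(s, e)
        bouts.sort()
        for s, e in bouts:
            states[s:e + 1] = 1
        return states, bouts

    if rng.uniform() < scenario.release_bout_prob:
        d = rng.normal(scenario.release_bout_days_mean,
                       scenario.release_bout_days_sd)
        d = float(np.clip(d, 1.5, scenario.bout_days_max))
        _claim(0, min(n_bins - 1, int(round(d * bpd)) - 1))

    months = n_bins / bpd / scenario.month_days
    n_bouts = rng.poisson(scenario.bouts_per_month * months)
    for _ in range(n_bouts):
        d = float(np.clip(rng.lognormal(scenario.bout_days_log_mean,
                                        scenario.bout_days_log_sd),
                          0.75, scenario.bout_days_max))
        nb = int(round(d * bpd))
        for _try in range(50):
            s = int(rng.integers(0, max(1, n_bins - nb)))
            e = s + nb - 1
            if not occupied[s:e + 1].any():
                _claim(s, e)
                break
    bouts.sort()
    for s, e in bouts:
        states[s:e + 1] = 1
    return states, bouts


def simulate_fish(scenario: SimScenario, fish_index: int
                  ) -> tuple[TagRecordSeries, GeneratorTruth]:
    """Simulate one fish's raw sensor series plus its generator truth.

    Depth and temperature samples are drawn at the scenario interval from
    the scheduled state's distribution: each 3-hour bin gets a target
    (diving amplitude, thermal habitat) drawn from the state's bivariate
    normal, and raw samples realise those targets.
    """
    rng = _fish_rng(scenario, fish_index, stream=0)
    fish_id = f"sim{fish_index:03d}"
    release = (pd.Timestamp(scenario.release_base)
               + pd.Timedelta(days=3 * fish_index))
    lo, hi = scenario.duration_days_range
    duration_days = float(np.floor(rng.uniform(lo, hi)))
    bpd = int(round(24.0 / scenario.bin_hours))
    n_bins = int(round(duration_days * bpd))

    states, bouts = _schedule_states(scenario, rng, n_bins, release)
    width = pd.Timedelta(hours=scenario.bin_hours)
    bin_starts = pd.DatetimeIndex([release + width * i for i in range(n_bins)])

    per_bin = int(round(scenario.bin_hours * 3600.0
                        / scenario.sampling_interval_s))
    times = (release
             + pd.to_timedelta(np.arange(n_bins * per_bin)
                               * scenario.sampling_interval_s, unit="s"))
    depth = np.empty(n_bins * per_bin)
    temp = np.empty(n_bins * per_bin)
    for b in range(n_bins):
        em = scenario.shallow if states[b] else scenario.deep
        cov = np.array([
            [em.depth_sd_sd ** 2,
             em.corr * em.depth_sd_sd * em.temp_sd],
            [em.corr * em.depth_sd_sd * em.temp_sd, em.temp_sd ** 2],
        ])
        tgt = rng.multivariate_normal([em.depth_sd_mean, em.temp_mean], cov)
        sd_t = max(0.25, tgt[0])
        sl = slice(b * per_bin, (b + 1) * per_bin)
        depth[sl] = np.clip(rng.normal(em.depth_level, sd_t, per_bin), 0, None)
        temp[sl] = rng.normal(tgt[1], scenario.within_bin_temp_sd, per_bin)

    samples = pd.DataFrame({"timestamp": times, "depth_m": depth,
                            "temp_c": np.round(temp, 3)})
    samples["depth_m"] = np.round(samples["depth_m"], 2)

    if scenario.n_gaps > 0:
        keep = np.ones(len(samples), dtype=bool)
        for _ in range(scenario.n_gaps):
            g0 = rng.uniform(0.1, 0.9) * duration_days
            t0 = release + pd.Timedelta(days=g0)
            t1 = t0 + pd.Timedelta(minutes=scenario.gap_minutes)
            keep &= ~((samples["timestamp"] >= t0)
                      & (samples["timestamp"] < t1)).to_numpy()
        samples = samples[keep].reset_index(drop=True)

    species = scenario.species_cycle[fish_index % len(scenario.species_cycle)]
    has_release_bout = bool(bouts and bouts[0][0] == 0)
    meta = TagMetadata(
        fish_id=fish_id,
        species=species,
        fork_length_cm=float(np.round(np.clip(rng.normal(71, 13), 35, 120), 1)),
        release_time=release,
        recapture_time=samples["timestamp"].iloc[-1]
        + pd.Timedelta(seconds=scenario.sampling_interval_s),
        release_school="FAD" if has_release_bout
        else str(rng.choice(["free", "log"])),
        recapture_set=str(rng.choice(["FAD", "free", "log"])),
        truncated=False,
    )
    series = TagRecordSeries(meta, samples)

    events = implied_events(states, bin_starts)
    covered = sum(e - s + 1 for s, e in events)
    months = duration_days / scenario.month_days
    truth = GeneratorTruth(
        fish_id=fish_id,
        bin_starts=bin_starts,
        states=states.astype(np.int8),
        bouts=bouts,
        expected_events=events,
        expected_event_days=[(e - s + 1) * scenario.bin_hours / 24.0
                             for s, e in events],
        expected_proportion=covered / n_bins if n_bins > 0 else np.nan,
        expected_events_per_month=len(events) / months,
        shallow=scenario.shallow,
        deep=scenario.deep,
    )
    return series, truth


def simulate_track(scenario: SimScenario, fish_index: int,
                   series: TagRecordSeries) -> pd.DataFrame:
    """Bounded random-walk geolocation estimates, three per deployment day."""
    rng = _fish_rng(scenario, fish_index, stream=1)
    release = series.metadata.release_time
    recapture = series.metadata.recapture_time
    n_days = int(np.floor((recapture - release).total_seconds() / 86400.0))
    step_h = 24.0 / scenario.estimates_per_day
    times = [release + pd.Timedelta(hours=2.0 + step_h * k)
             for k in range(n_days * scenario.estimates_per_day)]

    start_lon = scenario.lon0 + rng.uniform(-1.0, 1.0)
    start_lat = scenario.lat0 + rng.uniform(-1.0, 1.0)
    lon, lat = start_lon, start_lat
    lons, lats = [], []
    for _ in times:
        lons.append(lon)
        lats.append(lat)
        lon += rng.normal(0.0, scenario.track_step_deg)
        lat += rng.normal(0.0, scenario.track_step_deg)
        lon = float(np.clip(lon, scenario.lon0 - scenario.track_bound_deg,
                            scenario.lon0 + scenario.track_bound_deg))
        lat = float(np.clip(lat, scenario.lat0 - scenario.track_bound_deg,
                            scenario.lat0 + scenario.track_bound_deg))
    return pd.DataFrame({
        "fish_id": series.fish_id,
        "time": pd.DatetimeIndex(times),
        "lon": np.round(lons, 4),
        "lat": np.round(lats, 4),
        "ci_lon": scenario.ci_lon_deg,
        "ci_lat": scenario.ci_lat_deg,
    })


@dataclass
class Cohort:
    series: list[TagRecordSeries]
    truths: list[GeneratorTruth]
    tracks: pd.DataFrame


def simulate_cohort(scenario: SimScenario,
                    out_dir: str | Path | None = None,
                    with_tracks: bool = True) -> Cohort:
    """Simulate a cohort; optionally write a ready-to-analyse directory.

    The directory layout matches :func:`surfassoc.io_tags.run_pipeline`
    input: ``metadata.csv``, one ``<fish_id>.csv`` per fish, optionally
    ``tracks.csv``, plus a ``truth/`` bundle of per-fish JSON.
    """
    if scenario.n_fish < 1:
        raise ValueError("n_fish must be >= 1")
    series_list, truths, track_frames = [], [], []
    for i in range(scenario.n_fish):
        series, truth = simulate_fish(scenario, i)
        if with_tracks:
            tr = simulate_track(scenario, i, series)
            truth.track_lon = tr["lon"].to_numpy()
            truth.track_lat = tr["lat"].to_numpy()
            track_frames.append(tr)
        series_list.append(series)
        truths.append(truth)
    tracks = (pd.concat(track_frames, ignore_index=True)
              if track_frames else pd.DataFrame(
                  columns=["fish_id", "time", "lon", "lat", "ci_lon", "ci_lat"]))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_metadata([s.metadata for s in series_list],
                       out_dir / "metadata.csv")
        for s in series_list:
            write_tag_series(s, out_dir / f"{s.fish_id}.csv")
        if with_tracks and len(tracks):
            write_tracks(tracks, out_dir / "tracks.csv")
        truth_dir = out_dir / "truth"
        truth_dir.mkdir(exist_ok=True)
        for t in truths:
            (truth_dir / f"{t.fish_id}.json").write_text(
                json.dumps(t.to_json_dict()))
    return Cohort(series_list, truths, tracks)


def simulate_binned_hmm(means: np.ndarray, covs: np.ndarray, A: np.ndarray,
                        pi: np.ndarray, T: int, seed: int,
                        bin_hours: float = 3.0
                        ) -> tuple[BinnedSeries, np.ndarray]:
    """Draw a binned series directly from a two-state Gaussian HMM.

    Bypasses the raw-sample layer: observations come straight from the
    state emission distributions, so fitted parameters can be compared with
    the generating ones without binning noise.
    """
    rng = np.random.default_rng(seed)
    means = np.asarray(means, dtype=float)
    covs = np.asarray(covs, dtype=float)
    A = np.asarray(A, dtype=float)
    states = np.empty(T, dtype=np.int8)
    X = np.empty((T, 2))
    s = int(rng.choice(2, p=np.asarray(pi, dtype=float)))
    for t in range(T):
        states[t] = s
        X[t] = rng.multivariate_normal(means[s], covs[s])
        s = int(rng.choice(2, p=A[s]))
    X[:, 0] = np.maximum(X[:, 0], 0.0)   # diving amplitude cannot be negative
    starts = (pd.Timestamp("2010-01-01", tz="UTC")
              + pd.Timedelta(hours=bin_hours) * np.arange(T))
    binned = BinnedSeries(
        fish_id="hmm-sim", bin_starts=pd.DatetimeIndex(starts),
        depth_sd=X[:, 0].copy(), temp_mean=X[:, 1].copy(),
        n_samples=np.full(T, 90), valid=np.ones(T, dtype=bool),
        bin_hours=bin_hours)
    return binned, states
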