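"""Reading, writing and orchestration for archival-tag analyses.

All on-disk formats are plain text: UTF-8 CSV with ISO-8601 UTC timestamps
and '.' decimal separators.  A deployment directory holds one samples CSV per
fish (``<fish_id>.csv``), a single ``metadata.csv``, and optionally a
``tracks.csv`` of light-based geolocation estimates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("surfassoc")

SPECIES = ("bigeye", "yellowfin", "other")
RELEASE_SCHOOLS = ("FAD", "log", "free", "megafauna", "seamount", "unknown")
RECAPTURE_SETS = ("FAD", "log", "free", "unknown")

#: CSV column order for sample files.
SAMPLE_COLUMNS = ("timestamp", "depth_m", "temp_c", "internal_temp_c", "light")

#: Sampling-interval range (seconds) accepted for a valid archival series.
MIN_INTERVAL_S = 10.0
MAX_INTERVAL_S = 300.0


class TagDataError(ValueError):
    """Malformed or invariant-violating tag data."""


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Tunable parameters of the surface-association analysis.

    Defaults reproduce the published analysis choices: 3-hour bins, a
    trailing 24-hour (eight-bin) running mean, an event threshold of 0.75,
    a 0.01-0.99 threshold sweep in steps of 0.02, and 0.1-degree raster
    cells.
    """

    bin_hours: float = 3.0
    window_bins: int = 8
    event_threshold: float = 0.75
    sweep_lo: float = 0.01
    sweep_hi: float = 0.99
    sweep_step: float = 0.02
    raster_cell_deg: float = 0.1
    month_days: float = 30.4375          # mean Gregorian month
    rng_seed: int = 0
    # eligibility screening
    min_days: float = 30.0
    max_gap_hours: float = 1.0
    # binning
    coverage_floor: float = 0.5          # fraction of expected samples per bin
    # EM settings
    em_restarts: int = 3
    em_max_iter: int = 500
    em_tol: float = 1e-6
    min_valid_bins: int = 64
    log_depth_sd: bool = False           # fit on log1p(depth_sd) instead
    # events
    min_event_bins: int = 1
    centered_window: bool = False        # centered instead of trailing mean
    # spatial
    ellipse_full_width: bool = True      # CI width = full axis length

    def __post_init__(self) -> None:
        if not 0.0 < self.event_threshold < 1.0:
            raise ValueError("event_threshold must lie in (0, 1)")
        if self.window_bins < 1 or self.bin_hours <= 0:
            raise ValueError("window_bins and bin_hours must be positive")
        if self.sweep_lo >= self.sweep_hi:
            raise ValueError("sweep_lo must be < sweep_hi")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class TagMetadata:
    fish_id: str
    species: str = "other"
    fork_length_cm: float = float("nan")
    release_time: pd.Timestamp | None = None
    recapture_time: pd.Timestamp | None = None
    release_school: str = "unknown"
    recapture_set: str = "unknown"
    truncated: bool = False              # tag malfunction: series ends early

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise TagDataError(f"unknown species {self.species!r}")
        if self.release_school not in RELEASE_SCHOOLS:
            raise TagDataError(f"unknown release_school {self.release_school!r}")
        if self.recapture_set not in RECAPTURE_SETS:
            raise TagDataError(f"unknown recapture_set {self.recapture_set!r}")


@dataclass
class TagRecordSeries:
    """One fish's raw sensor time-series plus deployment metadata.

    ``samples`` columns: timestamp (UTC), depth_m, temp_c and optionally
    internal_temp_c / light (pass-through storage only).
    """

    metadata: TagMetadata
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.samples
        for col in ("timestamp", "depth_m", "temp_c"):
            if col not in df.columns:
                raise TagDataError(f"samples missing mandatory column {col!r}")
        ts = df["timestamp"]
        if not pd.api.types.is_datetime64_any_dtype(ts):
            raise TagDataError("timestamp column must be datetime")
        diffs = ts.diff().dropna().dt.total_seconds().to_numpy()
        if len(diffs) and (bad := np.flatnonzero(diffs <= 0)).size:
            # diff i refers to sample i+1; +2 more for the header line and
            # 1-based numbering in the source CSV
            raise TagDataError(
                f"timestamps not strictly increasing at row {bad[0] + 3} "
                f"(t={ts.iloc[bad[0] + 1]})"
            )
        if (df["depth_m"].to_numpy() < 0).any():
            raise TagDataError("negative depth")

    @property
    def fish_id(self) -> str:
        return self.metadata.fish_id

    @property
    def span_days(self) -> float:
        ts = self.samples["timestamp"]
        return (ts.iloc[-1] - ts.iloc[0]).total_seconds() / 86400.0

    def median_interval_s(self) -> float:
        d = self.samples["timestamp"].diff().dropna().dt.total_seconds()
        return float(d.median())


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _parse_times(col: pd.Series, what: str) -> pd.Series:
    out = pd.to_datetime(col, utc=True, format="ISO8601", errors="coerce")
    if out.isna().any():
        row = int(np.flatnonzero(out.isna().to_numpy())[0])
        raise TagDataError(
            f"{what}: unparseable timestamp at data row {row + 2} "
            f"(value {col.iloc[row]!r})"
        )
    return out


def read_tag_series(path: str | Path, metadata_path: str | Path) -> TagRecordSeries:
    """Read one fish's samples CSV plus its row from a metadata CSV.

    The metadata CSV may hold multiple fish; the row is matched by the
    sample file's stem (= fish_id).
    """
    path = Path(path)
    fish_id = path.stem
    meta_df = read_metadata(metadata_path)
    rows = meta_df[meta_df["fish_id"] == fish_id]
    if rows.empty:
        raise TagDataError(f"no metadata row for fish {fish_id!r}")
    meta = _metadata_from_row(rows.iloc[0])

    df = pd.read_csv(path)
    missing = {"timestamp", "depth_m", "temp_c"} - set(df.columns)
    if missing:
        raise TagDataError(f"{path}: missing mandatory column(s) {sorted(missing)}")
    df["timestamp"] = _parse_times(df["timestamp"], str(path))
    for col in ("depth_m", "temp_c", "internal_temp_c", "light"):
        if col in df.columns and not pd.api.types.is_numeric_dtype(df[col]):
            bad = pd.to_numeric(df[col], errors="coerce")
            row = int(np.flatnonzero(bad.isna().to_numpy() & df[col].notna().to_numpy())[0])
            raise TagDataError(f"{path}: non-numeric {col} at data row {row + 2}")
    try:
        return TagRecordSeries(meta, df)
    except TagDataError as exc:
        raise TagDataError(f"{path}: {exc}") from None


def write_tag_series(series: TagRecordSeries, path: str | Path) -> None:
    cols = [c for c in SAMPLE_COLUMNS if c in series.samples.columns]
    out = series.samples[cols].copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    out.to_csv(path, index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"fish_id": str})
    if "fish_id" not in df.columns:
        raise TagDataError(f"{path}: missing mandatory column 'fish_id'")
    return df


def _metadata_from_row(row: pd.Series) -> TagMetadata:
    def _ts(key: str) -> pd.Timestamp | None:
        v = row.get(key)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        return pd.to_datetime(v, utc=True)

    return TagMetadata(
        fish_id=str(row["fish_id"]),
        species=str(row.get("species", "other")),
        fork_length_cm=float(row.get("fork_length_cm", np.nan)),
        release_time=_ts("release_time"),
        recapture_time=_ts("recapture_time"),
        release_school=str(row.get("release_school", "unknown")),
        recapture_set=str(row.get("recapture_set", "unknown")),
        truncated=_parse_bool(row.get("truncated", False)),
    )


def _parse_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("true", "1", "yes")
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return False
    return bool(v)


def write_metadata(metas: Sequence[TagMetadata], path: str | Path) -> None:
    rows = []
    for m in metas:
        d = dataclasses.asdict(m)
        for key in ("release_time", "recapture_time"):
            if d[key] is not None:
                d[key] = pd.Timestamp(d[key]).strftime("%Y-%m-%dT%H:%M:%S%z")
        rows.append(d)
    cols = [f.name for f in dataclasses.fields(TagMetadata)]
    cols[cols.index("fork_length_cm")] = "fork_length_cm"
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_tracks(path: str | Path) -> pd.DataFrame:
    """Read geolocation estimates: fish_id, time, lon, lat, ci_lon, ci_lat."""
    df = pd.read_csv(path, dtype={"fish_id": str})
    missing = {"fish_id", "time", "lon", "lat", "ci_lon", "ci_lat"} - set(df.columns)
    if missing:
        raise TagDataError(f"{path}: missing track column(s) {sorted(missing)}")
    df["time"] = _parse_times(df["time"], str(path))
    if (df[["ci_lon", "ci_lat"]].to_numpy() <= 0).any():
        raise TagDataError(f"{path}: confidence-interval widths must be positive")
    return df


def write_tracks(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["time"] = out["time"].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------

def write_outputs(results: "PipelineResult", out_dir: str | Path) -> dict:
    """Write every result table as tidy CSV; return a file manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def _emit(name: str, df: pd.DataFrame) -> None:
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        manifest[name] = str(p)

    _emit("summary", results.summary)
    _emit("events", results.events)
    _emit("sweep", results.sweep)
    _emit("exclusions", results.exclusions)
    if results.posteriors is not None:
        _emit("posteriors", results.posteriors)
    if results.raster is not None:
        _emit("raster", results.raster)
    model_dir = out_dir / "models"
    model_dir.mkdir(exist_ok=True)
    for fish_id, model_json in results.models.items():
        p = model_dir / f"{fish_id}.json"
        p.write_text(json.dumps(model_json, indent=1, sort_keys=True))
        manifest[f"model:{fish_id}"] = str(p)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


@dataclass
class PipelineResult:
    summary: pd.DataFrame
    events: pd.DataFrame
    sweep: pd.DataFrame
    exclusions: pd.DataFrame
    posteriors: pd.DataFrame | None
    raster: pd.DataFrame | None
    models: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig, input_dir: str | Path,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full per-fish analysis over a deployment directory.

    Screens each series for eligibility, bins it, fits the two-state HMM,
    derives the surface-association probability, extracts events and summary
    metrics, sweeps thresholds, flags cohort outliers, and (when a
    ``tracks.csv`` is present) builds the combined probability raster.
    """
    from . import events as ev
    from . import hmm as hm
    from . import preprocess as pp
    from . import spatial as sp

    input_dir = Path(input_dir)
    meta_path = input_dir / "metadata.csv"
    if not meta_path.exists():
        raise TagDataError(f"no metadata.csv in {input_dir}")
    meta_df = read_metadata(meta_path)

    rng = np.random.default_rng(config.rng_seed)
    summaries, event_rows, sweep_rows, excl_rows, post_rows = [], [], [], [], []
    models: dict[str, dict] = {}
    sa_by_fish: dict[str, ev.SurfaceAssociationSeries] = {}

    for fish_id in meta_df["fish_id"]:
        sample_path = input_dir / f"{fish_id}.csv"
        if not sample_path.exists():
            excl_rows.append({"fish_id": fish_id, "reason": "no samples file"})
            continue
        series = read_tag_series(sample_path, meta_path)
        elig = pp.screen_eligibility(series, config.min_days, config.max_gap_hours)
        if not elig.eligible:
            logger.info("excluding %s: %s", fish_id, "; ".join(elig.reasons))
            excl_rows.append({"fish_id": fish_id, "reason": "; ".join(elig.reasons)})
            continue

        binned = pp.bin_series(series, config.bin_hours,
                               coverage_floor=config.coverage_floor)
        fit_seed = int(rng.integers(0, 2**31 - 1))
        model = hm.fit_hmm(binned, config, seed=fit_seed)
        post = hm.smooth_posteriors(binned, model)
        sa = ev.surface_association(post, config.window_bins,
                                    centered=config.centered_window,
                                    fish_id=fish_id)
        sa_by_fish[fish_id] = sa
        fish_events = ev.detect_events(sa, config.event_threshold,
                                       min_run_bins=config.min_event_bins)
        summary = ev.summarize_fish(fish_events, sa, series.metadata,
                                    month_days=config.month_days)
        summaries.append(summary.to_dict())
        event_rows.extend(e.to_dict() for e in fish_events)
        sweep = ev.threshold_sweep(sa, config.sweep_lo, config.sweep_hi,
                                   config.sweep_step,
                                   min_run_bins=config.min_event_bins)
        sweep["fish_id"] = fish_id
        sweep_rows.append(sweep)
        models[fish_id] = model.to_json_dict()
        logger.info("fitted %s: loglik=%.2f iters=%d restarts=%d",
                    fish_id, model.log_likelihood, model.n_iter, model.restarts_used)
        post_rows.append(pd.DataFrame({
            "fish_id": fish_id,
            "bin_start": sa.bin_starts,
            "p_shallow": post.p_shallow,
            "surface_association": sa.values,
        }))

    if not summaries:
        raise TagDataError("no eligible series after screening")

    events_df = (pd.DataFrame([r for r in event_rows])
                 if event_rows else ev.empty_events_frame())
    if len(events_df) >= 4:
        events_df = ev.flag_outliers(events_df, exclude_release=False)
    else:
        events_df["is_outlier"] = False

    raster_df = None
    tracks_path = input_dir / "tracks.csv"
    if tracks_path.exists():
        tracks = read_tracks(tracks_path)
        cells = []
        for fish_id, grp in tracks.groupby("fish_id", sort=True):
            if fish_id not in sa_by_fish:
                continue
            ellipses = sp.attach_probability(grp, sa_by_fish[fish_id],
                                             bin_hours=config.bin_hours)
            cells.extend(
                sp.rasterize(e, config.raster_cell_deg,
                             full_width=config.ellipse_full_width)
                for e in ellipses
            )
        if cells:
            raster_df = sp.combine(cells, config.raster_cell_deg).to_dataframe()

    result = PipelineResult(
        summary=pd.DataFrame(summaries),
        events=events_df,
        sweep=(pd.concat(sweep_rows, ignore_index=True)
               [["fish_id", "threshold", "proportion"]]),
        exclusions=pd.DataFrame(excl_rows, columns=["fish_id", "reason"]),
        posteriors=pd.concat(post_rows, ignore_index=True) if post_rows else None,
        raster=raster_df,
        models=models,
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result
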