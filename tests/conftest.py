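import numpy as np
import pandas as pd
import pytest

from surfassoc import TagMetadata, TagRecordSeries


def build_series(duration_days=45.0, interval_s=120.0, depth=10.0, temp=28.0,
                 fish_id="f1", start="2010-01-01T00:00:00+00:00",
                 drop_slices=(), depth_fn=None, temp_fn=None,
                 truncated=False) -> TagRecordSeries:
    """Constant (or callable-driven) series builder for unit tests."""
    start = pd.Timestamp(start)
    n = int(round(duration_days * 86400.0 / interval_s)) + 1
    t = start + pd.to_timedelta(np.arange(n) * interval_s, unit="s")
    i = np.arange(n)
    d = depth_fn(i) if depth_fn else np.full(n, float(depth))
    c = temp_fn(i) if temp_fn else np.full(n, float(temp))
    df = pd.DataFrame({"timestamp": t, "depth_m": d, "temp_c": c})
    keep = np.ones(n, dtype=bool)
    for sl in drop_slices:
        keep[sl] = False
    df = df[keep].reset_index(drop=True)
    meta = TagMetadata(
        fish_id=fish_id, species="bigeye", fork_length_cm=70.0,
        release_time=start,
        recapture_time=df["timestamp"].iloc[-1] + pd.Timedelta(seconds=interval_s),
        release_school="FAD", recapture_set="free", truncated=truncated)
    return TagRecordSeries(meta, df)


@pytest.fixture
def const_series():
    return build_series()


@pytest.fixture
def rng():
    return np.random.default_rng(42)
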