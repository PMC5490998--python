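"""Surface-association series, event extraction, summaries, dip test."""

import numpy as np
import pandas as pd
import pytest

import surfassoc as sf
from surfassoc.events import (SurfaceAssociationSeries, dip_statistic,
                              outlier_duration_threshold)
from surfassoc.hmm import StatePosteriors
from surfassoc.io_tags import TagMetadata

from _dip_oracle import dip_lp


def _posteriors(p):
    p = np.asarray(p, dtype=float)
    starts = pd.DatetimeIndex(
        pd.Timestamp("2010-01-01", tz="UTC")
        + pd.Timedelta(hours=3) * np.arange(len(p)))
    return StatePosteriors(bin_starts=starts, p_shallow=p, log_likelihood=0.0)


def _sa_from_values(values, fish_id="f1"):
    """Hand-built surface-association series (values may contain NaN)."""
    values = np.asarray(values, dtype=float)
    starts = pd.DatetimeIndex(
        pd.Timestamp("2010-01-01", tz="UTC")
        + pd.Timedelta(hours=3) * np.arange(len(values)))
    return SurfaceAssociationSeries(
        fish_id=fish_id, bin_starts=starts, values=values,
        p_shallow=np.nan_to_num(values), window_bins=8, bin_hours=3.0)


def _scan_events(values, threshold, min_run=1):
    """Brute-force linear scan over a (possibly NaN-holed) sa vector."""
    runs, start = [], None
    for i, v in enumerate(values):
        above = (not np.isnan(v)) and v > threshold
        if above and start is None:
            start = i
        elif not above and start is not None:
            if i - start >= min_run:
                runs.append((start, i - 1))
            start = None
    if start is not None and len(values) - start >= min_run:
        runs.append((start, len(values) - 1))
    return runs


class TestSurfaceAssociation:
    def test_diel_switching_gives_exactly_half(self):
        """12 h shallow / 12 h deep alternation: running mean exactly 0.5."""
        p = np.tile([1, 1, 1, 1, 0, 0, 0, 0], 40)
        sa = sf.surface_association(_posteriors(p))
        assert np.isnan(sa.values[:7]).all()
        np.testing.assert_array_equal(sa.values[7:], 0.5)
        assert sf.detect_events(sa, 0.75) == []

    def test_constant_one_posterior(self):
        sa = sf.surface_association(_posteriors(np.ones(30)))
        np.testing.assert_array_equal(sa.values[7:], 1.0)

    def test_matches_direct_sliding_mean(self, rng):
        p = rng.uniform(size=200)
        sa = sf.surface_association(_posteriors(p))
        for t in range(7, 200):
            assert abs(sa.values[t] - p[t - 7:t + 1].mean()) < 1e-12

    def test_centered_window_alignment(self, rng):
        p = rng.uniform(size=50)
        sa = sf.surface_association(_posteriors(p), centered=True)
        # window of 8 centered on t covers t-4 .. t+3
        for t in range(4, 46):
            assert abs(sa.values[t] - p[t - 4:t + 4].mean()) < 1e-12

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError, match="shorter than window"):
            sf.surface_association(_posteriors(np.ones(5)))


class TestDetectEvents:
    def test_no_events_at_half(self):
        sa = _sa_from_values(np.full(50, 0.5))
        assert sf.detect_events(sa, 0.75) == []

    def test_single_day_run(self):
        v = np.full(40, 0.3)
        v[10:18] = 0.9
        events = sf.detect_events(_sa_from_values(v), 0.75)
        assert len(events) == 1
        assert (events[0].start_bin, events[0].end_bin) == (10, 17)
        assert events[0].duration_days == pytest.approx(1.0)

    def test_threshold_is_strict(self):
        v = np.full(20, 0.75)
        assert sf.detect_events(_sa_from_values(v), 0.75) == []

    @pytest.mark.parametrize("min_run", [1, 3])
    def test_matches_brute_force_scan(self, rng, min_run):
        for _ in range(200):
            v = rng.uniform(0.5, 1.0, size=rng.integers(8, 60))
            v[rng.uniform(size=len(v)) < 0.1] = np.nan
            got = [(e.start_bin, e.end_bin)
                   for e in sf.detect_events(_sa_from_values(v), 0.75,
                                             min_run_bins=min_run)]
            assert got == _scan_events(v, 0.75, min_run)


class TestThresholdSweep:
    def test_step_function_input(self):
        sa = _sa_from_values(np.full(60, 0.5))
        sweep = sf.threshold_sweep(sa, 0.01, 0.99, 0.02)
        below = sweep[sweep["threshold"] < 0.5]
        above = sweep[sweep["threshold"] > 0.5]
        np.testing.assert_array_equal(below["proportion"], 1.0)
        np.testing.assert_array_equal(above["proportion"], 0.0)
        assert len(sweep) == 50

    def test_monotone_and_matches_rerun(self, rng):
        v = rng.uniform(size=120)
        v[:7] = np.nan
        sa = _sa_from_values(v)
        sweep = sf.threshold_sweep(sa, 0.01, 0.99, 0.02)
        prop = sweep["proportion"].to_numpy()
        assert np.all(np.diff(prop) <= 1e-12)
        for thr in (0.01, 0.45, 0.99):
            events = sf.detect_events(sa, thr)
            expect = sum(e.n_bins for e in events) / len(sa)
            got = sweep.loc[np.isclose(sweep["threshold"], thr),
                            "proportion"].iloc[0]
            assert got == pytest.approx(expect)

    def test_bad_bounds_raise(self):
        sa = _sa_from_values(np.full(20, 0.5))
        with pytest.raises(ValueError):
            sf.threshold_sweep(sa, 0.9, 0.1)


def _meta(fish_id, release, recapture, truncated=False):
    return TagMetadata(fish_id=fish_id, species="bigeye",
                       release_time=pd.Timestamp(release),
                       recapture_time=(None if recapture is None
                                       else pd.Timestamp(recapture)),
                       truncated=truncated)


class TestSummaries:
    def test_two_day_event_in_twenty_days_is_tenth(self):
        v = np.full(160, 0.3)                  # 20 days of 3-h bins
        v[:7] = np.nan
        v[40:56] = 0.9                         # one 16-bin (2-day) event
        sa = _sa_from_values(v)
        meta = _meta("f1", sa.bin_starts[0],
                     sa.bin_starts[0] + pd.Timedelta(days=20))
        events = sf.detect_events(sa, 0.75)
        s = sf.summarize_fish(events, sa, meta)
        assert s.prop_surface_associated == pytest.approx(0.1)
        assert s.n_events == 1 and not s.has_release_event

    def test_events_per_month_arithmetic(self):
        n = 366                                # 45.75 days of bins
        v = np.full(n, 0.3)
        v[:7] = np.nan
        for s0 in (20, 100, 200):
            v[s0:s0 + 8] = 0.9
        sa = _sa_from_values(v)
        release = sa.bin_starts[0]
        meta = _meta("f1", release, release + pd.Timedelta(days=45.65625))
        s = sf.summarize_fish(sf.detect_events(sa, 0.75), sa, meta,
                              month_days=30.4375)
        assert s.events_per_month == pytest.approx(2.0)

    def test_release_and_recapture_events_flagged(self):
        v = np.full(300, 0.3)
        v[:7] = np.nan
        v[7:30] = 0.9                          # starts within first 24 h
        v[290:] = 0.9                          # overlaps final 24 h
        sa = _sa_from_values(v)
        meta = _meta("f1", sa.bin_starts[0],
                     sa.bin_starts[-1] + pd.Timedelta(hours=3))
        events = sf.detect_events(sa, 0.75)
        s = sf.summarize_fish(events, sa, meta)
        assert s.has_release_event and events[0].is_release_event
        assert s.has_recapture_event and events[-1].is_recapture_event
        assert s.release_event_days == pytest.approx(23 * 3 / 24)
        assert len(s.final_week_daily_sa) == 7
        assert s.final24_mean_sa is not None

    def test_truncated_series_skips_recapture_metrics(self):
        v = np.full(300, 0.3)
        v[:7] = np.nan
        sa = _sa_from_values(v)
        meta = _meta("f1", sa.bin_starts[0], None, truncated=True)
        s = sf.summarize_fish(sf.detect_events(sa, 0.75), sa, meta)
        assert s.final24_mean_sa is None
        assert s.has_recapture_event is None
        assert s.final_week_daily_sa == []

    def test_missing_recapture_on_complete_series_is_error(self):
        sa = _sa_from_values(np.full(60, 0.5))
        meta = _meta("f1", sa.bin_starts[0], None, truncated=False)
        with pytest.raises(ValueError, match="recapture"):
            sf.summarize_fish([], sa, meta)


class TestOutliers:
    def _frame(self, durations, release=None):
        release = release or [False] * len(durations)
        return pd.DataFrame({
            "fish_id": [f"f{i}" for i in range(len(durations))],
            "duration_days": durations,
            "is_release_event": release,
        })

    def test_single_extreme_value_flagged(self):
        df = sf.flag_outliers(self._frame([1, 1, 2, 2, 3, 3, 50]))
        assert df["is_outlier"].tolist() == [False] * 6 + [True]

    def test_equal_durations_unflagged(self):
        df = sf.flag_outliers(self._frame([2.0] * 8))
        assert not df["is_outlier"].any()

    def test_matches_direct_quantile_rule(self, rng):
        d = rng.lognormal(0.7, 0.8, size=60)
        df = sf.flag_outliers(self._frame(d))
        q1, q3 = np.percentile(d, [25, 75])
        np.testing.assert_array_equal(df["is_outlier"],
                                      d > q3 + 1.5 * (q3 - q1))
        assert outlier_duration_threshold(d) == pytest.approx(q3 + 1.5 * (q3 - q1))

    def test_release_exclusion_variant(self):
        d = [1, 1, 2, 2, 3, 3, 10.0]
        rel = [False] * 6 + [True]
        summ_all = sf.outlier_summary(self._frame(d, rel))
        summ_excl = sf.outlier_summary(self._frame(d, rel), exclude_release=True)
        assert summ_all.n_outliers == 1
        assert summ_excl.n_events == 6 and summ_excl.n_outliers == 0

    def test_small_cohort_warns(self):
        with pytest.warns(UserWarning, match="fewer than 4"):
            df = sf.flag_outliers(self._frame([1, 2, 3]))
        assert not df["is_outlier"].any()


class TestDip:
    def test_known_exact_values(self):
        assert dip_statistic([5.0, 5.0, 5.0]) == 0.0
        assert dip_statistic([0, 0, 1, 1]) == pytest.approx(0.25, abs=1e-9)
        n = 20
        assert dip_statistic(np.arange(n) / n) == pytest.approx(1 / (2 * n),
                                                                abs=1e-9)

    def test_agrees_with_lp_oracle(self, rng):
        """Shape-constrained LP feasibility is the independent reference."""
        for trial in range(25):
            n = int(rng.integers(4, 14))
            if trial % 3 == 0:
                x = rng.uniform(size=n)
            elif trial % 3 == 1:
                x = np.concatenate([rng.normal(0, 0.05, n // 2),
                                    rng.normal(1, 0.05, n - n // 2)])
            else:
                x = rng.integers(0, 4, n).astype(float)
            if x.max() == x.min():
                continue
            assert dip_statistic(x) == pytest.approx(dip_lp(x), abs=1e-9)

    def test_separated_modes_are_significant(self):
        rng = np.random.default_rng(12)
        x = np.concatenate([rng.normal(0.2, 0.02, 50),
                            rng.normal(0.8, 0.02, 50)])
        res = sf.dip_test(x, n_boot=500, seed=1)
        assert res.p_value < 0.05

    def test_uniform_null_is_calibrated(self):
        """p-values on uniform data are not systematically small."""
        rng = np.random.default_rng(3)
        null = np.array([dip_statistic(rng.uniform(size=100))
                         for _ in range(400)])
        ps = []
        for _ in range(50):
            d = dip_statistic(rng.uniform(size=100))
            ps.append(np.mean(null >= d))
        assert np.median(ps) > 0.2

    def test_constant_input(self):
        res = sf.dip_test(np.full(10, 3.0), n_boot=50, seed=0)
        assert res.dip == 0.0 and res.p_value == 1.0

    def test_too_few_values_raise(self):
        with pytest.raises(ValueError):
            sf.dip_test([1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# Property-based invariants
# ---------------------------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays


probability_vectors = arrays(
    np.float64, st.integers(min_value=8, max_value=60),
    elements=st.floats(0.0, 1.0, allow_nan=False))


@settings(deadline=None, max_examples=60, derandomize=True)
@given(probability_vectors)
def test_running_mean_stays_within_posterior_hull(p):
    """The windowed mean is bounded by the window's min and max posterior."""
    sa = sf.surface_association(_posteriors(p))
    for t in range(7, len(p)):
        w = p[t - 7:t + 1]
        assert w.min() - 1e-12 <= sa.values[t] <= w.max() + 1e-12


@settings(deadline=None, max_examples=60, derandomize=True)
@given(probability_vectors, st.floats(0.05, 0.95))
def test_event_coverage_non_increasing_in_threshold(p, thr):
    """Raising the threshold never grows the event-covered bin set."""
    sa = sf.surface_association(_posteriors(p))
    lower = {b for e in sf.detect_events(sa, thr)
             for b in range(e.start_bin, e.end_bin + 1)}
    higher = {b for e in sf.detect_events(sa, min(0.99, thr + 0.1))
              for b in range(e.start_bin, e.end_bin + 1)}
    assert higher <= lower


@settings(deadline=None, max_examples=40, derandomize=True)
@given(arrays(np.float64, st.integers(min_value=4, max_value=30),
              elements=st.floats(0.0, 1.0, allow_nan=False)))
def test_dip_bounds(x):
    """0 <= dip <= 1/4, and dip >= 1/(2n) when two values differ."""
    d = dip_statistic(x)
    assert 0.0 <= d <= 0.25 + 1e-9
    if np.unique(x).size > 1:
        assert d >= 1.0 / (2 * len(x)) - 1e-9
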