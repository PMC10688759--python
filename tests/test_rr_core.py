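"""RR data model, file round-trips, windowing and trailing averages."""

import numpy as np
import pytest

from fetalhrv.errors import (
    OutOfRangeError,
    ParseError,
    ValidationError,
)
from fetalhrv.indices import hourly_values
from fetalhrv.rr import (
    IndexTrace,
    RRSeries,
    WindowSpec,
    load_rr,
    segment,
    trailing_average,
    window_grid,
    write_rr,
)

from conftest import constant_series


class TestLoading:
    def test_intervals_file_reconstructs_beat_times(self, tmp_path):
        path = tmp_path / "rr.txt"
        path.write_text("600\n610\n620\n")
        s = load_rr(path, "intervals_ms")
        np.testing.assert_allclose(s.beat_times, [0.0, 0.600, 1.210])
        np.testing.assert_allclose(s.rr_intervals, [600, 610, 620])

    def test_non_positive_interval_names_line(self, tmp_path):
        path = tmp_path / "rr.txt"
        path.write_text("600\n-5\n620\n")
        with pytest.raises(ValidationError, match="line 2"):
            load_rr(path, "intervals_ms")

    def test_malformed_line_names_line(self, tmp_path):
        path = tmp_path / "rr.txt"
        path.write_text("600\nsix hundred\n620\n")
        with pytest.raises(ParseError, match="line 2"):
            load_rr(path, "intervals_ms")

    def test_csv_dialect_matches_intervals_dialect(self, tmp_path):
        (tmp_path / "a.txt").write_text("600\n610\n")
        (tmp_path / "b.csv").write_text("0.0,600\n0.6,610\n")
        a = load_rr(tmp_path / "a.txt", "intervals_ms")
        b = load_rr(tmp_path / "b.csv", "beat_time_csv")
        np.testing.assert_allclose(a.beat_times, b.beat_times)
        np.testing.assert_allclose(a.rr_intervals, b.rr_intervals)

    @pytest.mark.parametrize("fmt", ["intervals_ms", "beat_time_csv"])
    def test_round_trip(self, tmp_path, rng, fmt):
        rr = rng.normal(350, 20, 200).clip(250, 500)
        s = RRSeries.from_intervals(rr)
        path = tmp_path / "out.txt"
        write_rr(s, path, fmt)
        back = load_rr(path, fmt)
        np.testing.assert_allclose(back.rr_intervals, s.rr_intervals, atol=0.5)
        np.testing.assert_allclose(back.beat_times, s.beat_times, atol=5e-4)


class TestSeriesInvariants:
    def test_too_short(self):
        with pytest.raises(ValidationError):
            RRSeries.from_intervals([500.0])

    def test_inconsistent_times_rejected(self):
        with pytest.raises(ValidationError, match="inconsistent"):
            RRSeries(beat_times=[0.0, 0.5, 1.0],
                     rr_intervals=[600.0, 500.0, 500.0])

    def test_oversized_interval_flagged_not_dropped(self):
        rr = [500.0, 2500.0, 500.0]
        times = [0.0, 0.5, 3.0]
        with pytest.warns(UserWarning, match="physiologic bound"):
            s = RRSeries(beat_times=times, rr_intervals=rr)
        assert s.n_beats == 3


class TestSegmentation:
    def test_first_minute_window(self):
        s = constant_series(500.0, 120.0)
        seg = segment(s, WindowSpec(60.0), t_end=60.0)
        assert seg.n_beats == 120  # window / interval
        assert seg.beat_times[0] == 0.0
        assert seg.beat_times[-1] < 60.0

    def test_t_end_beyond_record(self):
        s = constant_series(500.0, 120.0)
        with pytest.raises(OutOfRangeError):
            segment(s, WindowSpec(60.0), t_end=200.0)

    def test_window_count_matches_step(self):
        s = constant_series(500.0, 137.0)
        grid = window_grid(s, WindowSpec(60.0, step=1.0))
        assert grid.size == int(np.floor(s.duration - 60.0)) + 1

    def test_sparse_window_returns_missing(self):
        s = constant_series(500.0, 120.0)
        assert segment(s, WindowSpec(60.0), 60.0, min_beats=500) is None

    def test_beats_unit_window_takes_last_n_beats(self):
        s = constant_series(500.0, 120.0)
        seg = segment(s, WindowSpec(50, unit="beats"), t_end=60.0)
        assert seg.n_beats == 50
        assert seg.beat_times[-1] < 60.0


class TestTraceExport:
    def test_trace_csv_round_trips_with_missing(self, tmp_path):
        import pandas as pd

        tr = IndexTrace("SDNN", [1.0, 2.0, 3.0], [5.5, np.nan, 6.5])
        tr.to_csv(tmp_path / "trace.csv")
        back = pd.read_csv(tmp_path / "trace.csv")
        assert list(back.columns) == ["time_s", "SDNN"]
        assert back["SDNN"].isna()[1]
        np.testing.assert_allclose(back["SDNN"][[0, 2]], [5.5, 6.5])


class TestArtifactFilter:
    def test_clean_record_untouched(self):
        from fetalhrv.rr import median_filter_artifacts

        s = constant_series(500.0, 60.0)
        cleaned, rejected = median_filter_artifacts(s)
        assert not rejected.any()
        assert cleaned is s

    def test_single_outlier_rejected(self):
        from fetalhrv.rr import median_filter_artifacts

        rr = np.full(100, 400.0)
        rr[50] = 700.0  # 75% above the running median
        s = RRSeries.from_intervals(rr)
        cleaned, rejected = median_filter_artifacts(s)
        assert rejected.sum() == 1 and rejected[50]
        assert cleaned.n_beats == 99
        np.testing.assert_allclose(cleaned.rr_intervals, 400.0)


class TestTrailingAverage:
    def test_constant_trace(self):
        tr = IndexTrace("x", np.arange(1, 1301, dtype=float),
                        np.full(1300, 8.0))
        assert trailing_average(tr, at=1300.0) == pytest.approx(8.0)

    def test_alternating_trace(self):
        times = np.arange(1, 1201, dtype=float)
        vals = np.where(times % 2 == 0, 4.0, 6.0)
        tr = IndexTrace("x", times, vals)
        assert trailing_average(tr, at=1200.0) == pytest.approx(5.0)

    def test_mostly_missing_window_is_missing(self, rng):
        times = np.arange(1, 1201, dtype=float)
        vals = np.full(1200, 3.0)
        missing = rng.choice(1200, size=840, replace=False)  # 70% missing
        vals[missing] = np.nan
        tr = IndexTrace("x", times, vals)
        assert np.isnan(trailing_average(tr, at=1200.0))

    def test_order_invariance_within_window(self, rng):
        """The trailing average is a mean: permuting sample values within
        the window cannot change it."""
        times = np.arange(1, 1201, dtype=float)
        vals = rng.normal(5, 1, 1200)
        tr1 = IndexTrace("x", times, vals)
        tr2 = IndexTrace("x", times, rng.permutation(vals))
        assert trailing_average(tr1, 1200.0) == pytest.approx(
            trailing_average(tr2, 1200.0))


class TestHourlyValues:
    def test_short_record_rejected_with_context(self):
        s = constant_series(500.0, 1199.0, subject_id="lps01", timepoint="H2")
        with pytest.raises(OutOfRangeError, match="lps01/H2"):
            hourly_values(s, ["SDNN"])

    def test_exact_trailing_span_is_defined(self):
        s = constant_series(500.0, 1200.5)
        vals = hourly_values(s, ["SDNN"], {"time": WindowSpec(60.0, step=10.0)})
        assert vals["SDNN"] == pytest.approx(0.0)

    def test_requested_indices_only(self):
        s = constant_series(500.0, 1201.0)
        vals = hourly_values(s, ["SDNN", "RMSSD"],
                             {"time": WindowSpec(60.0, step=10.0)})
        assert set(vals) == {"SDNN", "RMSSD"}

    def test_stationary_record_matches_single_window(self, rng):
        """For a stationary record the hourly value is within sampling noise
        of the index computed on any one full window."""
        from fetalhrv.time_domain import sdnn

        from conftest import make_segment

        rr = rng.normal(350, 10, 4000)
        s = RRSeries.from_intervals(rr)
        vals = hourly_values(s, ["SDNN"], {"time": WindowSpec(60.0, step=5.0)})
        one_window = sdnn(make_segment(rr[:170]))
        # sampling SD of an SD estimate: sigma/sqrt(2(n-1)) with n ~ 170
        tol = 2 * 10.0 / np.sqrt(2 * 169)
        assert abs(vals["SDNN"] - one_window) < 2 * tol
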