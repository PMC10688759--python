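import numpy as np
import pytest

from fetalhrv.rr import RRSegment, RRSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20231130)


def make_segment(intervals_ms, start=0.0, mean_spacing=None):
    """Build an RRSegment whose onsets are the cumulative interval times."""
    rr = np.asarray(intervals_ms, dtype=float)
    times = start + np.concatenate([[0.0], np.cumsum(rr[:-1]) / 1000.0])
    end = times[-1] + rr[-1] / 1000.0
    return RRSegment(beat_times=times, rr_intervals=rr, start=start, end=end)


def constant_series(rr_ms=500.0, duration_s=120.0, **meta):
    n = int(duration_s * 1000 / rr_ms)
    return RRSeries.from_intervals(np.full(n, rr_ms), **meta)


def modulated_segment(duration=64.0, mean_rr=350.0, amp=10.0, freq=0.4,
                      start=0.0):
    """Segment whose RR series carries one sinusoidal modulation."""
    times = [start]
    rr = []
    t = start
    while t < start + duration:
        interval = mean_rr + amp * np.sin(2 * np.pi * freq * t)
        rr.append(interval)
        t += interval / 1000.0
        times.append(t)
    return RRSegment(beat_times=np.array(times[:-1]),
                     rr_intervals=np.array(rr),
                     start=start, end=start + duration)


@pytest.fixture
def random_segments(rng):
    """Bank of physiologic random segments for oracle-equivalence checks."""
    segs = []
    for _ in range(200):
        n = int(rng.integers(30, 120))
        rr = rng.normal(350.0, 15.0, n).clip(200, 600)
        segs.append(make_segment(rr))
    return segs
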