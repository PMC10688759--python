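"""RR-interval data model, file I/O and the moving-window/trailing-average scheme.

The atomic input is an :class:`RRSeries`: beat-to-beat intervals in
milliseconds together with the onset time of each interval in seconds from
record start.  Indices are recomputed on a moving window that slides in
steps of ``step`` seconds (1 s by default), producing a per-second
:class:`IndexTrace`; the hourly value of an index is the arithmetic mean of
its trace over the trailing 20 minutes of the record.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    ConfigError,
    InsufficientDataError,
    OutOfRangeError,
    ParseError,
    ValidationError,
)

log = logging.getLogger(__name__)

#: Physiologic upper bound for a fetal RR interval (ms).  Intervals at or
#: above this are flagged with a warning but kept, so artifacts stay visible.
RR_UPPER_BOUND_MS = 2000.0

#: Tolerance for the beat-time / interval consistency invariant (ms).
CONSISTENCY_TOL_MS = 0.5


@dataclass
class RRSeries:
    """A subject-hour's beat-to-beat interval record.

    ``beat_times[i]`` is the onset (in seconds from record start) of the
    interval ``rr_intervals[i]`` (in ms); consecutive onsets therefore differ
    by the preceding interval.  The record ends at
    ``beat_times[-1] + rr_intervals[-1] / 1000``.
    """

    beat_times: np.ndarray
    rr_intervals: np.ndarray
    subject_id: str = ""
    timepoint: str = ""
    sampling_note: str = ""

    def __post_init__(self):
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.rr_intervals = np.asarray(self.rr_intervals, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = self.beat_times.size
        if n != self.rr_intervals.size:
            raise ValidationError(
                f"beat_times ({n}) and rr_intervals ({self.rr_intervals.size}) "
                "must have equal length"
            )
        if n < 2:
            raise ValidationError("an RR series needs at least 2 beats")
        bad = np.nonzero(self.rr_intervals <= 0)[0]
        if bad.size:
            raise ValidationError(
                f"non-positive RR interval(s) at index {bad.tolist()}"
            )
        high = np.nonzero(self.rr_intervals >= RR_UPPER_BOUND_MS)[0]
        if high.size:
            warnings.warn(
                f"{high.size} RR interval(s) >= {RR_UPPER_BOUND_MS:g} ms "
                f"(indices {high[:10].tolist()}...) exceed the fetal "
                "physiologic bound; kept and flagged",
                stacklevel=2,
            )
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValidationError("beat_times must be strictly increasing")
        # interval i must match the gap to the next onset (last one is open)
        gaps_ms = np.diff(self.beat_times) * 1000.0
        mismatch = np.nonzero(
            np.abs(gaps_ms - self.rr_intervals[:-1]) > CONSISTENCY_TOL_MS
        )[0]
        if mismatch.size:
            raise ValidationError(
                "rr_intervals inconsistent with beat_times at index "
                f"{mismatch.tolist()} (tolerance {CONSISTENCY_TOL_MS} ms)"
            )

    @classmethod
    def from_intervals(cls, intervals_ms, **meta) -> "RRSeries":
        """Build a series from intervals alone; first beat at t = 0."""
        rr = np.asarray(intervals_ms, dtype=float)
        times = np.concatenate([[0.0], np.cumsum(rr[:-1]) / 1000.0])
        return cls(beat_times=times, rr_intervals=rr, **meta)

    @property
    def duration(self) -> float:
        """Record length in seconds (end of the last interval)."""
        return float(self.beat_times[-1] + self.rr_intervals[-1] / 1000.0)

    @property
    def n_beats(self) -> int:
        return int(self.beat_times.size)


@dataclass
class RRSegment:
    """A windowed slice of an :class:`RRSeries` over ``[start, end)``."""

    beat_times: np.ndarray
    rr_intervals: np.ndarray
    start: float
    end: float

    @property
    def n_beats(self) -> int:
        return int(self.beat_times.size)

    @property
    def span(self) -> float:
        return self.end - self.start


@dataclass
class WindowSpec:
    """Analysis window for one index family.

    ``window_length`` is seconds when ``unit == "seconds"``, a beat count
    when ``unit == "beats"`` (entropy/fractal indices are defined per beat,
    not per second).  ``step`` is the recomputation interval of the moving
    window and ``trailing_average`` the averaging span for hourly values.
    """

    window_length: float
    step: float = 1.0
    trailing_average: float = 1200.0
    unit: str = "seconds"

    def __post_init__(self):
        if self.window_length <= 0 or self.step <= 0:
            raise ValidationError("window_length and step must be positive")
        if self.unit not in ("seconds", "beats"):
            raise ValidationError(f"unknown window unit {self.unit!r}")
        if self.unit == "seconds" and self.trailing_average < self.window_length:
            raise ValidationError(
                "trailing_average must cover at least one window"
            )


@dataclass
class IndexTrace:
    """Per-window values of one index over a record; NaN marks missing."""

    index_name: str
    times: np.ndarray
    values: np.ndarray
    step: float = 1.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValidationError("trace times must be strictly increasing")

    def to_csv(self, path) -> None:
        """Write the trace as ``time_s,<index_name>`` (missing as empty)."""
        with open(path, "w") as fh:
            fh.write(f"time_s,{self.index_name}\n")
            for t, v in zip(self.times, self.values):
                fh.write(f"{t:.3f},{'' if np.isnan(v) else format(v, '.9g')}\n")


# ---------------------------------------------------------------------------
# File I/O: two plain-text dialects
# ---------------------------------------------------------------------------

def load_rr(path, format: str = "intervals_ms", **meta) -> RRSeries:
    """Read an RR record.

    ``intervals_ms``
        One interval per line, in milliseconds; beat times reconstructed by
        cumulative sum with the first beat at t = 0.
    ``beat_time_csv``
        Header line then ``beat_time_s,rr_ms`` rows.
    """
    if format == "intervals_ms":
        intervals = []
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                text = raw.strip()
                if not text:
                    continue
                try:
                    value = float(text)
                except ValueError:
                    raise ParseError(
                        f"cannot parse RR interval {text!r}", line=lineno
                    ) from None
                if value <= 0:
                    raise ValidationError(
                        f"non-positive RR interval {value:g} on line {lineno}"
                    )
                intervals.append(value)
        if len(intervals) < 2:
            raise ValidationError(f"{path}: fewer than 2 intervals")
        return RRSeries.from_intervals(intervals, **meta)
    if format == "beat_time_csv":
        times, intervals = [], []
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                text = raw.strip()
                if not text:
                    continue
                parts = text.split(",")
                if lineno == 1 and not _is_number(parts[0]):
                    continue  # header
                if len(parts) != 2:
                    raise ParseError(
                        f"expected 2 comma-separated fields, got {len(parts)}",
                        line=lineno,
                    )
                try:
                    times.append(float(parts[0]))
                    intervals.append(float(parts[1]))
                except ValueError:
                    raise ParseError(
                        f"cannot parse row {text!r}", line=lineno
                    ) from None
        if len(intervals) < 2:
            raise ValidationError(f"{path}: fewer than 2 beats")
        return RRSeries(
            beat_times=np.asarray(times), rr_intervals=np.asarray(intervals), **meta
        )
    raise ConfigError(f"unknown RR file format {format!r}")


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_rr(series: RRSeries, path, format: str = "intervals_ms") -> None:
    """Write a record in either dialect (round-trips within 0.5 ms)."""
    if format == "intervals_ms":
        with open(path, "w") as fh:
            for rr in series.rr_intervals:
                fh.write(f"{rr:.6f}\n")
    elif format == "beat_time_csv":
        with open(path, "w") as fh:
            fh.write("beat_time_s,rr_ms\n")
            for t, rr in zip(series.beat_times, series.rr_intervals):
                fh.write(f"{t:.6f},{rr:.6f}\n")
    else:
        raise ConfigError(f"unknown RR file format {format!r}")


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

def segment(
    series: RRSeries,
    spec: WindowSpec,
    t_end: float,
    min_beats: int = 2,
) -> RRSegment | None:
    """Slice the window ending at ``t_end``.

    Seconds-unit windows take all beats whose onset lies in the half-open
    interval ``[t_end − L, t_end)``; beats-unit windows take the last
    ``window_length`` beats with onset before ``t_end``.  Returns ``None``
    (missing-marker) when fewer than ``min_beats`` beats fall inside.
    """
    duration = series.duration
    if t_end > duration + 1e-9:
        raise OutOfRangeError(
            f"t_end={t_end:g} s beyond record end ({duration:g} s)"
        )
    if spec.unit == "beats":
        hi = np.searchsorted(series.beat_times, t_end, side="left")
        lo = max(0, hi - int(spec.window_length))
        if hi - lo < max(min_beats, int(spec.window_length)):
            return None
        start = float(series.beat_times[lo])
    else:
        if t_end < spec.window_length - 1e-9:
            raise OutOfRangeError(
                f"t_end={t_end:g} s precedes the first full window "
                f"({spec.window_length:g} s)"
            )
        start = t_end - spec.window_length
        lo = np.searchsorted(series.beat_times, start - 1e-12, side="left")
        hi = np.searchsorted(series.beat_times, t_end - 1e-12, side="left")
        if hi - lo < min_beats:
            return None
    return RRSegment(
        beat_times=series.beat_times[lo:hi],
        rr_intervals=series.rr_intervals[lo:hi],
        start=start,
        end=float(t_end),
    )


def window_grid(series: RRSeries, spec: WindowSpec) -> np.ndarray:
    """Window end times for a full sweep of the record.

    With ``step = 1`` over a T-second record and an L-second window this is
    exactly ``floor(T − L) + 1`` windows, ending at L, L+step, ..., ≤ T.
    """
    T = series.duration
    if spec.unit == "beats":
        w = int(spec.window_length)
        if series.n_beats <= w:
            raise OutOfRangeError(
                f"record ({series.n_beats} beats) shorter than window ({w} beats)"
            )
        L = float(series.beat_times[w])  # first t_end with w prior beats
    else:
        L = spec.window_length
    if T < L:
        raise OutOfRangeError(
            f"record ({T:g} s) shorter than window ({L:g} s)"
        )
    n = int(np.floor((T - L) / spec.step + 1e-9)) + 1
    return L + spec.step * np.arange(n)


def compute_trace(
    series: RRSeries,
    func,
    spec: WindowSpec,
    index_name: str = "index",
    min_beats: int = 2,
) -> IndexTrace:
    """Evaluate ``func(segment) -> float`` on every window of the sweep.

    Windows with too few beats, or where ``func`` raises
    :class:`InsufficientDataError`, become NaN — never zero.
    """
    t_ends = window_grid(series, spec)
    values = np.full(t_ends.size, np.nan)
    n_missing = 0
    for i, t_end in enumerate(t_ends):
        seg = segment(series, spec, t_end, min_beats=min_beats)
        if seg is None:
            n_missing += 1
            continue
        try:
            values[i] = func(seg)
        except InsufficientDataError:
            n_missing += 1
    if n_missing:
        log.info(
            "%s: %d/%d windows with insufficient data",
            index_name, n_missing, t_ends.size,
        )
    return IndexTrace(index_name=index_name, times=t_ends, values=values,
                      step=spec.step)


def median_filter_artifacts(
    series: RRSeries,
    threshold: float = 0.30,
    kernel: int = 5,
) -> tuple[RRSeries, np.ndarray]:
    """Optional artifact rejection: drop intervals deviating more than
    ``threshold`` (fractional) from the running median of ``kernel``
    neighbours.  OFF by default throughout the pipeline — the reproduced
    procedure applies no correction — but available for noisy recordings.

    Returns the cleaned series and the boolean mask of rejected beats.
    """
    from scipy.signal import medfilt

    rr = series.rr_intervals
    running = medfilt(rr, kernel_size=kernel)
    rejected = np.abs(rr - running) > threshold * running
    # never reject so much that the series degenerates
    if rejected.sum() >= rr.size - 1:
        raise ValidationError("artifact filter would reject the whole record")
    if not rejected.any():
        return series, rejected
    # rebuild onsets from the surviving intervals (contiguous NN series)
    cleaned = RRSeries.from_intervals(
        rr[~rejected],
        subject_id=series.subject_id,
        timepoint=series.timepoint,
        sampling_note=(series.sampling_note
                       + f" [{int(rejected.sum())} artifact(s) removed]"),
    )
    return cleaned, rejected


def trailing_average(
    trace: IndexTrace,
    at: float,
    duration: float = 1200.0,
    max_missing_frac: float = 0.5,
) -> float:
    """Mean of the trace over ``(at − duration, at]``.

    Missing (NaN) samples are excluded from the mean; the result is itself
    missing when more than ``max_missing_frac`` of the expected samples
    (duration / step) are absent.
    """
    if at < duration - 1e-9:
        raise OutOfRangeError(
            f"trailing average at t={at:g} s needs {duration:g} s of trace"
        )
    mask = (trace.times > at - duration + 1e-12) & (trace.times <= at + 1e-12)
    vals = trace.values[mask]
    expected = max(1, int(round(duration / trace.step)))
    n_ok = int(np.isfinite(vals).sum())
    if n_ok < (1.0 - max_missing_frac) * expected:
        log.warning(
            "%s: trailing average at %.0f s missing (%d/%d samples present)",
            trace.index_name, at, n_ok, expected,
        )
        return float("nan")
    return float(np.nanmean(vals)) if n_ok else float("nan")


__all__ = [
    "RRSeries",
    "RRSegment",
    "WindowSpec",
    "IndexTrace",
    "load_rr",
    "write_rr",
    "segment",
    "window_grid",
    "compute_trace",
    "trailing_average",
    "RR_UPPER_BOUND_MS",
]
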