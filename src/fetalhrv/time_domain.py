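"""Time-domain variability indices: SDNN, RMSSD, STV and LTV.

STV and LTV follow the obstetric convention built on 3.75-second epochs
(16 epochs per analyzed minute): the epoch value is the mean RR interval of
the beats falling inside the epoch, STV is the mean absolute difference
between successive epoch values, and LTV is the range (max − min) of the 16
epoch values of a minute, averaged over the complete minutes of the window.

"Mean difference" for STV is taken as the mean ABSOLUTE difference: the
signed mean telescopes to ~0 for any quasi-stationary record and matches no
published STV usage.
"""

from __future__ import annotations

import numpy as np

from .errors import InsufficientDataError
from .rr import RRSegment

EPOCH_LENGTH_S = 3.75
EPOCHS_PER_MINUTE = 16  # 16 × 3.75 s = 60 s exactly


def sdnn(seg: RRSegment) -> float:
    """Sample standard deviation (n − 1 denominator) of the intervals, ms."""
    if seg.n_beats < 2:
        raise InsufficientDataError("SDNN needs >= 2 intervals")
    return float(np.std(seg.rr_intervals, ddof=1))


def rmssd(seg: RRSegment) -> float:
    """Root mean square of successive interval differences, ms."""
    if seg.n_beats < 3:
        raise InsufficientDataError("RMSSD needs >= 3 intervals")
    d = np.diff(seg.rr_intervals)
    return float(np.sqrt(np.mean(d * d)))


def epoch_means(seg: RRSegment, epoch_length: float = EPOCH_LENGTH_S) -> np.ndarray:
    """Mean RR per complete epoch, aligned to the window's left edge.

    Only epochs fully covered by the window are returned; an epoch that
    contains no beat is NaN (missing propagates, values are never invented).
    """
    n_epochs = int(np.floor((seg.span + 1e-9) / epoch_length))
    if n_epochs == 0:
        return np.empty(0)
    idx = np.floor((seg.beat_times - seg.start) / epoch_length).astype(int)
    keep = (idx >= 0) & (idx < n_epochs)
    idx, rr = idx[keep], seg.rr_intervals[keep]
    sums = np.bincount(idx, weights=rr, minlength=n_epochs)
    counts = np.bincount(idx, minlength=n_epochs)
    with np.errstate(invalid="ignore"):
        means = sums / counts
    means[counts == 0] = np.nan
    return means


def stv(seg: RRSegment) -> float:
    """Short-term variability: mean |Δ| between successive epoch means, ms."""
    means = epoch_means(seg)
    if np.isfinite(means).sum() < 2:
        raise InsufficientDataError("STV needs >= 2 complete epochs")
    d = np.abs(np.diff(means))
    d = d[np.isfinite(d)]  # pairs touching a missing epoch are skipped
    if d.size == 0:
        raise InsufficientDataError("STV: no adjacent pair of complete epochs")
    return float(np.mean(d))


def ltv(seg: RRSegment) -> float:
    """Long-term variability: mean per-minute range of the 16 epoch means, ms."""
    means = epoch_means(seg)
    n_minutes = means.size // EPOCHS_PER_MINUTE
    if n_minutes == 0:
        raise InsufficientDataError("LTV needs >= 1 complete minute (16 epochs)")
    ranges = []
    for m in range(n_minutes):
        block = means[m * EPOCHS_PER_MINUTE:(m + 1) * EPOCHS_PER_MINUTE]
        if np.isnan(block).any():
            continue  # minutes with a missing epoch are skipped
        ranges.append(block.max() - block.min())
    if not ranges:
        raise InsufficientDataError("LTV: every minute had a missing epoch")
    return float(np.mean(ranges))


__all__ = ["sdnn", "rmssd", "stv", "ltv", "epoch_means",
           "EPOCH_LENGTH_S", "EPOCHS_PER_MINUTE"]
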