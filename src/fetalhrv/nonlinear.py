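"""Nonlinear indices: Poincaré SD1/SD2, approximate entropy, DFA exponents.

Conventions
-----------
* SD1² is half the UNCENTRED second moment of successive differences,
  ``mean(ΔRR²)/2``, which makes the identity ``SD1 = RMSSD/√2`` exact.
  SD2² = 2·SDNN² − SD1² (sample-variance SDNN), clamped at 0 so floating
  point rounding can never produce a negative radicand.
* ApEn is Pincus' statistic with Chebyshev distance and self-matches
  counted: ApEn = Φ^m(r) − Φ^{m+1}(r) with Φ^m the mean over templates of
  ln C_i^m(r).  Defaults m = 2, r = 0.2 × segment SD.
* DFA integrates the centred series, splits it into non-overlapping boxes,
  removes a least-squares line per box, and fits the slope of log F(n) vs
  log n.  α1 uses 4–16-beat boxes, α2 16–64-beat boxes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .errors import InsufficientDataError, ValidationError
from .rr import RRSegment
from .time_domain import sdnn as _sdnn

#: ~8 log-spaced box sizes per fitted range.
ALPHA1_SCALES = (4, 5, 6, 8, 10, 12, 14, 16)
ALPHA2_SCALES = (16, 20, 24, 32, 40, 48, 56, 64)


@dataclass
class PoincareSummary:
    sd1: float
    sd2: float
    sd_ratio: float


@dataclass
class ApEnConfig:
    embedding_m: int = 2
    tolerance_factor: float = 0.2  # r = factor × segment SD
    min_beats: int = 50

    def __post_init__(self):
        if self.embedding_m < 1 or self.tolerance_factor <= 0:
            raise ValidationError("ApEn needs m >= 1 and a positive tolerance")


@dataclass
class DFAConfig:
    alpha1_scales: tuple = ALPHA1_SCALES
    alpha2_scales: tuple = ALPHA2_SCALES

    def __post_init__(self):
        for scales in (self.alpha1_scales, self.alpha2_scales):
            if len(scales) < 4 or np.any(np.diff(scales) <= 0):
                raise ValidationError(
                    "DFA scale lists must be increasing with >= 4 points"
                )


def poincare(seg: RRSegment) -> PoincareSummary:
    """Poincaré plot dispersions from plotting RR_{i+1} against RR_i."""
    if seg.n_beats < 3:
        raise InsufficientDataError("Poincaré needs >= 3 intervals")
    d = np.diff(seg.rr_intervals)
    sd1 = float(np.sqrt(np.mean(d * d) / 2.0))
    s = _sdnn(seg)
    sd2 = float(np.sqrt(max(0.0, 2.0 * s * s - sd1 * sd1)))
    ratio = sd2 / sd1 if sd1 > 0 else float("nan")
    return PoincareSummary(sd1=sd1, sd2=sd2, sd_ratio=ratio)


def apen(seg_or_x, config: ApEnConfig | None = None,
         r: float | None = None) -> float:
    """Approximate entropy of the interval series.

    ``r`` overrides the SD-scaled tolerance (used when comparing against a
    fixed-tolerance reference).  A zero-variance segment with no explicit
    ``r`` has no defined tolerance and returns NaN.
    """
    config = config or ApEnConfig()
    x = seg_or_x.rr_intervals if isinstance(seg_or_x, RRSegment) else \
        np.asarray(seg_or_x, dtype=float)
    if x.size < config.min_beats:
        raise InsufficientDataError(
            f"ApEn needs >= {config.min_beats} intervals"
        )
    if r is None:
        sd = float(np.std(x, ddof=1))
        if sd <= 0:
            return float("nan")
        r = config.tolerance_factor * sd
    m = config.embedding_m
    return _phi(x, m, r) - _phi(x, m + 1, r)


def _phi(x: np.ndarray, m: int, r: float) -> float:
    """Mean over templates of ln(fraction of templates within r), Chebyshev."""
    n_templ = x.size - m + 1
    X = np.lib.stride_tricks.sliding_window_view(x, m)
    counts = np.empty(n_templ)
    block = max(1, int(2**22 // (n_templ * m)))  # bound broadcast memory
    for lo in range(0, n_templ, block):
        hi = min(lo + block, n_templ)
        d = np.abs(X[lo:hi, None, :] - X[None, :, :]).max(axis=2)
        counts[lo:hi] = (d <= r).sum(axis=1)
    return float(np.mean(np.log(counts / n_templ)))


def dfa(seg_or_x, scales=ALPHA1_SCALES) -> float:
    """Detrended fluctuation scaling exponent over the given box sizes."""
    x = seg_or_x.rr_intervals if isinstance(seg_or_x, RRSegment) else \
        np.asarray(seg_or_x, dtype=float)
    scales = np.asarray(scales, dtype=int)
    if x.size < 4 * scales.max():
        raise InsufficientDataError(
            f"DFA needs >= {4 * scales.max()} beats for max scale "
            f"{scales.max()}"
        )
    y = np.cumsum(x - x.mean())
    log_f = np.empty(scales.size)
    for i, n in enumerate(scales):
        f = _fluctuation(y, int(n))
        if f <= 0:
            return float("nan")  # constant series has no fluctuation slope
        log_f[i] = np.log(f)
    slope, _ = np.polyfit(np.log(scales.astype(float)), log_f, 1)
    return float(slope)


@lru_cache(maxsize=128)
def _detrend_matrices(n: int):
    t = np.arange(n, dtype=float)
    design = np.vstack([np.ones(n), t])  # (2, n)
    proj = np.linalg.pinv(design.T)  # (2, n), shared across boxes and windows
    return design, proj


def _fluctuation(y: np.ndarray, n: int) -> float:
    """Pooled RMS residual of per-box linear detrending at box size n."""
    m = y.size // n
    boxes = y[: m * n].reshape(m, n)
    design, proj = _detrend_matrices(n)
    coef = boxes @ proj.T  # (m, 2) least-squares line per box
    resid = boxes - coef @ design
    return float(np.sqrt(np.mean(resid * resid)))


__all__ = ["PoincareSummary", "ApEnConfig", "DFAConfig", "poincare", "apen",
           "dfa", "ALPHA1_SCALES", "ALPHA2_SCALES"]
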