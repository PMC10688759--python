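"""Spectral indices: LF and HF band power of the RR tachogram and their ratio.

The irregularly sampled tachogram RR(t) is resampled onto a uniform grid by
cubic interpolation, mean-removed, and its power spectral density estimated
by Welch's method.  Band power is the integral of the density over the band:
LF covers [0.04, 0.15) Hz, HF covers [0.15, hf_high] Hz (half-open at
0.15 Hz, so a component exactly at the edge belongs to HF deterministically).
dB values are 10·log10 of the power referenced to 1 ms².  LF/HF is the ratio
of the LINEAR powers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal
from scipy.interpolate import CubicSpline

from .errors import InsufficientDataError, ValidationError
from .rr import RRSegment


@dataclass
class BandDefinition:
    lf_low: float = 0.04
    lf_high: float = 0.15
    hf_low: float = 0.15
    hf_high: float = 1.0

    def __post_init__(self):
        if not (0 < self.lf_low < self.lf_high == self.hf_low < self.hf_high):
            raise ValidationError(
                "bands must satisfy 0 < lf_low < lf_high = hf_low < hf_high"
            )

    def lf_mask(self, freqs: np.ndarray) -> np.ndarray:
        return (freqs >= self.lf_low) & (freqs < self.lf_high)

    def hf_mask(self, freqs: np.ndarray) -> np.ndarray:
        return (freqs >= self.hf_low) & (freqs <= self.hf_high)


@dataclass
class SpectrumEstimate:
    frequencies: np.ndarray
    power_density: np.ndarray  # ms²/Hz
    fs: float
    nperseg: int

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("frequency_hz,power_ms2_per_hz\n")
            for f, p in zip(self.frequencies, self.power_density):
                fh.write(f"{f:.9g},{p:.9g}\n")


def resample_tachogram(seg: RRSegment, fs: float = 4.0,
                       min_span: float = 25.0) -> tuple[np.ndarray, np.ndarray]:
    """Cubic interpolation of RR(t) onto a uniform grid; mean removed.

    Returns ``(t_grid, x)``; grid spacing is exactly ``1/fs``.  The span must
    cover at least one LF period (1 / 0.04 Hz = 25 s by default).
    """
    t, rr = seg.beat_times, seg.rr_intervals
    if t.size < 4 or t[-1] - t[0] < min_span:
        raise InsufficientDataError(
            f"segment span {t[-1] - t[0] if t.size else 0:.1f} s too short "
            "for LF resolution"
        )
    grid = t[0] + np.arange(int(np.floor((t[-1] - t[0]) * fs)) + 1) / fs
    x = CubicSpline(t, rr)(grid)
    return grid, x - x.mean()


def welch_spectrum(seg: RRSegment, fs: float = 4.0, seg_seconds: float = 64.0,
                   overlap: float = 0.5) -> SpectrumEstimate:
    """Welch PSD of the resampled tachogram (Hann window, 50% overlap)."""
    _, x = resample_tachogram(seg, fs=fs)
    nperseg = min(int(seg_seconds * fs), x.size)
    freqs, psd = sp_signal.welch(
        x, fs=fs, window="hann", nperseg=nperseg,
        noverlap=int(nperseg * overlap), detrend="constant",
    )
    return SpectrumEstimate(frequencies=freqs, power_density=psd,
                            fs=fs, nperseg=nperseg)


def band_power(seg: RRSegment, band: BandDefinition | None = None,
               fs: float = 4.0) -> dict:
    """LF/HF band powers in ms² and dB from the Welch spectrum.

    Zero power in a band makes its dB value NaN (log of zero), never -inf.
    """
    band = band or BandDefinition()
    spec = welch_spectrum(seg, fs=fs)
    f, p = spec.frequencies, spec.power_density
    lf = _integrate(f, p, band.lf_mask(f))
    hf = _integrate(f, p, band.hf_mask(f))
    return {
        "lf_ms2": lf,
        "hf_ms2": hf,
        "lf_db": 10.0 * np.log10(lf) if lf > 0 else float("nan"),
        "hf_db": 10.0 * np.log10(hf) if hf > 0 else float("nan"),
    }


def _integrate(freqs: np.ndarray, psd: np.ndarray, mask: np.ndarray) -> float:
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


def lf_hf_ratio(lf_ms2: float, hf_ms2: float) -> float:
    """Linear power ratio LF/HF; missing when HF power is zero."""
    if not np.isfinite(lf_ms2) or not np.isfinite(hf_ms2) or hf_ms2 <= 0:
        return float("nan")
    return float(lf_ms2 / hf_ms2)


__all__ = ["BandDefinition", "SpectrumEstimate", "resample_tachogram",
           "welch_spectrum", "band_power", "lf_hf_ratio"]
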