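"""Registry of the 14 supported HRV indices and hourly-value computation.

Indices are grouped into families that share an analysis window, so one
sweep of the moving window serves every index of the family:

========== =========================== ==========================
family     indices                     default window
========== =========================== ==========================
time       SDNN, RMSSD, STV, LTV       60 s
poincare   SD1, SD2, ratioSD           60 s
spectral   LF, HF, LFHF                256 s
apen       ApEn                        300 beats
dfa        DFA_a1, DFA_a2              512 beats
fsi        FSI                         64 s
========== =========================== ==========================

The per-index window lengths (other than the 64-s FSI window, which the
index definition fixes) are engineering defaults, exposed as configuration:
a 1-s recomputation step cannot itself carry a window, and each index needs
enough data for its own statistics (a DFA slope needs hundreds of beats, an
epoch-based LTV needs whole minutes).
"""

from __future__ import annotations

import logging

import numpy as np

from . import nonlinear, spectral, time_domain
from .errors import ConfigError, InsufficientDataError, OutOfRangeError
from .fsi import FSIConfig, fsi_from_segment
from .rr import IndexTrace, RRSeries, WindowSpec, segment, trailing_average, window_grid

log = logging.getLogger(__name__)

ALL_INDICES = (
    "SDNN", "RMSSD", "STV", "LTV",
    "LF", "HF", "LFHF",
    "SD1", "SD2", "ratioSD",
    "ApEn", "DFA_a1", "DFA_a2",
    "FSI",
)

FAMILY_OF = {
    "SDNN": "time", "RMSSD": "time", "STV": "time", "LTV": "time",
    "SD1": "poincare", "SD2": "poincare", "ratioSD": "poincare",
    "LF": "spectral", "HF": "spectral", "LFHF": "spectral",
    "ApEn": "apen",
    "DFA_a1": "dfa", "DFA_a2": "dfa",
    "FSI": "fsi",
}

DEFAULT_SPECS = {
    "time": WindowSpec(60.0),
    "poincare": WindowSpec(60.0),
    "spectral": WindowSpec(256.0),
    "apen": WindowSpec(300, unit="beats"),
    "dfa": WindowSpec(512, unit="beats"),
    "fsi": WindowSpec(64.0),
}

_MIN_BEATS = {"time": 4, "poincare": 3, "spectral": 30, "apen": 50,
              "dfa": 256, "fsi": 20}


def _eval_time(seg):
    out = {}
    for name, fn in (("SDNN", time_domain.sdnn), ("RMSSD", time_domain.rmssd),
                     ("STV", time_domain.stv), ("LTV", time_domain.ltv)):
        try:
            out[name] = fn(seg)
        except InsufficientDataError:
            out[name] = np.nan
    return out


def _eval_poincare(seg):
    p = nonlinear.poincare(seg)
    return {"SD1": p.sd1, "SD2": p.sd2, "ratioSD": p.sd_ratio}


def _eval_spectral(seg):
    bp = spectral.band_power(seg)
    return {"LF": bp["lf_db"], "HF": bp["hf_db"],
            "LFHF": spectral.lf_hf_ratio(bp["lf_ms2"], bp["hf_ms2"])}


def _eval_apen(seg):
    return {"ApEn": nonlinear.apen(seg)}


def _eval_dfa(seg):
    return {"DFA_a1": nonlinear.dfa(seg, nonlinear.ALPHA1_SCALES),
            "DFA_a2": nonlinear.dfa(seg, nonlinear.ALPHA2_SCALES)}


def _eval_fsi(seg, config: FSIConfig | None = None):
    return {"FSI": fsi_from_segment(seg, config)}


_FAMILY_EVAL = {
    "time": _eval_time,
    "poincare": _eval_poincare,
    "spectral": _eval_spectral,
    "apen": _eval_apen,
    "dfa": _eval_dfa,
    "fsi": _eval_fsi,
}


def compute_traces(
    series: RRSeries,
    indices=ALL_INDICES,
    specs: dict | None = None,
) -> dict[str, IndexTrace]:
    """Per-window traces for the requested indices.

    ``specs`` may override the window per index name or per family name.
    """
    indices = list(indices)
    unknown = [i for i in indices if i not in FAMILY_OF]
    if unknown:
        raise ConfigError(f"unknown index name(s): {unknown}")
    specs = specs or {}
    # group requested indices by (family, effective spec)
    by_family: dict[str, list[str]] = {}
    for name in indices:
        by_family.setdefault(FAMILY_OF[name], []).append(name)
    traces: dict[str, IndexTrace] = {}
    for family, members in by_family.items():
        spec = None
        for name in members:
            if name in specs:
                spec = specs[name]
        spec = spec or specs.get(family) or DEFAULT_SPECS[family]
        evaluate = _FAMILY_EVAL[family]
        t_ends = window_grid(series, spec)
        values = {name: np.full(t_ends.size, np.nan) for name in members}
        n_missing = 0
        for i, t_end in enumerate(t_ends):
            seg = segment(series, spec, t_end, min_beats=_MIN_BEATS[family])
            if seg is None:
                n_missing += 1
                continue
            try:
                result = evaluate(seg)
            except InsufficientDataError:
                n_missing += 1
                continue
            for name in members:
                values[name][i] = result[name]
        if n_missing:
            log.info("%s/%s family: %d/%d windows insufficient",
                     series.subject_id, family, n_missing, t_ends.size)
        for name in members:
            traces[name] = IndexTrace(index_name=name, times=t_ends,
                                      values=values[name], step=spec.step)
    return traces


def hourly_values(
    series: RRSeries,
    indices=ALL_INDICES,
    specs: dict | None = None,
    trailing: float = 1200.0,
    max_missing_frac: float = 0.5,
) -> dict[str, float]:
    """One value per index: trailing 20-min average of its trace at record end.

    The record must span at least the trailing-average duration.
    """
    if series.duration < trailing:
        raise OutOfRangeError(
            f"record {series.subject_id}/{series.timepoint} spans "
            f"{series.duration:.0f} s < trailing average {trailing:.0f} s"
        )
    traces = compute_traces(series, indices, specs)
    return {
        name: trailing_average(trace, at=series.duration, duration=trailing,
                               max_missing_frac=max_missing_frac)
        for name, trace in traces.items()
    }


__all__ = ["ALL_INDICES", "FAMILY_OF", "DEFAULT_SPECS", "compute_traces",
           "hourly_values"]
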