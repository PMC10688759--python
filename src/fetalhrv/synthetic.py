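"""Synthetic LPS/control fetal-sheep cohort generator.

Emulates the study conditions of an acute endotoxemia experiment in
chronically instrumented near-term fetal sheep: 8 LPS fetuses and 7 saline
controls, observed at baseline (H0) and hourly for six hours after
injection (H1–H6), each subject-hour contributing an RR-interval record
plus companion physiology (blood pressure, blood gases, lactate, IL-6).

RR model
--------
The instantaneous RR profile on a uniform grid is

    RR(t) = mean_RR + A_LF sin(2π·0.095·t + φ1) + A_HF sin(2π·0.4·t + φ2)
            + σ_f · fGn_α(t)

with fractional Gaussian noise generated by spectral synthesis
(power ∝ f^−β, β = 2α − 1), plus white per-beat measurement noise.  Beats
are placed by integrating the instantaneous rate 1/RR(t), so the spectral
content survives at the beat level.

The LPS effect structure is calibrated to the DIRECTION and approximate
ratio of the study's group medians, not to absolute index values (which
depend on unrecoverable windowing details of the original analysis):

* hours H2–H4 scale total interval variance up (global-variability surge;
  SDNN ratio ≈ 1.7–1.95) by inflating the fractional-noise amplitude, and
  pull the fractal exponent from 1.1 toward 0.5 (whiter, less complex —
  the DFA α1/α2 drop);
* hours H5–H6 raise mean FHR by ~25–30 bpm (tachycardia);
* control hours are stationary (any hour looks like baseline).

Companion physiology follows the study's group-median trajectories with
between-subject Gaussian noise (log-normal for IL-6, censored at the
7.8 pg/ml assay floor).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .errors import ConfigError
from .rr import RRSeries, write_rr

log = logging.getLogger(__name__)

HOURS = ("H0", "H1", "H2", "H3", "H4", "H5", "H6")
IL6_FLOOR = 7.8  # pg/ml assay detection limit

#: Group-median physiology trajectories over H0..H6 (per group) and noise
#: scales.  Medians follow the study's printed group trajectories; noise
#: scales are set to the order of the printed interquartile ranges.
PHYSIOLOGY_TRAJECTORIES: dict[str, dict] = {
    "MAP": {
        "LPS": [45.5, 49.0, 47.0, 44.5, 46.0, 42.0, 41.0],
        "Control": [48.0, 47.0, 45.0, 43.0, 48.0, 43.0, 47.0],
        "sd_between": 3.0, "sd_within": 1.5, "dist": "normal",
        "bounds": (20.0, 90.0),
    },
    "pH": {
        "LPS": [7.39, 7.39, 7.35, 7.32, 7.33, 7.33, 7.33],
        "Control": [7.41, 7.41, 7.41, 7.40, 7.41, 7.40, 7.40],
        "sd_between": 0.015, "sd_within": 0.010, "dist": "normal",
        "bounds": (7.0, 7.6),
    },
    "pCO2": {
        "LPS": [47.6, 49.3, 51.7, 54.4, 52.3, 52.4, 51.8],
        "Control": [48.1, 48.0, 48.3, 47.8, 48.1, 48.3, 47.8],
        "sd_between": 2.0, "sd_within": 1.0, "dist": "normal",
        "bounds": (25.0, 80.0),
    },
    "pO2": {
        "LPS": [17.0, 19.0, 19.5, 16.0, 16.0, 16.5, 16.5],
        "Control": [19.0, 19.0, 19.0, 19.0, 18.0, 19.0, 18.0],
        "sd_between": 2.0, "sd_within": 1.0, "dist": "normal",
        "bounds": (5.0, 40.0),
    },
    "BaseExcess": {
        "LPS": [3.5, 3.5, 1.0, 1.0, 0.5, 1.5, 1.0],
        "Control": [6.0, 6.0, 6.0, 6.0, 5.0, 6.0, 5.0],
        "sd_between": 1.5, "sd_within": 0.7, "dist": "normal",
        "bounds": (-15.0, 15.0),
    },
    "HCO3": {
        "LPS": [27.9, 28.2, 26.5, 26.3, 25.9, 26.1, 26.5],
        "Control": [30.2, 30.2, 30.2, 29.8, 29.8, 30.1, 29.0],
        "sd_between": 1.2, "sd_within": 0.6, "dist": "normal",
        "bounds": (10.0, 45.0),
    },
    "Lactate": {
        "LPS": [2.19, 2.44, 3.16, 4.44, 4.58, 5.29, 5.65],
        "Control": [2.55, 2.43, 2.35, 2.00, 2.12, 2.10, 2.09],
        "sd_between": 0.25, "sd_within": 0.15, "dist": "normal",
        "bounds": (0.3, 15.0),
    },
    "IL6": {
        # medians below the assay floor are reported at the floor
        "LPS": [5.0, 54.1, 1062.0, 3166.0, 3330.0, 3783.0, 3340.0],
        "Control": [2.5] * 7,
        "sigma_log": 0.35, "dist": "lognormal",
        "bounds": (IL6_FLOOR, 80000.0),
    },
}


@dataclass
class RRBaseline:
    """Stationary (control / H0) RR composition parameters."""

    lf_freq: float = 0.095   # Hz, slow vasomotor/baroreflex band
    lf_amp_ms: float = 5.0
    hf_freq: float = 0.40    # Hz, breathing-movement band
    hf_amp_ms: float = 4.0
    fgn_sd_ms: float = 6.0
    fgn_alpha: float = 1.1   # 1/f-like fractal exponent of a healthy fetus
    white_sd_ms: float = 2.0

    @property
    def total_var(self) -> float:
        return (self.lf_amp_ms**2 / 2 + self.hf_amp_ms**2 / 2
                + self.fgn_sd_ms**2 + self.white_sd_ms**2)


@dataclass
class LPSEffects:
    """Hour-by-hour LPS effect trajectories (H0..H6).

    ``sdnn_mult`` is the target multiplier on total interval SD (achieved by
    inflating the fractional-noise variance); ``fgn_alpha`` the fractal
    exponent trajectory; ``fhr_bpm`` the mean-FHR trajectory.
    """

    sdnn_mult: tuple = (1.00, 1.09, 1.71, 1.95, 1.90, 1.31, 1.18)
    fgn_alpha: tuple = (1.10, 1.05, 0.75, 0.65, 0.70, 0.95, 1.00)
    fhr_bpm: tuple = (173.0, 166.0, 174.0, 161.0, 181.0, 196.0, 203.0)

    def __post_init__(self):
        for name in ("sdnn_mult", "fgn_alpha", "fhr_bpm"):
            vals = getattr(self, name)
            if len(vals) != len(HOURS):
                raise ConfigError(f"{name} needs {len(HOURS)} hourly values")
            if min(vals) <= 0:
                raise ConfigError(f"{name} values must be positive")


@dataclass
class SyntheticCohortConfig:
    n_lps: int = 8
    n_control: int = 7
    record_length: float = 1500.0  # s per subject-hour
    seed: int = 0
    baseline: RRBaseline = field(default_factory=RRBaseline)
    lps_effects: LPSEffects = field(default_factory=LPSEffects)
    control_fhr_bpm: float = 177.0
    fhr_subject_sd: float = 4.0     # bpm, stable between-subject offset
    amp_subject_sigma: float = 0.12  # log-normal jitter on amplitudes
    grid_fs: float = 4.0            # Hz, profile grid for beat placement

    def __post_init__(self):
        if self.n_lps < 2 or self.n_control < 2:
            raise ConfigError("group sizes must be >= 2")
        if self.record_length < 1200.0:
            raise ConfigError(
                "record_length must be >= 1200 s (trailing-average span)"
            )

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False,
                           allow_unicode=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticCohortConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "baseline" in raw:
            raw["baseline"] = RRBaseline(**raw["baseline"])
        if "lps_effects" in raw:
            raw["lps_effects"] = LPSEffects(
                **{k: tuple(v) for k, v in raw["lps_effects"].items()}
            )
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"invalid cohort config: {exc}") from None


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    rr: dict           # hour -> RRSeries
    physiology: dict   # hour -> {variable: value}


@dataclass
class CohortDataset:
    subjects: list
    config: SyntheticCohortConfig

    def physiology_frame(self) -> pd.DataFrame:
        rows = []
        for subj in self.subjects:
            for hour in HOURS:
                row = {"subject": subj.subject_id, "group": subj.group,
                       "timepoint": hour}
                row.update(subj.physiology[hour])
                rows.append(row)
        return pd.DataFrame(rows)

    def iter_records(self):
        for subj in self.subjects:
            for hour in HOURS:
                yield subj.subject_id, subj.group, hour, subj.rr[hour]


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def spectral_fgn(n: int, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD fractional Gaussian noise with DFA exponent ≈ alpha.

    Spectral synthesis: random-phase Fourier amplitudes with power ∝ f^−β,
    β = 2α − 1 (β = 0 recovers white noise, β = 1 pink noise).
    """
    beta = 2.0 * alpha - 1.0
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros(freqs.size)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, freqs.size)
    x = np.fft.irfft(amp * np.exp(1j * phases), n)
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x


def _rng_for(seed: int, *key: int) -> np.random.Generator:
    """Splittable per-(subject, hour) stream: any record is reproducible in
    isolation from the master seed and its coordinates."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def generate_rr(
    mean_rr_ms: float,
    record_length: float,
    rng: np.random.Generator,
    baseline: RRBaseline | None = None,
    fgn_sd_ms: float | None = None,
    fgn_alpha: float | None = None,
    amp_scale: float = 1.0,
    grid_fs: float = 4.0,
    subject_id: str = "",
    timepoint: str = "",
) -> RRSeries:
    """One subject-hour RR record; beats placed by integrating 1/RR(t)."""
    b = baseline or RRBaseline()
    if mean_rr_ms <= 120.0 or mean_rr_ms >= 1500.0:
        raise ConfigError(f"mean RR {mean_rr_ms:g} ms outside fetal bounds")
    fgn_sd = b.fgn_sd_ms if fgn_sd_ms is None else fgn_sd_ms
    alpha = b.fgn_alpha if fgn_alpha is None else fgn_alpha
    # generate a small margin past the nominal length, then trim, so the
    # record always spans >= record_length despite beat quantization
    margin = 3.0 * mean_rr_ms / 1000.0 + 3.0
    n = int((record_length + margin) * grid_fs)
    t = np.arange(n) / grid_fs
    prof = np.full(n, float(mean_rr_ms))
    if b.lf_amp_ms > 0:
        prof += amp_scale * b.lf_amp_ms * np.sin(
            2 * np.pi * b.lf_freq * t + rng.uniform(0, 2 * np.pi))
    if b.hf_amp_ms > 0:
        prof += amp_scale * b.hf_amp_ms * np.sin(
            2 * np.pi * b.hf_freq * t + rng.uniform(0, 2 * np.pi))
    if fgn_sd > 0:
        prof += amp_scale * fgn_sd * spectral_fgn(n, alpha, rng)
    np.clip(prof, 0.5 * mean_rr_ms, 2.0 * mean_rr_ms, out=prof)
    rate = 1000.0 / prof  # beats per second
    cum = cumulative_trapezoid(rate, t, initial=0.0)
    n_beats = int(np.floor(cum[-1]))
    beat_t = np.interp(np.arange(1.0, n_beats + 1.0), cum, t)
    # keep ~1.5 s past the nominal end so summed per-beat noise (SD ~2 ms
    # x thousands of beats) cannot pull the total span below record_length
    cut = np.searchsorted(beat_t, record_length + 1.5, side="left")
    beat_t = beat_t[: min(cut + 1, beat_t.size)]
    rr = np.diff(beat_t, prepend=0.0) * 1000.0
    if b.white_sd_ms > 0:
        rr = rr + rng.normal(0.0, b.white_sd_ms, rr.size)
        rr = np.clip(rr, 0.3 * mean_rr_ms, None)
    return RRSeries.from_intervals(rr, subject_id=subject_id,
                                   timepoint=timepoint)


def _hour_rr_params(config: SyntheticCohortConfig, group: str, hour_idx: int,
                    fhr_offset_bpm: float) -> dict:
    """Resolve the RR generator knobs for one group-hour."""
    b = config.baseline
    if group == "LPS":
        eff = config.lps_effects
        fhr = eff.fhr_bpm[hour_idx] + fhr_offset_bpm
        mult = eff.sdnn_mult[hour_idx]
        alpha = eff.fgn_alpha[hour_idx]
    else:  # control hours are stationary by construction
        fhr = config.control_fhr_bpm + fhr_offset_bpm
        mult, alpha = 1.0, b.fgn_alpha
    other_var = b.lf_amp_ms**2 / 2 + b.hf_amp_ms**2 / 2 + b.white_sd_ms**2
    fgn_var = max(mult**2 * b.total_var - other_var, 0.25 * b.fgn_sd_ms**2)
    return {
        "mean_rr_ms": 60000.0 / fhr,
        "fgn_sd_ms": float(np.sqrt(fgn_var)),
        "fgn_alpha": alpha,
    }


def generate_physiology(config: SyntheticCohortConfig, group: str,
                        hour_idx: int, subject_effects: dict,
                        rng: np.random.Generator,
                        trajectories: dict | None = None) -> dict:
    """Companion physiology values for one subject-hour."""
    out = {}
    for var, spec in (trajectories or PHYSIOLOGY_TRAJECTORIES).items():
        median = spec[group][hour_idx]
        lo, hi = spec["bounds"]
        if spec["dist"] == "lognormal":
            val = median * np.exp(subject_effects[var]
                                  + rng.normal(0.0, spec["sigma_log"] / 2))
            val = max(val, IL6_FLOOR)  # censored at the assay floor
        else:
            val = median + subject_effects[var] \
                + rng.normal(0.0, spec["sd_within"])
        if not lo <= val <= hi:
            log.info("%s clamped to physiologic bounds [%g, %g]", var, lo, hi)
            val = float(np.clip(val, lo, hi))
        out[var] = float(val)
    return out


def generate_cohort(config: SyntheticCohortConfig | None = None,
                    out_dir=None) -> CohortDataset:
    """Full cohort: (n_lps + n_control) subjects × 7 timepoints.

    Deterministic under a fixed ``config.seed``.  When ``out_dir`` is given,
    per-record RR files (intervals_ms dialect), a manifest CSV, a physiology
    CSV and the config YAML are written there.
    """
    config = config or SyntheticCohortConfig()
    subjects = []
    groups = [("LPS", config.n_lps), ("Control", config.n_control)]
    si = 0
    for group, n_group in groups:
        for j in range(n_group):
            subject_id = f"{group.lower()}{j + 1:02d}"
            subj_rng = _rng_for(config.seed, si)
            fhr_offset = subj_rng.normal(0.0, config.fhr_subject_sd)
            amp_scale = float(np.exp(
                subj_rng.normal(0.0, config.amp_subject_sigma)))
            effects = {}
            for var, spec in PHYSIOLOGY_TRAJECTORIES.items():
                if spec["dist"] == "lognormal":
                    effects[var] = subj_rng.normal(0.0, spec["sigma_log"])
                else:
                    effects[var] = subj_rng.normal(0.0, spec["sd_between"])
            rr, physiology = {}, {}
            for hi, hour in enumerate(HOURS):
                hour_rng = _rng_for(config.seed, si, hi)
                params = _hour_rr_params(config, group, hi, fhr_offset)
                series = generate_rr(
                    params["mean_rr_ms"], config.record_length, hour_rng,
                    baseline=config.baseline,
                    fgn_sd_ms=params["fgn_sd_ms"],
                    fgn_alpha=params["fgn_alpha"],
                    amp_scale=amp_scale, grid_fs=config.grid_fs,
                    subject_id=subject_id, timepoint=hour,
                )
                rr[hour] = series
                phys = generate_physiology(config, group, hi, effects, hour_rng)
                # FHR is measured from the generated record, so the
                # physiology table and the RR data can never disagree
                phys["FHR"] = 60000.0 / float(np.mean(series.rr_intervals))
                physiology[hour] = phys
            subjects.append(SyntheticSubject(subject_id=subject_id,
                                             group=group, rr=rr,
                                             physiology=physiology))
            si += 1
    cohort = CohortDataset(subjects=subjects, config=config)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: CohortDataset, out_dir) -> pd.DataFrame:
    """Write RR files + manifest + physiology + config; returns the manifest."""
    out = Path(out_dir)
    (out / "rr").mkdir(parents=True, exist_ok=True)
    rows = []
    for subject, group, hour, series in cohort.iter_records():
        rel = f"rr/{subject}_{hour}.txt"
        write_rr(series, out / rel, format="intervals_ms")
        rows.append({"subject": subject, "group": group, "timepoint": hour,
                     "path": rel})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    cohort.physiology_frame().to_csv(out / "physiology.csv", index=False)
    cohort.config.to_yaml(out / "config.yaml")
    return manifest


__all__ = ["HOURS", "IL6_FLOOR", "PHYSIOLOGY_TRAJECTORIES", "RRBaseline",
           "LPSEffects", "SyntheticCohortConfig", "SyntheticSubject",
           "CohortDataset", "spectral_fgn", "generate_rr",
           "generate_physiology", "generate_cohort", "write_cohort"]
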