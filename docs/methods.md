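# Methods

This note documents the models, conventions and numerical choices behind
`fetalhrv`: what each index computes, how the moving-window/trailing-average
scheme is defined, what the synthetic cohort generator emulates (and what it
does not), and where genuinely open design questions were settled.

## Windowing and hourly values

Indices are recomputed continuously on a moving analysis window.  The
recomputation **step** defaults to 1 s; the window **length** is
index-specific, because a 1-s stretch of data cannot itself support a
standard deviation, a spectrum or a fractal slope:

| family | indices | window | rationale |
|---|---|---|---|
| time | SDNN, RMSSD, STV, LTV | 60 s | one full 16-epoch minute |
| Poincaré | SD1, SD2, ratioSD | 60 s | same statistics base as SDNN |
| spectral | LF, HF, LF/HF | 256 s | ≥10 LF periods for a stable Welch PSD |
| entropy | ApEn | 300 beats | ApEn is defined per beat count |
| fractal | DFA α1, α2 | 512 beats | ≥4 boxes at the largest (64-beat) scale |
| FSI | FSI | 64 s | fixed by the index definition |

All lengths are configuration (`WindowSpec`), not constants.  Windows are
half-open `[t − L, t)` on beat onset times; the interval "belonging" to a
beat is the interval starting at that onset.  A window with too few beats
yields a missing value (NaN), never a zero.

The hourly value of an index is the arithmetic mean of its per-window trace
over the trailing 20 min (1200 s) of the subject-hour record; the value is
missing when more than 50% of the expected trace samples are missing (a
policy of this artifact — the upstream definition is silent).  Because the
records are quasi-stationary within an hour, this trailing average is
insensitive to the recomputation step; cohort-scale runs (the numbered
analysis scripts and the multi-seed recovery experiment) therefore use a
30-s step, which changes hourly values by far less than their
between-subject spread while cutting compute by ~30×.

No artifact/ectopic-beat correction is applied by default (none is part of
the reproduced procedure); loading validates positivity, monotone beat
times and interval/beat-time consistency to 0.5 ms, and intervals ≥2000 ms
are flagged with a warning but kept visible.

## Index definitions

**SDNN** — sample standard deviation (n−1) of the window's intervals.

**RMSSD** — root mean square of successive interval differences.

**STV / LTV** — built on 3.75-s epochs aligned to the window's left edge
(16 epochs per analyzed minute).  The epoch value is the mean RR of the
beats inside the epoch; an epoch with no beats is missing and every
difference or range touching it is skipped.  STV is the mean **absolute**
difference between successive epoch values: the signed mean telescopes to
≈0 for any quasi-stationary record and matches no published STV usage, so
the absolute reading is adopted (and flagged here, since the source wording
says only "mean difference").  LTV is the range (max − min) of the 16 epoch
values of a minute, averaged over the window's complete minutes.

**LF / HF / LF-HF ratio** — the tachogram RR(t) is cubically interpolated
onto a uniform 4-Hz grid, mean-removed, and its PSD estimated by Welch's
method (Hann window, 64-s segments, 50% overlap).  Band power is the
trapezoidal integral of the density: LF = [0.04, 0.15) Hz,
HF = [0.15, 1.0] Hz.  The half-open edge makes a 0.15-Hz component belong
to HF deterministically.  The upper HF bound for a fetus beating at
~3 beats/s is not fixed anywhere authoritative; 1.0 Hz is the default and
is configuration.  dB values are 10·log10(power / 1 ms²); the ratio is
computed from the **linear** powers.  (The reproduced study's printed
LF/HF values are arithmetically inconsistent with its LF/HF dB rows under
any single convention, so the spectral pipeline here is documented rather
than claimed to match those numbers.)

**Poincaré SD1/SD2** — SD1² is half the *uncentred* second moment of
successive differences, `mean(ΔRR²)/2`, making `SD1 = RMSSD/√2` an exact
identity; SD2² = 2·SDNN² − SD1², clamped at zero against floating-point
rounding.  The identity `SD1² + SD2² = 2·SDNN²` then holds by construction.

**ApEn** — Pincus' approximate entropy: embedding m = 2, tolerance
r = 0.2 × segment SD (sample SD), Chebyshev distance, self-matches counted.
ApEn = Φ^m(r) − Φ^{m+1}(r) with Φ the mean log fraction of matching
templates.  All three choices are the dominant HRV convention and are
configuration.  Note ApEn is unimodal in r: it tends to zero for both very
small and very large tolerances and decreases monotonically past its peak.

**DFA α1/α2** — centre, cumulative-sum integrate, split into
non-overlapping boxes (tail remainder discarded), least-squares line per
box, pooled RMS residual F(n); the exponent is the OLS slope of log F vs
log n.  α1 fits 4–16-beat boxes (8 log-spaced scales), α2 16–64 beats.
Small-box DFA carries a known upward bias (white noise reads ≈0.59 on the
4–16-beat range); parameter-recovery checks therefore fit 16–256-beat
boxes, where synthesized noise at exponents 0.5/0.75/1.0 is recovered
within ±0.05.  The reproduced study prints DFA values on an implausible
"E-18" scale including negatives; this artifact computes standard
exponents and reproduces only the direction of the group effect.

**FSI** — the 64-s window's RR series is resampled at 8 Hz, normalized
(divided by the window-mean RR, then mean-removed — making it
dimensionless and heart-rate independent, which is how the published
constants can transfer across heart rates), and high-pass filtered above
0.15 Hz by a Daubechies-4 DWT (periodized, 5 levels at 8 Hz: the
approximation band [0, 0.125 Hz] is zeroed, details spanning 0.125–4 Hz
kept).  Upper/lower envelopes are linear interpolations through strict
local maxima/minima, held at the nearest extremum toward the edges and
pointwise-corrected so upper ≥ lower.  The inter-envelope area over the
window is split into four equal 16-s sub-areas; AUCmin is the smallest,
scaled by a normalization constant (default 4.0) chosen so a
moderate-variability near-term fetal segment yields AUCmin of order 1 —
the published calibration set for the constants a, b is unavailable, so
the absolute FSI level is a convention, while the algebra
FSI = 39.84·AUCmin + 9.38 clamped to [0, 100], the exact 9.38 score of a
steady rhythm, and monotonicity in fast-oscillation amplitude are all
exact, tested properties.

## Statistics

Within each group, each variable is screened across H0–H6 with a Friedman
test; post-hoc Wilcoxon signed-rank tests of each hour against baseline are
computed **only** when the screen rejects at p < 0.05 (the gate).
Between-group comparisons at each hour use the Mann–Whitney test.  All
tests are two-sided; no multiple-testing correction is applied — a faithful
reproduction of the original procedure, not an endorsement.

* Friedman: chi-square approximation on within-subject average ranks with
  tie correction (k−1 df) at study scale; for tiny designs without ties an
  exact permutation enumeration over (k!)^n orderings is available and is
  the default when (k!)^n ≤ 20 000.  Subjects with missing cells are
  excluded (logged) since the test needs a complete block design.
* Wilcoxon: zero differences dropped (Wilcoxon's convention); exact
  distribution for n ≤ 25, else normal approximation with tie/continuity
  correction.  Whether the original analysis used exact or approximate
  p-values at n = 8 is unknowable; exact is the default and configurable.
* Mann–Whitney: exact for min(n) ≤ 8 without ties, else asymptotic with
  corrections.  Under the null at n = 8 vs 7 the empirical rejection rate
  at 0.05 is ≈0.04 (the exact test is mildly conservative on a discrete
  support).
* Summaries are median (Q1; Q3) with quartiles by linear interpolation
  (type-7), so the formatted strings are bit-reproducible.

## Synthetic cohort generator

The generator emulates the study conditions — 8 LPS and 7 control
near-term fetal sheep at ~170–205 bpm, one ≥1200-s RR record per subject
per hour H0–H6 plus blood-gas/IL-6 physiology — with this RR model on a
uniform profile grid:

    RR(t) = mean_RR + A_LF sin(2π·0.095 t + φ) + A_HF sin(2π·0.40 t + φ')
            + σ_f · fGn_α(t),     plus N(0, 2 ms) per-beat noise.

Defaults: A_LF = 5 ms, A_HF = 4 ms, σ_f = 6 ms, α = 1.1, mean FHR 177 bpm
(control) — a composite interval SD of ≈7.8 ms, the order of the study's
baseline SDNN medians (8–12 ms).  Fractional Gaussian noise comes from
random-phase spectral synthesis with power ∝ f^−β, β = 2α − 1, giving the
DFA recovery tests a ground truth.  Beats are placed by integrating the
instantaneous rate 1/RR(t) and marking integer crossings, so spectral
content survives at the beat level.  Per-(subject, hour) RNG streams are
split from the master seed by coordinates, making any single record
reproducible in isolation.

The LPS effect structure is calibrated to the **direction and
median-ratio** of the study's findings, not to absolute index values
(which depend on unrecoverable windowing details of the original
pipeline):

* `sdnn_mult` = (1, 1.09, 1.71, 1.95, 1.90, 1.31, 1.18) over H0–H6 — the
  study's SDNN median ratios; achieved by inflating the fGn variance so the
  composite interval SD scales by the target factor;
* `fgn_alpha` = (1.10, 1.05, 0.75, 0.65, 0.70, 0.95, 1.00) — the
  complexity loss: whiter, less correlated fluctuations at H2–H4 drive the
  DFA α1/α2 drop;
* `fhr_bpm` = (173, 166, 174, 161, 181, 196, 203) — the study's LPS FHR
  medians, producing tachycardia at H5–H6.  Control hours are stationary.
  The physiology table's FHR is measured from the generated record itself,
  so the two can never disagree.

Companion physiology follows the study's printed group-median trajectories
(MAP, pH, pCO2, pO2, base excess, HCO3, lactate, IL-6) with a
between-subject random effect plus within-subject noise at the order of
the printed IQRs; IL-6 is log-normal and censored at the 7.8 pg/ml assay
floor (control medians sit below the floor, so control IL-6 is reported at
the floor throughout).

**What passing tests do and do not show.**  The generator's variance surge
is broadband, so it leaks into indices the study found unchanged (RMSSD,
SD1, STV also rise in the synthetic LPS group) and the FHR shift moves the
spectral indices; the recovery experiment therefore only claims that the
pipeline re-detects the *modelled* effects (SDNN, LTV, SD2 up; DFA α1
down; H2–H4) and that a stationary group does not trip the criterion —
not that the generator reproduces the study's full selectivity pattern,
and not anything about real fetal ECG (no gestational-age drift, no fetal
behavioural states, no artifact/ectopy, no R-wave detection noise
structure).

## Problem sizes

The multi-seed recovery experiment regenerates 50 full cohorts (50 × 105
records) with a 30-s recomputation step over the four effect-carrying
indices; oracle-equivalence checks use 1000 random segments of 50–90
beats; DFA recovery uses 5 × 4096-beat records per exponent; null
calibration uses 2000 simulated 8-vs-7 comparisons.  These sizes put the
whole validation suite at a few minutes on one core.

## Known limitations

* Absolute FSI and spectral-dB levels are convention-dependent (documented
  above) and are not comparable to the original tables.
* The 4–16-beat DFA α1 range carries the standard small-box bias; values
  are comparable within this package, not across DFA implementations with
  different box handling.
* Welch band integration at a 1/64 Hz resolution smears tones near the
  0.15-Hz band edge across both bands; the half-open convention decides
  only the grid-point assignment.
* The Friedman exact path is feasible only for tiny designs; at study
  scale (n = 8, k = 7) the chi-square approximation is used, as in the
  original analysis software.
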