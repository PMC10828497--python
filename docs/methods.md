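# Methods

## Noise model

Beat-time errors are modeled as i.i.d. zero-mean perturbations added to
every beat time, in milliseconds, then the RR series is recomputed from the
perturbed times. Four families are parameterized so that the perturbation
standard deviation equals a target σ:

| family     | parameters                                   | variance |
|------------|----------------------------------------------|----------|
| gaussian   | μ̂ = 0, σ̂ = σ                                | σ²       |
| uniform    | lower = −√3 σ, upper = +√3 σ                  | σ²       |
| triangular | A = −√6 σ, B = 0, C = +√6 σ                   | σ²       |
| student_t  | ν̂ = 3, σ̂ = σ/√3 (`variance_matched`, default) | σ²       |
| student_t  | ν̂ = 3, σ̂ = √((ν̂−1)σ²/ν̂) (`literal_eq4`)      | 2σ²      |

The two Student-*t* modes exist because the commonly quoted scale
σ̂ = √((ν−1)σ²/ν) at ν = 3 gives a noise variance of νσ̂²/(ν−2) = 2σ²,
i.e. an SD of √2·σ, not σ. The default mode matches the variance to σ² via
σ̂ = σ√((ν−2)/ν); the literal mode reproduces the other parameterization
exactly. ν = 3 is the smallest integer ν with a finite second moment, so
the tails are as heavy as possible while σ remains defined.

σ = 0 is accepted as the degenerate zero-noise case (all draws exactly
zero); this makes the zero-noise identity — bias = MAE = RMSE = 0 — exact
rather than approximate. Perturbations that would break beat-time
monotonicity are *resampled* (up to 100 rounds) rather than clipped,
because clipping would distort the noise distribution; at σ ≤ 10 ms and
RR ≥ 300 ms such draws are vanishingly rare.

Two analytic consequences are used as oracles throughout the tests:
differencing i.i.d. beat noise gives interval noise with variance 2σ²
(triangular-distributed when the beat noise is uniform), and second
differencing gives var(ε_{i+2} − 2ε_{i+1} + ε_i) = 6σ², so the expected
mean squared successive difference (RMSSD²) inflates by exactly 6σ².

## Synthetic cohort

Real resting recordings are emulated by integral pulse frequency
modulation: a beat is emitted whenever ∫r dt crosses an integer, with
r(t) = r₀(1 + m(t)) and m(t) the sum of two band-limited zero-mean Gaussian
processes — one spanning 0.04–0.15 Hz (LF) and one of 0.1 Hz bandwidth
centered at the respiratory frequency (default 0.25 Hz, HF). Each component
is scaled so the *measured* RR band power matches its target: because one
RR interval averages the modulation over a beat period T, a component at
frequency f is attenuated by sinc(fT), and the generator pre-compensates
this factor at each band's center frequency. The modulation is synthesized
in the frequency domain at 4 Hz, interpolated with a cubic spline, and the
IPFM integral evaluated by trapezoidal rule on a 1-ms grid (beat times by
linear inverse interpolation of the integral; timing error ≪ 1 µs, far
below the 1-ms noise floor studied). When both band powers are zero the
integral is linear and beats are placed in closed form, making the
zero-modulation tachogram exactly regular.

Defaults describe a resting healthy adult cohort: population mean heart
rate 69 bpm with between-subject SD 9.6 bpm (per-recording rates drawn from
a normal truncated to 40–120 bpm), 8-min recordings, LF/HF target powers
1100/1300 ms². These choices put the population means of the common
parameters (MeanRR, SDNN, RMSSD, spectral powers) inside typical 5th–95th
percentile brackets for large resting cohorts, and give ~344 ± 48 beats per
5-min window. What the generator does *not* emulate: ectopic beats,
respiration–blood-pressure coupling, age dependence, nonstationarity
beyond the band-limited modulation, and 1/f very-low-frequency structure
(so DFA α₂ runs low relative to real cohorts). Passing tests therefore
demonstrate correct propagation of *timing* noise through the metric suite,
not robustness to rhythm abnormalities or slow drifts.

## Segment sampling

5-min analysis windows are drawn by choosing a recording uniformly at
random (with replacement, unweighted), then a start beat uniformly among
beats with ≥ 300 s of recording remaining, and including every beat in the
half-open window [t_start, t_start + 300 s); windows may overlap.
Recordings shorter than the window are excluded from the draw. A
convergence table reports, per parameter, the normalized standard error
1.96·σ_s/(√n·μ_s) and the smallest n pushing it below 2% (capped at
15,000).

## HRV parameters — numerical conventions

All internals use RR in milliseconds and beat times in seconds. No beat
correction, artifact detection or detrending is applied anywhere.

* **SDNN, SD2**: SD with N−1 denominator. **RMSSD**: uncentered RMS of the
  N−1 successive differences. **SD1** is defined as RMSSD/√2 (uncentered
  convention), so the SD1–RMSSD identity holds exactly.
* **NN50/pNN50**: strict |ΔRR| > 50 ms; pNN50 normalized by the number of
  RR intervals.
* **HRVti/TINN**: RR histogram with 1/128-s bins aligned to multiples of
  the bin width. HRVti = total count / modal count. TINN is the base of the
  least-squares triangle with apex fixed at the modal bin height, endpoints
  searched on the bin-center grid (padded 4 bins beyond the occupied range;
  ties broken toward the narrower triangle, so a one-bin histogram gives
  TINN = 0).
* **SI**: √(AMo·100% / (2·Mo·MxDMn)) on a 50-ms histogram, Mo the modal bin
  center (s), MxDMn the RR range (s); ranges below 1e−9 s (constant up to
  float jitter) are flagged.
* **PRSA DC/AC**: anchors are intervals longer (DC) / shorter (AC) than
  their predecessor, excluding relative changes > 5%; four-point capacity
  (X(0)+X(1)−X(−1)−X(−2))/4 over anchors with a full window, modified
  two-point variants (X(0)−X(−1))/2 over all anchors.
* **Spectrum**: RR anchored at the time of the beat ending each interval,
  cubic-spline interpolated, sampled at 4 Hz; Welch PSD with 150-s Hann
  windows, 50% overlap, per-window mean removal only. Band powers by
  trapezoidal integration with interpolated band edges (VLF 0–0.04, LF
  0.04–0.15, HF 0.15–0.4 Hz); total power = VLF+LF+HF, normalized units
  exclude VLF so nLF + nHF = 100 identically; LF/HF is flagged when HF = 0.
* **ApEn/SampEn**: m = 2, r = 0.2·SD of the segment floored at 1e−6 ms,
  Chebyshev distance; ApEn includes self-matches, SampEn excludes them and
  uses equal template counts at lengths m and m+1; no matches → flagged.
* **DFA**: integrated mean-centered series, first-order detrending in
  non-overlapping boxes, α₁ over all box sizes 4–16 (needs ≥ 100
  intervals), α₂ over 16–64 (≥ 130).
* **D2**: Grassberger–Procaccia with embedding 10, delay 1, Euclidean
  distance; the slope of log C(r) vs log r is fitted where
  max(1e−3, 10/pairs) ≤ C(r) ≤ 0.25, skipping the sparse small-distance
  tail and saturation near the attractor diameter.
* **RPA**: embedding 10, delay 1, threshold √m·SD(rr), Euclidean norm,
  line-of-identity excluded, minimum diagonal line length 2; ShanEn is the
  natural-log entropy of the line-length distribution. A constant series is
  fully recurrent (REC = 100); note that even then the diagonal lines have
  many different lengths, so DET is just below 100 and ShanEn > 0 — the
  combinatorics of the recurrence matrix, not an artifact.
* **Sentinels**: any undefined value is NaN plus a reason code on the
  profile; the evaluation drops sentinel pairs per parameter and reports
  their counts, so undefined segments never silently bias the aggregates.

The profile computation accepts a parameter subset, used to keep large
sweeps economical when only a few parameters are under study.

MeanHR is defined as 60000/MeanRR throughout. (Published reference tables
sometimes list a cohort-mean heart rate alongside a mean RR that is not its
exact reciprocal, because the mean of a reciprocal is not the reciprocal of
the mean; this package always reports the ratio as defined.)

## Evaluation

Errors e = x̂ − x and averages a = (x̂ + x)/2 are recorded per segment,
parameter, family and σ. Cell statistics: bias (mean), MAE, RMSE and
5th/95th percentiles (linear interpolation between order statistics). The
linear sensitivity α is fitted through the origin across the σ grid on
per-σ aggregate statistics (10 points by default): bias against σ·x̄/100
(signed, so α_bias can be negative), MAE and RMSE against σ·|x̄|/100 (so
α_MAE, α_RMSE ≥ 0 as befits magnitudes); fit quality r is the Pearson
correlation of the statistic with σ. KS tests compare per-parameter error
samples between family pairs per σ (reported at σ = 5 and 7 ms by default,
significance at p < 0.05, no multiple-testing correction). Bland–Altman
tables give the Pearson r of a vs e, the bias line and the 1.96·SD limits
of agreement, evaluated at the largest σ of the first family. Each
(family, σ) condition uses an independent random stream spawned from the
master seed, so families are compared on independent noise and every run is
bit-reproducible.

## Problem sizes

The test suite exercises the pipeline at desk scale, chosen so the expected
behavior is statistically decidable: 10⁶ draws for the noise-SD checks,
500 segments for the variance-inflation laws and the MeanRR neutrality fit,
2000 segments for the qualitative sensitivity ordering (restricted to the
six parameters compared), 10⁵ alternating intervals for the triangular
differencing law (alternating intervals share no beat and are therefore
independent, as the KS null requires), and ≤ 200-point series for the
brute-force oracle equivalences. `scripts/acceptance.py` recomputes the two
headline quantities with 10⁶ draws and 500 segments respectively.

## Known limitations

* Noise is temporally independent; correlated errors (e.g. respiratory
  modulation of PPG pulse-arrival times), missed and extra beats are out of
  scope.
* Spectral estimates follow one declared convention (spline + Welch);
  other resamplers/AR spectra will shift frequency-domain values slightly.
* The D2 scaling region and the RPA threshold are declared choices; D2 in
  particular is sensitive to them and to series length.
* Absolute sensitivity coefficients depend on the cohort's ground-truth
  distribution; only the qualitative ordering generalizes across cohorts.
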