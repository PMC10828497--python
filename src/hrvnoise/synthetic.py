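"""Synthetic RR tachograms via integral pulse frequency modulation (IPFM).

The generator emulates resting sinus-rhythm recordings: an instantaneous
heart rate r(t) = r0 (1 + m(t)) is integrated and a beat is emitted each
time the integral crosses an integer.  The modulation m(t) is the sum of two
band-limited zero-mean Gaussian processes — one in the low-frequency band
(0.04-0.15 Hz, baroreflex/Mayer-wave activity) and one centered at the
respiratory frequency inside the high-frequency band (0.15-0.4 Hz,
respiratory sinus arrhythmia) — each scaled so that the resulting RR series
carries approximately the requested band power in ms^2.

Because noise is later added to the emitted *beat times*, perturbations have
the same meaning as timing errors of a QRS detector on real data.

Default cohort statistics target a resting healthy adult population:
mean heart rate 69 bpm with a between-subject SD of 9.6 bpm, and LF/HF band
powers of roughly 1.1e3 / 1.3e3 ms^2 so that common time- and
frequency-domain HRV values fall in physiologically typical ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .io import Tachogram

__all__ = ["CohortSpec", "generate_tachogram", "generate_cohort"]

HR_TRUNCATION_BPM = (40.0, 120.0)  # resting healthy cohort
_MOD_FS = 4.0       # Hz, frequency-domain synthesis grid of m(t)
_INT_DT = 1e-3      # s, trapezoidal integration step for the IPFM integral


@dataclass(frozen=True)
class CohortSpec:
    """Population-level description of a synthetic cohort."""

    n_recordings: int = 100
    duration: float = 480.0      # s per recording
    mean_hr: float = 69.0        # bpm, population mean
    hr_sd: float = 9.6           # bpm, between-subject SD
    lf_power: float = 1100.0     # ms^2, target RR power in 0.04-0.15 Hz
    hf_power: float = 1300.0     # ms^2, target RR power around resp_freq
    resp_freq: float = 0.25      # Hz, HF oscillation center
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_recordings < 1:
            raise ValueError("n_recordings must be >= 1")
        if self.mean_hr <= 0 or self.duration <= 0:
            raise ValueError("mean_hr and duration must be > 0")
        if self.lf_power < 0 or self.hf_power < 0:
            raise ValueError("band powers must be >= 0")
        if not (0.15 <= self.resp_freq <= 0.4):
            raise ValueError("resp_freq must lie inside 0.15-0.4 Hz")


def _bandlimited_noise(
    rng: np.random.Generator, duration: float, f_lo: float, f_hi: float
) -> np.ndarray:
    """Unit-variance Gaussian process band-limited to [f_lo, f_hi] at 4 Hz."""
    n = int(round(duration * _MOD_FS)) + 1
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / _MOD_FS)
    spec[(freqs < f_lo) | (freqs > f_hi)] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_tachogram(
    spec: CohortSpec,
    seed: int | np.random.Generator,
    mean_hr: float | None = None,
    recording_id: str = "",
) -> Tachogram:
    """Generate one IPFM tachogram of ``spec.duration`` seconds.

    ``mean_hr`` overrides the population mean for this recording (used by
    :func:`generate_cohort` to draw per-recording rates).  Raises if the
    requested modulation powers drive the instantaneous rate non-positive.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    hr = spec.mean_hr if mean_hr is None else float(mean_hr)
    mean_rr_ms = 60000.0 / hr

    if spec.lf_power == 0 and spec.hf_power == 0:
        # zero modulation: the IPFM integral is exactly linear, beats are
        # equally spaced — computed in closed form to avoid integration noise
        period = 60.0 / hr
        n_beats = int(math.floor(spec.duration / period))
        return Tachogram.from_beat_times(
            np.arange(n_beats + 1) * period, recording_id
        )

    hf_lo = max(0.15, spec.resp_freq - 0.05)
    hf_hi = min(0.40, spec.resp_freq + 0.05)
    t_mod = np.arange(int(round(spec.duration * _MOD_FS)) + 1) / _MOD_FS
    m = np.zeros_like(t_mod)
    # RR modulation of SD s (ms) corresponds to rate modulation of SD
    # s / mean_rr to first order, so the requested band power in the RR
    # series fixes the scale of each rate-modulation component.
    # Each RR interval averages the modulation over one beat period T, which
    # attenuates a component at frequency f by sinc(f T); pre-compensating at
    # the band center keeps the *measured* RR band power on target.
    period_s = 60.0 / hr
    if spec.lf_power > 0:
        gain = np.sinc(0.5 * (0.04 + 0.15) * period_s)
        m += (np.sqrt(spec.lf_power) / mean_rr_ms / gain) * _bandlimited_noise(
            rng, spec.duration, 0.04, 0.15
        )
    if spec.hf_power > 0:
        gain = np.sinc(spec.resp_freq * period_s)
        m += (np.sqrt(spec.hf_power) / mean_rr_ms / gain) * _bandlimited_noise(
            rng, spec.duration, hf_lo, hf_hi
        )
    if np.min(1.0 + m) <= 0.0:
        raise ValueError(
            "modulation drives the instantaneous rate non-positive; "
            "lower lf_power/hf_power"
        )

    # integrate r(t) = r0 (1 + m(t)) on a fine grid; beats at integer crossings
    t = np.arange(int(round(spec.duration / _INT_DT)) + 1) * _INT_DT
    rate = (hr / 60.0) * (1.0 + CubicSpline(t_mod, m)(t))
    increments = 0.5 * (rate[1:] + rate[:-1]) * _INT_DT
    phase = np.concatenate([[0.0], np.cumsum(increments)])
    n_beats = int(np.floor(phase[-1]))
    targets = np.arange(1, n_beats + 1, dtype=float)
    beat_times = np.interp(targets, phase, t)
    beat_times = np.concatenate([[0.0], beat_times])
    return Tachogram.from_beat_times(beat_times, recording_id)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError("truncated-normal rejection sampling failed")


def generate_cohort(spec: CohortSpec) -> list[Tachogram]:
    """Generate ``spec.n_recordings`` tachograms.

    Per-recording mean heart rates are Normal(mean_hr, hr_sd) truncated to
    40-120 bpm; per-recording random streams are spawned deterministically
    from ``spec.seed``, so identical specs give identical cohorts.
    """
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_recordings + 1)
    hr_rng = np.random.default_rng(children[0])
    cohort = []
    for i in range(spec.n_recordings):
        hr = _truncated_normal(
            hr_rng, spec.mean_hr, spec.hr_sd, *HR_TRUNCATION_BPM
        )
        cohort.append(
            generate_tachogram(
                spec,
                np.random.default_rng(children[i + 1]),
                mean_hr=hr,
                recording_id=f"synt{i:04d}",
            )
        )
    return cohort
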