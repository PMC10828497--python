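"""The 34-parameter HRV suite for 5-min RR segments.

Time-domain, frequency-domain and nonlinear heart-rate-variability
parameters computed on raw RR series: no beat correction, no noise
detection, and no detrending are applied, so that the influence of
beat-timing errors on each parameter is observed directly.

Degenerate inputs (constant series, too few beats, undefined ratios) yield
flagged sentinel values (NaN plus a reason code on the profile), never
silent wrong numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import welch
from scipy.spatial.distance import pdist, squareform

from .io import Segment, Tachogram

__all__ = [
    "PARAMETERS",
    "HRVProfile",
    "SpectralEstimate",
    "mean_rr_hr",
    "sdnn",
    "rmssd",
    "nn50_pnn50",
    "geometric",
    "stress_index",
    "prsa_dc_ac",
    "resample_rr",
    "welch_psd",
    "band_powers",
    "poincare",
    "apen",
    "sampen",
    "dfa",
    "correlation_sums",
    "corr_dim",
    "rpa_metrics",
    "hrv_profile",
    "profiles_to_frame",
]

#: canonical parameter order (Table-style abbreviations, CSV column names)
PARAMETERS = (
    "MeanRR", "MeanHR", "SDNN", "RMSSD", "NN50", "pNN50",
    "HRVti", "TINN", "SI",
    "DC", "DCmod", "AC", "ACmod",
    "LFpower", "HFpower", "TOTpower", "pLF", "pHF", "nLF", "nHF", "LF/HF",
    "SD1", "SD2", "SD2/SD1",
    "ApEn", "SampEn", "DFA_alpha1", "DFA_alpha2", "D2",
    "REC", "DET", "Lmean", "Lmax", "ShanEn",
)

VLF_BAND = (0.0, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

HIST_BIN_S = 1.0 / 128.0      # RR histogram bin width for HRVti/TINN
SI_BIN_MS = 50.0              # RR histogram bin width for the stress index
PRSA_MAX_REL_CHANGE = 0.05    # anchor exclusion threshold
ENTROPY_R_FLOOR = 1e-6        # ms, tolerance floor for near-constant series
RESAMPLE_FS = 4.0             # Hz
WELCH_WINDOW_S = 150.0


@dataclass(frozen=True)
class SpectralEstimate:
    """One-sided Welch PSD of the evenly resampled RR signal (ms^2/Hz)."""

    freqs: np.ndarray
    psd: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        p = np.asarray(self.psd, dtype=float)
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequency grid must be ascending")
        if np.any(p < 0):
            raise ValueError("PSD must be non-negative")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "psd", p)


@dataclass
class HRVProfile:
    """Named parameter values of one segment plus sentinel reasons."""

    values: dict[str, float]
    sentinels: dict[str, str] = field(default_factory=dict)
    recording_id: str = ""

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_series(self) -> pd.Series:
        return pd.Series(self.values)


# ---------------------------------------------------------------------------
# time domain


def mean_rr_hr(rr: np.ndarray) -> tuple[float, float]:
    """Mean RR interval (ms) and mean heart rate 60000/MeanRR (bpm)."""
    rr = np.asarray(rr, dtype=float)
    if rr.size < 1:
        raise ValueError("need at least one interval")
    mean_rr = float(rr.mean())
    return mean_rr, 60000.0 / mean_rr


def sdnn(rr: np.ndarray) -> float:
    """Standard deviation of RR intervals (ms), N-1 denominator."""
    rr = np.asarray(rr, dtype=float)
    if rr.size < 2:
        raise ValueError("need at least two intervals")
    return float(rr.std(ddof=1))


def rmssd(rr: np.ndarray) -> float:
    """Root mean square of successive RR differences (ms)."""
    rr = np.asarray(rr, dtype=float)
    if rr.size < 2:
        raise ValueError("need at least two intervals")
    d = np.diff(rr)
    return float(np.sqrt(np.mean(d * d)))


def nn50_pnn50(rr: np.ndarray) -> tuple[int, float]:
    """Count of successive differences strictly exceeding 50 ms, and that
    count relative to the number of RR intervals (%)."""
    rr = np.asarray(rr, dtype=float)
    if rr.size < 2:
        raise ValueError("need at least two intervals")
    nn50 = int(np.sum(np.abs(np.diff(rr)) > 50.0))
    return nn50, 100.0 * nn50 / rr.size


def _rr_histogram(rr: np.ndarray, width_ms: float):
    lo = math.floor(rr.min() / width_ms) * width_ms
    nbins = int(math.floor((rr.max() - lo) / width_ms)) + 1
    edges = lo + np.arange(nbins + 1) * width_ms
    counts, _ = np.histogram(rr, edges)
    centers = edges[:-1] + width_ms / 2.0
    return counts, centers


def geometric(rr: np.ndarray) -> tuple[float, float]:
    """HRV triangular index and TINN (ms) from the 1/128 s RR histogram.

    HRVti is the total beat count divided by the modal bin count.  TINN is
    the base width M - N of the triangle with apex fixed at the modal bin
    height that fits the histogram best in the least-squares sense
    (triangular interpolation).
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size < 2:
        raise ValueError("need at least two intervals")
    width = HIST_BIN_S * 1000.0
    counts, centers = _rr_histogram(rr, width)
    peak = int(np.argmax(counts))
    hrvti = rr.size / counts[peak]

    # extend the grid so the triangle base may pass the occupied range;
    # every zero-count bin under the triangle adds squared error, so the
    # optimum stays close to the data and a small pad suffices
    pad = 4
    y = np.concatenate([np.zeros(pad), counts, np.zeros(pad)]).astype(float)
    c = np.concatenate(
        [
            centers[0] + width * np.arange(-pad, 0),
            centers,
            centers[-1] + width * np.arange(1, pad + 1),
        ]
    )
    mo = peak + pad
    h = float(counts[peak])
    best = (np.inf, 0.0)
    for ni in range(0, mo + 1):
        for mi in range(mo, len(c)):
            q = np.zeros_like(y)
            if ni < mo:
                q[ni : mo + 1] = h * (c[ni : mo + 1] - c[ni]) / (c[mo] - c[ni])
            if mi > mo:
                q[mo : mi + 1] = h * (c[mi] - c[mo : mi + 1]) / (c[mi] - c[mo])
            q[mo] = h
            sse = float(np.sum((y - q) ** 2))
            base = c[mi] - c[ni]
            # ties broken toward the narrower triangle
            if sse < best[0] - 1e-12 or (
                abs(sse - best[0]) <= 1e-12 and base < best[1]
            ):
                best = (sse, base)
    return float(hrvti), float(best[1])


def stress_index(rr: np.ndarray) -> float:
    """Square root of the Baevsky stress index.

    SI = sqrt(AMo * 100% / (2 * Mo * MxDMn)) with Mo the modal 50-ms bin
    center (s), AMo the modal bin's relative frequency (%), and MxDMn the
    RR range (s).  Constant series (MxDMn = 0) are flagged.
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size < 2:
        raise ValueError("need at least two intervals")
    mxdmn = (rr.max() - rr.min()) / 1000.0
    if mxdmn < 1e-9:  # constant up to float jitter
        return float("nan")
    counts, centers = _rr_histogram(rr, SI_BIN_MS)
    peak = int(np.argmax(counts))
    mo = centers[peak] / 1000.0
    amo = 100.0 * counts[peak] / rr.size
    return float(math.sqrt(amo / (2.0 * mo * mxdmn)))


def prsa_dc_ac(rr: np.ndarray) -> tuple[float, float, float, float]:
    """Deceleration/acceleration capacity by phase-rectified averaging.

    Anchors are intervals longer (DC) or shorter (AC) than their
    predecessor, excluding anchors whose relative change exceeds 5%.  The
    four-point variants average (X(0)+X(1)-X(-1)-X(-2))/4 over anchors with
    a full window; the modified two-point variants average (X(0)-X(-1))/2
    over all anchors.  Returns (DC, DCmod, AC, ACmod) in ms; a capacity
    without anchors is NaN.
    """
    rr = np.asarray(rr, dtype=float)
    n = rr.size
    if n < 5:
        raise ValueError("need at least five intervals")
    prev = rr[:-1]
    change = rr[1:] - prev
    ok = np.abs(change) <= PRSA_MAX_REL_CHANGE * prev
    out = []
    for sign in (+1.0, -1.0):
        anchors = np.flatnonzero((sign * change > 0) & ok) + 1
        full = anchors[(anchors >= 2) & (anchors <= n - 2)]
        if full.size:
            four = (rr[full] + rr[full + 1] - rr[full - 1] - rr[full - 2]) / 4.0
            out.append(float(four.mean()))
        else:
            out.append(float("nan"))
        if anchors.size:
            out.append(float(((rr[anchors] - rr[anchors - 1]) / 2.0).mean()))
        else:
            out.append(float("nan"))
    return out[0], out[1], out[2], out[3]


# ---------------------------------------------------------------------------
# frequency domain


def resample_rr(
    tachogram: Tachogram, fs: float = RESAMPLE_FS
) -> tuple[np.ndarray, np.ndarray]:
    """Evenly sampled RR signal by cubic-spline interpolation.

    Each interval is anchored at the time of the beat that ends it; the
    spline is sampled at ``fs`` Hz between the first and last anchor.
    Returns (time grid s, RR signal ms).
    """
    if len(tachogram) < 4:
        raise ValueError("need at least four beats")
    t_rr = tachogram.beat_times[1:]
    spline = CubicSpline(t_rr, tachogram.rr)
    grid = t_rr[0] + np.arange(int((t_rr[-1] - t_rr[0]) * fs) + 1) / fs
    return grid, spline(grid)


def welch_psd(signal: np.ndarray, fs: float = RESAMPLE_FS) -> SpectralEstimate:
    """Welch PSD with 150-s Hann windows and 50% overlap (ms^2/Hz)."""
    signal = np.asarray(signal, dtype=float)
    nperseg = int(WELCH_WINDOW_S * fs)
    if signal.size < nperseg:
        raise ValueError(
            f"signal shorter than one {WELCH_WINDOW_S:.0f}-s Welch window"
        )
    freqs, psd = welch(
        signal,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
    )
    return SpectralEstimate(freqs, psd)


def _band_power(est: SpectralEstimate, lo: float, hi: float) -> float:
    inside = est.freqs[(est.freqs > lo) & (est.freqs < hi)]
    grid = np.unique(np.concatenate([[lo], inside, [hi]]))
    vals = np.interp(grid, est.freqs, est.psd)
    return float(np.trapezoid(vals, grid))


def band_powers(est: SpectralEstimate) -> dict[str, float]:
    """Band integrals and derived relative/normalized powers.

    Total power is the integral over 0-0.4 Hz (VLF + LF + HF exactly);
    normalized units exclude the VLF share, so nLF + nHF = 100 whenever
    LF + HF > 0.  Undefined ratios are NaN.
    """
    vlf = _band_power(est, *VLF_BAND)
    lf = _band_power(est, *LF_BAND)
    hf = _band_power(est, *HF_BAND)
    tot = vlf + lf + hf
    nan = float("nan")
    out = {"LFpower": lf, "HFpower": hf, "TOTpower": tot}
    out["pLF"] = 100.0 * lf / tot if tot > 0 else nan
    out["pHF"] = 100.0 * hf / tot if tot > 0 else nan
    if lf + hf > 0:
        out["nLF"] = 100.0 * lf / (lf + hf)
        out["nHF"] = 100.0 - out["nLF"]
    else:
        out["nLF"] = out["nHF"] = nan
    out["LF/HF"] = lf / hf if hf > 0 else nan
    return out


# ---------------------------------------------------------------------------
# nonlinear


def poincare(rr: np.ndarray) -> tuple[float, float, float]:
    """Poincare-plot short/long axis SDs and their ratio (ms, ms, -).

    SD1 is the RMS of successive differences divided by sqrt(2), i.e.
    SD1 = RMSSD/sqrt(2) identically; SD2 is the ddof=1 SD of
    (rr_i + rr_{i+1})/sqrt(2).
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size < 3:
        raise ValueError("need at least three intervals")
    sd1 = rmssd(rr) / math.sqrt(2.0)
    sd2 = float(((rr[1:] + rr[:-1]) / math.sqrt(2.0)).std(ddof=1))
    ratio = sd2 / sd1 if sd1 > 0 else float("nan")
    return sd1, sd2, ratio


def _entropy_tolerance(rr: np.ndarray, r: float | None) -> float:
    if r is None:
        r = 0.2 * float(np.std(rr, ddof=1))
    return max(r, ENTROPY_R_FLOOR)


def _chebyshev_template_dist(x: np.ndarray, m: int) -> np.ndarray:
    """n x n Chebyshev distances between all length-m templates of x."""
    n = x.size - m + 1
    d = np.zeros((n, n))
    for k in range(m):
        seg = x[k : k + n]
        np.maximum(d, np.abs(seg[:, None] - seg[None, :]), out=d)
    return d


def apen(rr: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Approximate entropy (self-matches included, Chebyshev distance)."""
    rr = np.asarray(rr, dtype=float)
    if rr.size < m + 2:
        raise ValueError("need at least m+2 intervals")
    r = _entropy_tolerance(rr, r)
    phi = []
    for mm in (m, m + 1):
        d = _chebyshev_template_dist(rr, mm)
        c = (d <= r).mean(axis=1)
        phi.append(float(np.mean(np.log(c))))
    return phi[0] - phi[1]


def sampen(rr: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy -ln(A/B) (self-matches excluded); NaN when no matches."""
    rr = np.asarray(rr, dtype=float)
    if rr.size < m + 2:
        raise ValueError("need at least m+2 intervals")
    r = _entropy_tolerance(rr, r)
    n_templ = rr.size - m  # same template count at lengths m and m+1
    counts = []
    for mm in (m, m + 1):
        d = _chebyshev_template_dist(rr, mm)[:n_templ, :n_templ]
        match = d <= r
        counts.append(int(match.sum() - n_templ))  # exclude self-matches
    a, b = counts[1], counts[0]
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def dfa(
    rr: np.ndarray,
    short_range: tuple[int, int] = (4, 16),
    long_range: tuple[int, int] = (16, 64),
) -> tuple[float, float]:
    """Detrended fluctuation analysis slopes (alpha1, alpha2).

    The mean-centered RR series is integrated; in non-overlapping boxes of
    each size a first-order trend is removed and the RMS fluctuation F(s)
    computed; alpha is the log-log slope of F vs box size (alpha1 over
    boxes 4-16, alpha2 over 16-64).  A slope is NaN when the series is too
    short (alpha1 < 100, alpha2 < 130 intervals) or degenerate.
    """
    rr = np.asarray(rr, dtype=float)
    n = rr.size
    y = np.cumsum(rr - rr.mean())

    def slope(lo: int, hi: int) -> float:
        sizes = np.arange(lo, hi + 1)
        fl = []
        for s in sizes:
            nb = n // s
            boxes = y[: nb * s].reshape(nb, s)
            t = np.arange(s, dtype=float)
            t -= t.mean()
            boxes = boxes - boxes.mean(axis=1, keepdims=True)
            beta = boxes @ t / np.dot(t, t)
            resid = boxes - beta[:, None] * t
            fl.append(math.sqrt(float(np.mean(resid * resid))))
        fl = np.asarray(fl)
        if np.any(fl <= 0):
            return float("nan")
        return float(np.polyfit(np.log(sizes), np.log(fl), 1)[0])

    a1 = slope(*short_range) if n >= 100 else float("nan")
    a2 = slope(*long_range) if n >= 130 else float("nan")
    return a1, a2


def _embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    n = x.size - (m - 1) * tau
    if n < 2:
        raise ValueError("series too short for the requested embedding")
    idx = np.arange(n)[:, None] + np.arange(m)[None, :] * tau
    return x[idx]


def correlation_sums(
    rr: np.ndarray, radii: np.ndarray, m: int = 10, tau: int = 1
) -> np.ndarray:
    """Grassberger-Procaccia correlation sums C(r) at the given radii.

    C(r) is the fraction of distinct embedded-vector pairs with Euclidean
    distance <= r.
    """
    x = _embed(np.asarray(rr, dtype=float), m, tau)
    d = np.sort(pdist(x))
    return np.searchsorted(d, np.asarray(radii, dtype=float), side="right") / d.size


def corr_dim(rr: np.ndarray, m: int = 10, tau: int = 1) -> float:
    """Correlation dimension D2: slope of log C(r) vs log r.

    The slope is fitted over the scaling region where the correlation sum
    lies between 1e-3 (but at least 10 pairs) and 0.25, which skips both
    the sparsely populated small-distance tail and the saturation near the
    attractor diameter.  NaN for constant or too-short series.
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size < 200:
        return float("nan")
    x = _embed(rr, m, tau)
    d = pdist(x)
    positive = d[d > 0]
    if positive.size == 0:
        return float("nan")
    radii = np.geomspace(np.min(positive), np.max(d), 60)
    c = correlation_sums(rr, radii, m, tau)
    lo = max(1e-3, 10.0 / d.size)
    mask = (c >= lo) & (c <= 0.25)
    if mask.sum() < 3:
        return float("nan")
    return float(np.polyfit(np.log(radii[mask]), np.log(c[mask]), 1)[0])


def rpa_metrics(
    rr: np.ndarray, m: int = 10, tau: int = 1, lmin: int = 2
) -> tuple[float, float, float, float, float]:
    """Recurrence-plot analysis: (REC %, DET %, Lmean, Lmax, ShanEn).

    Embedded vectors recur when their Euclidean distance is at most
    r = sqrt(m) * SD(rr).  The line-of-identity is excluded.  Diagonal
    lines of length >= ``lmin`` define determinism, the mean and maximum
    line length, and the Shannon entropy of the line-length distribution.
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size < m * tau + 10:
        raise ValueError("series too short for recurrence analysis")
    x = _embed(rr, m, tau)
    nv = x.shape[0]
    r = math.sqrt(m) * float(np.std(rr, ddof=1))
    rec_matrix = squareform(pdist(x)) <= r
    n_recurrent = int(rec_matrix.sum()) - nv  # LOI excluded
    total = nv * nv - nv
    rec = 100.0 * n_recurrent / total
    nan = float("nan")
    if n_recurrent == 0:
        return rec, nan, nan, nan, nan

    # run lengths along all upper-triangle diagonals (matrix is symmetric)
    diags = [
        np.concatenate([rec_matrix.diagonal(k), [False]])
        for k in range(1, nv)
    ]
    flat = np.concatenate([[False]] + diags).astype(np.int8)
    change = np.diff(flat)
    lengths = np.flatnonzero(change == -1) - np.flatnonzero(change == 1)
    lines = lengths[lengths >= lmin]
    det = 100.0 * 2.0 * lines.sum() / n_recurrent
    if lines.size == 0:
        return rec, det, nan, nan, nan
    _, counts = np.unique(lines, return_counts=True)
    p = counts / counts.sum()
    shanen = float(-(p * np.log(p)).sum())
    return rec, det, float(lines.mean()), float(lines.max()), shanen


# ---------------------------------------------------------------------------
# profile assembly

_GROUPS: dict[str, tuple[str, ...]] = {
    "basic": ("MeanRR", "MeanHR", "SDNN", "RMSSD", "NN50", "pNN50"),
    "geometric": ("HRVti", "TINN"),
    "si": ("SI",),
    "prsa": ("DC", "DCmod", "AC", "ACmod"),
    "freq": ("LFpower", "HFpower", "TOTpower", "pLF", "pHF", "nLF", "nHF", "LF/HF"),
    "poincare": ("SD1", "SD2", "SD2/SD1"),
    "apen": ("ApEn",),
    "sampen": ("SampEn",),
    "dfa": ("DFA_alpha1", "DFA_alpha2"),
    "d2": ("D2",),
    "rpa": ("REC", "DET", "Lmean", "Lmax", "ShanEn"),
}


def hrv_profile(
    segment: Segment | Tachogram, params: tuple[str, ...] | None = None
) -> HRVProfile:
    """Compute the requested HRV parameters (all 34 by default) of a segment.

    Metric-level failures (too few beats, degenerate series) are recorded
    as NaN sentinels with a reason and never abort the batch.  The result
    is deterministic for identical input.
    """
    tach = segment.tachogram if isinstance(segment, Segment) else segment
    rr = tach.rr
    requested = PARAMETERS if params is None else tuple(params)
    unknown = set(requested) - set(PARAMETERS)
    if unknown:
        raise ValueError(f"unknown parameters: {sorted(unknown)}")
    req = set(requested)
    values: dict[str, float] = {}
    sentinels: dict[str, str] = {}

    def put(names, vals, reason=None):
        for name, val in zip(names, vals):
            if name not in req:
                continue
            values[name] = float(val)
            if reason is not None or (
                isinstance(val, float) and math.isnan(val)
            ):
                sentinels[name] = reason or "degenerate input"

    def run(group, fn):
        names = _GROUPS[group]
        if not req & set(names):
            return
        try:
            put(names, fn())
        except (ValueError, RuntimeError) as exc:
            put(names, [float("nan")] * len(names), reason=str(exc))

    run("basic", lambda: (*mean_rr_hr(rr), sdnn(rr), rmssd(rr), *nn50_pnn50(rr)))
    run("geometric", lambda: geometric(rr))
    run("si", lambda: (stress_index(rr),))
    run("prsa", lambda: prsa_dc_ac(rr))

    def _freq():
        _, sig = resample_rr(tach)
        bp = band_powers(welch_psd(sig))
        return tuple(bp[name] for name in _GROUPS["freq"])

    run("freq", _freq)
    run("poincare", lambda: poincare(rr))
    run("apen", lambda: (apen(rr),))
    run("sampen", lambda: (sampen(rr),))
    run("dfa", lambda: dfa(rr))
    run("d2", lambda: (corr_dim(rr),))
    run("rpa", lambda: rpa_metrics(rr))

    ordered = {name: values[name] for name in requested}
    return HRVProfile(ordered, sentinels, tach.recording_id)


def profiles_to_frame(profiles: list[HRVProfile]) -> pd.DataFrame:
    """One tidy row per segment, columns named by parameter abbreviation."""
    return pd.DataFrame([p.values for p in profiles])
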